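"""File formats: label fields as PNG/TIFF with JSON sidecars, masks, configs.

Conventions: 2D label fields are 16-bit PNGs in which the interface code -1
is stored as 65535; 3D fields are multi-page TIFFs (one page per x-slice);
arrival-time fields are 32-bit float TIFFs. Every image gets a ``.json``
sidecar holding resolution (mm/cell), origin, the code table and metadata —
pixel size is metadata, never inferred from image headers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

from .geometry import Arena, ArrivalField, INTERFACE, LabelField, SeedConfig, SimParams

__all__ = [
    "write_label_field",
    "read_label_field",
    "write_arrival_field",
    "read_arrival_field",
    "read_mask",
    "binarize",
    "write_agreement_png",
    "config_hash",
]

_INTERFACE_CODE = 65535  # on-disk stand-in for label -1 in uint16 images


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def _write_sidecar(path, lf_like, codes: dict) -> None:
    meta = {
        "resolution_mm": float(lf_like.resolution),
        "origin_mm": np.asarray(lf_like.origin, dtype=float).tolist(),
        "codes": codes,
        "meta": _jsonable(lf_like.meta),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_label_field(labels: LabelField, path) -> Path:
    """Write a label field as 16-bit PNG (2D) or multi-page TIFF (3D),
    plus a JSON sidecar with grid geometry and the code table."""
    path = Path(path)
    grid = labels.grid.astype(np.int64)
    if grid.max(initial=0) >= _INTERFACE_CODE:
        raise ValueError("too many labels for 16-bit storage")
    encoded = np.where(grid == INTERFACE, _INTERFACE_CODE, grid).astype(np.uint16)
    if labels.dim == 2:
        iio.imwrite(path, encoded, extension=".png")
    elif labels.dim == 3:
        tifffile.imwrite(path, encoded, photometric="minisblack")
    else:
        raise ValueError("only 2D/3D label fields are supported")
    codes = {"unreached": 0, "interface": _INTERFACE_CODE}
    _write_sidecar(path, labels, codes)
    return path


def read_label_field(path) -> LabelField:
    """Read a label field written by :func:`write_label_field`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        encoded = tifffile.imread(path)
    else:
        encoded = iio.imread(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    iface = sidecar.get("codes", {}).get("interface", _INTERFACE_CODE)
    grid = encoded.astype(np.int32)
    grid[encoded == iface] = INTERFACE
    return LabelField(
        grid=grid,
        resolution=float(sidecar["resolution_mm"]),
        origin=np.asarray(sidecar["origin_mm"], dtype=float),
        meta=sidecar.get("meta", {}),
    )


def write_arrival_field(arrivals: ArrivalField, path) -> Path:
    """Write arrival times as a 32-bit float TIFF (+inf preserved)."""
    path = Path(path)
    tifffile.imwrite(path, arrivals.grid.astype(np.float32), photometric="minisblack")
    _write_sidecar(path, arrivals, {"unreached": "inf"})
    return path


def read_arrival_field(path) -> ArrivalField:
    path = Path(path)
    grid = tifffile.imread(path).astype(np.float64)
    sidecar = json.loads(_sidecar_path(path).read_text())
    return ArrivalField(
        grid=grid,
        resolution=float(sidecar["resolution_mm"]),
        origin=np.asarray(sidecar["origin_mm"], dtype=float),
        meta=sidecar.get("meta", {}),
    )


def read_mask(path, resolution: float = 1.0, origin=None) -> LabelField:
    """Read an 8-/16-bit PNG or (multi-page) TIFF as a label field.

    Pixel value 0 is background; distinct nonzero values become labels
    1..K in ascending value order (so an 8-bit {0, 255} mask is a single
    label). A sidecar JSON next to the image, when present, overrides
    ``resolution``/``origin``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
        if img.ndim == 3 and img.shape[-1] in (3, 4):  # RGB(A) -> luminance
            img = img[..., :3].max(axis=-1)
    if not np.issubdtype(img.dtype, np.integer):
        if not np.allclose(img, np.round(img)):
            raise ValueError(f"{path}: non-integer pixel values; not a mask")
        img = np.round(img).astype(np.int64)
    values = np.unique(img)
    values = values[values > 0]
    grid = np.zeros(img.shape, dtype=np.int32)
    for new, val in enumerate(values, start=1):
        grid[img == val] = new
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        sc = json.loads(sidecar.read_text())
        resolution = float(sc.get("resolution_mm", resolution))
        if "origin_mm" in sc:
            origin = sc["origin_mm"]
    if origin is None:
        origin = np.zeros(grid.ndim)
    return LabelField(
        grid=grid, resolution=float(resolution), origin=np.asarray(origin, float)
    )


def binarize(image, threshold: float = 0.5, largest_component: bool = False) -> np.ndarray:
    """Threshold a grayscale image at ``threshold * max`` intensity.

    Minimal segmentation stand-in for mask creation: no morphology or
    contour refinement. ``largest_component=True`` keeps only the largest
    connected foreground component.
    """
    img = np.asarray(image, dtype=float)
    mx = img.max(initial=0.0)
    if mx <= 0:
        raise ValueError("blank image: nothing to binarize")
    mask = img >= threshold * mx
    if largest_component and mask.any():
        comp, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
            mask = comp == (1 + int(np.argmax(sizes)))
    return mask


def write_agreement_png(category_grid: np.ndarray, path) -> Path:
    """Write an agreement map as RGB PNG (white/red/blue/black palette)."""
    from .metrics import agreement_rgb

    path = Path(path)
    iio.imwrite(path, agreement_rgb(category_grid), extension=".png")
    return path


def config_hash(d: dict) -> str:
    """Stable sha256 of a JSON-serialisable configuration (provenance)."""
    canon = json.dumps(_jsonable(d), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
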