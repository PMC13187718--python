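"""Binary-mask similarity between experimental and simulated partitions.

Implements the three mask-agreement statistics used to compare colony
images against simulated partitions — Jaccard index, mean Chamfer distance
(in physical units), and Pearson correlation of the 0/1 fields — plus the
four-category agreement map and an area-weighted multi-label report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import LabelField

__all__ = [
    "jaccard",
    "chamfer_mean",
    "pearson_binary",
    "agreement_map",
    "multilabel_report",
    "SimilarityReport",
    "AGREEMENT_CODES",
    "AGREEMENT_PALETTE",
]

#: agreement-map category codes
AGREEMENT_CODES = {"neither": 0, "only_experiment": 1, "only_simulation": 2, "both": 3}
#: RGB palette: neither=black, experiment-only=red, simulation-only=blue, both=white
AGREEMENT_PALETTE = np.array(
    [[0, 0, 0], [255, 0, 0], [0, 0, 255], [255, 255, 255]], dtype=np.uint8
)


def _as_bool(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool:
        m = m.astype(bool)
    return m


def _check_shapes(a, b):
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def jaccard(a, b) -> float:
    """Intersection over union of two binary masks; 1 iff identical."""
    a = _as_bool(a)
    b = _as_bool(b)
    _check_shapes(a, b)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise ValueError("Jaccard undefined: both masks are empty")
    inter = int(np.count_nonzero(a & b))
    return inter / union


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Cells true with at least one false face-neighbour (array edge counts
    as false), i.e. face-connectivity boundary extraction."""
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    return mask & ~ndimage.binary_erosion(mask, structure=struct, border_value=0)


def chamfer_mean(a, b, resolution: float = 1.0, symmetric: bool = True):
    """Mean Chamfer distance between mask boundaries, in mm.

    Extracts the face-connectivity boundary of each mask, then returns
    ``0.5 * (mean over dA of nearest-dB distance + mean over dB of
    nearest-dA distance) * resolution``. Smaller is more similar; 0 iff the
    boundary sets coincide. With ``symmetric=False`` the two directed means
    are returned as a tuple instead.
    """
    a = _as_bool(a)
    b = _as_bool(b)
    _check_shapes(a, b)
    if not a.any() or not b.any():
        raise ValueError("Chamfer distance requires two nonempty masks")
    ba = _boundary(a)
    bb = _boundary(b)
    # Euclidean distance (cell units) from every cell to the nearest boundary cell
    d_to_bb = ndimage.distance_transform_edt(~bb)
    d_to_ba = ndimage.distance_transform_edt(~ba)
    ab = float(d_to_bb[ba].mean()) * resolution
    ba_ = float(d_to_ba[bb].mean()) * resolution
    if symmetric:
        return 0.5 * (ab + ba_)
    return ab, ba_


def pearson_binary(a, b) -> float:
    """Pearson correlation of the two masks as 0/1 fields."""
    a = _as_bool(a)
    b = _as_bool(b)
    _check_shapes(a, b)
    x = a.reshape(-1).astype(float)
    y = b.reshape(-1).astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson undefined for a constant mask (zero variance)")
    return float(np.corrcoef(x, y)[0, 1])


def agreement_map(experiment, simulation):
    """Four-category comparison grid and counts.

    Categories: both (white), only_experiment (red), only_simulation (blue),
    neither (black). Counts satisfy
    ``jaccard = both / (both + only_experiment + only_simulation)``.

    Returns (category grid of codes per :data:`AGREEMENT_CODES`, counts dict).
    """
    e = _as_bool(experiment)
    s = _as_bool(simulation)
    _check_shapes(e, s)
    cat = np.zeros(e.shape, dtype=np.uint8)
    cat[e & ~s] = AGREEMENT_CODES["only_experiment"]
    cat[~e & s] = AGREEMENT_CODES["only_simulation"]
    cat[e & s] = AGREEMENT_CODES["both"]
    counts = {
        name: int(np.count_nonzero(cat == code))
        for name, code in AGREEMENT_CODES.items()
    }
    return cat, counts


def agreement_rgb(category_grid: np.ndarray) -> np.ndarray:
    """Render an agreement map as an RGB image (white/red/blue/black)."""
    return AGREEMENT_PALETTE[category_grid]


@dataclass
class SimilarityReport:
    """Per-label similarity metrics with area-weighted aggregates.

    ``per_label`` has one row per compared label with columns
    ``jaccard``, ``chamfer_mm``, ``pearson``, ``area_cells``; the weighted
    aggregate of each metric is sum(metric_k * area_k) / sum(area_k).
    ``counts`` are pooled foreground agreement counts over the evaluation
    region.
    """

    per_label: pd.DataFrame
    counts: dict
    area_weighting: str = "experiment"
    meta: dict = field(default_factory=dict)

    def _weighted(self, col: str) -> float:
        w = self.per_label["area_cells"].to_numpy(dtype=float)
        v = self.per_label[col].to_numpy(dtype=float)
        return float((v * w).sum() / w.sum())

    @property
    def weighted_jaccard(self) -> float:
        return self._weighted("jaccard")

    @property
    def weighted_chamfer(self) -> float:
        return self._weighted("chamfer_mm")

    @property
    def weighted_pearson(self) -> float:
        return self._weighted("pearson")

    def to_frame(self) -> pd.DataFrame:
        """Per-label table plus a trailing area-weighted aggregate row."""
        df = self.per_label.copy()
        agg = {
            "label": "weighted",
            "jaccard": self.weighted_jaccard,
            "chamfer_mm": self.weighted_chamfer,
            "pearson": self.weighted_pearson,
            "area_cells": df["area_cells"].sum(),
        }
        return pd.concat([df, pd.DataFrame([agg])], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "per_label": self.per_label.to_dict(orient="records"),
            "weighted": {
                "jaccard": self.weighted_jaccard,
                "chamfer_mm": self.weighted_chamfer,
                "pearson": self.weighted_pearson,
            },
            "counts": self.counts,
            "area_weighting": self.area_weighting,
        }


def _label_masks(obj, labels=None) -> dict:
    """Normalise a LabelField / label array / dict-of-masks to {label: mask}."""
    if isinstance(obj, dict):
        return {int(k): _as_bool(v) for k, v in obj.items()}
    if isinstance(obj, LabelField):
        grid = obj.grid
    else:
        grid = np.asarray(obj)
    if labels is None:
        vals = np.unique(grid)
        labels = [int(v) for v in vals if v > 0]
    return {int(k): grid == int(k) for k in labels}


def multilabel_report(
    experiment,
    simulation,
    pairing: Optional[dict] = None,
    region: Optional[np.ndarray] = None,
    resolution: Optional[float] = None,
    area_weighting: str = "experiment",
) -> SimilarityReport:
    """Compare a multi-label experiment against a multi-label simulation.

    Per paired label, computes Jaccard, mean Chamfer (mm) and the Pearson
    coefficient of the masks, then area-weighted aggregates. Interface (-1)
    and unreached (0) cells count as background. ``pairing`` maps experiment
    labels to simulation labels (default: identity on the experiment's
    labels) and must be a bijection over the labels present; a label present
    on one side but unpaired on the other is an error. ``region`` optionally
    restricts evaluation (e.g. the tessellation crop); pooled agreement
    counts then sum to the region's cell count.

    ``area_weighting`` selects the weights: ``"experiment"`` (the
    experimental mask areas) or ``"union"``.
    """
    if resolution is None:
        for obj in (experiment, simulation):
            if isinstance(obj, LabelField):
                resolution = obj.resolution
                break
        else:
            resolution = 1.0
    exp_masks = _label_masks(experiment)
    sim_masks = _label_masks(simulation)
    if pairing is None:
        pairing = {k: k for k in exp_masks}
    if len(set(pairing.values())) != len(pairing):
        raise ValueError("pairing must be a bijection")
    missing_e = sorted(set(exp_masks) - set(pairing))
    missing_s = sorted(set(sim_masks) - set(pairing.values()))
    if missing_e or missing_s:
        raise ValueError(
            f"unpaired labels present: experiment {missing_e}, simulation {missing_s}"
        )

    if region is not None:
        region = _as_bool(region)

    shape = next(iter({**exp_masks, **sim_masks}.values())).shape
    rows = []
    for ke, ks in sorted(pairing.items()):
        me = exp_masks.get(ke, np.zeros(shape, dtype=bool))
        ms = sim_masks.get(ks, np.zeros(shape, dtype=bool))
        _check_shapes(me, ms)
        if region is not None:
            me = me & region
            ms = ms & region
        if me.any() != ms.any():
            raise ValueError(
                f"label pair ({ke}, {ks}) is empty on one side only; "
                "exclude it from the pairing or fix the masks"
            )
        if not me.any():
            raise ValueError(f"label pair ({ke}, {ks}) empty on both sides")
        area = int(np.count_nonzero(me | ms if area_weighting == "union" else me))
        rows.append(
            {
                "label": ke,
                "jaccard": jaccard(me, ms),
                "chamfer_mm": chamfer_mean(me, ms, resolution=resolution),
                "pearson": pearson_binary(me, ms),
                "area_cells": area,
            }
        )

    fg_e = np.zeros(shape, dtype=bool)
    fg_s = np.zeros_like(fg_e)
    for ke, ks in pairing.items():
        fg_e |= exp_masks.get(ke, fg_e)
        fg_s |= sim_masks.get(ks, fg_s)
    if region is not None:
        fg_e &= region
        fg_s &= region
    _, counts = agreement_map(fg_e, fg_s)
    if region is not None:
        counts["neither"] = int(region.sum()) - (
            counts["both"] + counts["only_experiment"] + counts["only_simulation"]
        )
    return SimilarityReport(
        per_label=pd.DataFrame(rows),
        counts=counts,
        area_weighting=area_weighting,
        meta={"resolution": resolution},
    )
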