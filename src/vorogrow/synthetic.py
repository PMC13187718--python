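"""Synthetic seeding arrangements and pseudo-experimental colony images.

Generates (a) the seeding presets used across the study conditions —
triangular, square, cross and hexagonal inoculation grids, annular and
disordered arrangements, cube vertices in 3D — and (b) noisy
pseudo-experimental masks and time-lapses with retained ground truth:
smoothly rough colony boundaries, a low-density interface gap, and speckle,
emulating scanner/confocal segmentation output so the whole pipeline is
testable without any external images.

All randomness is seeded explicitly; identical seeds give bit-identical
output, and the seed is recorded in every manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .geometry import Arena, LabelField, SeedConfig, SimParams
from .rgm import simulate_rgm, snapshot

__all__ = [
    "SynthParams",
    "make_arrangement",
    "render_pseudo_experiment",
    "make_timelapse",
    "PseudoExperiment",
    "Timelapse",
    "ARRANGEMENTS",
]

ARRANGEMENTS = ("triangle", "square", "cross", "hexagon", "annulus", "disordered", "cube")


@dataclass(frozen=True)
class SynthParams:
    """Noise model for pseudo-experimental masks.

    boundary_sigma : float
        Standard deviation of the radial boundary perturbation, mm.
    boundary_corr : float
        Angular correlation length of the boundary roughness, degrees;
        larger values give smoother, longer-wavelength undulations.
    gap_width : float
        Width of the low-density band carved between adjacent colonies, mm
        (mimics the visible interface gap in the images).
    speckle_rate : float
        Fraction of mask cells flipped at random (segmentation speckle);
        must be < 0.05.
    rng_seed : int
        Seed for all randomness; recorded in output metadata.
    """

    boundary_sigma: float = 0.0
    boundary_corr: float = 30.0
    gap_width: float = 0.0
    speckle_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.boundary_sigma < 0 or self.boundary_corr < 0 or self.gap_width < 0:
            raise ValueError("noise parameters must be nonnegative")
        if not (0 <= self.speckle_rate < 0.05):
            raise ValueError("speckle_rate must be in [0, 0.05)")


# ---------------------------------------------------------------------------
# seeding arrangements
# ---------------------------------------------------------------------------


def _ring(n: int, radius: float, phase: float = 0.0) -> np.ndarray:
    ang = phase + 2 * np.pi * np.arange(n) / n
    return radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def make_arrangement(
    kind: str,
    spacing: float,
    n: Optional[int] = None,
    jitter: float = 0.0,
    rng_seed: Optional[int] = None,
    arena: Optional[Arena] = None,
    rates=None,
) -> SeedConfig:
    """Seeding positions for a named preset, centred on the arena centre.

    Presets and the meaning of ``spacing`` (mm):

    - ``triangle``: equilateral triangle, side = spacing (e.g. the 4 cm
      triple-inoculation layout).
    - ``square``: square, side = spacing.
    - ``cross``: centre seed plus 4 seeds at distance = spacing along the axes.
    - ``hexagon``: 6 seeds at circumradius = spacing, so nearest-neighbour
      spacing = spacing (e.g. the 5.5 mm pellicle hexagon).
    - ``annulus``: ``n`` seeds evenly spaced on a circle of radius = spacing.
    - ``disordered``: ``n`` seeds drawn uniformly inside the arena with
      minimum pairwise separation max(spacing, 4 * resolution); requires
      ``arena`` and ``rng_seed``.
    - ``cube``: 8 seeds at the vertices of a cube with edge = spacing (3D).

    ``jitter`` adds seeded isotropic Gaussian displacement (mm) to the
    deterministic presets. Regular presets are bit-reproducible; stochastic
    ones are reproducible for a fixed ``rng_seed``.
    """
    kind = kind.lower()
    if kind not in ARRANGEMENTS:
        raise ValueError(f"unknown arrangement {kind!r}; choose from {ARRANGEMENTS}")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")

    rng = np.random.default_rng(rng_seed)

    if kind == "triangle":
        pos = _ring(3, spacing / np.sqrt(3.0), phase=np.pi / 2)
    elif kind == "square":
        pos = _ring(4, spacing / np.sqrt(2.0), phase=np.pi / 4)
    elif kind == "cross":
        pos = np.vstack([[0.0, 0.0], _ring(4, spacing)])
    elif kind == "hexagon":
        pos = _ring(6, spacing)
    elif kind == "annulus":
        if n is None or n < 2:
            raise ValueError("annulus preset needs n >= 2")
        pos = _ring(n, spacing)
    elif kind == "cube":
        h = spacing / 2.0
        pos = np.array(
            [[sx * h, sy * h, sz * h] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
    elif kind == "disordered":
        if n is None or n < 1:
            raise ValueError("disordered preset needs n >= 1")
        if arena is None:
            raise ValueError("disordered preset needs an arena")
        if rng_seed is None:
            raise ValueError("disordered preset is stochastic: rng_seed is required")
        min_sep = max(spacing, 4.0 * arena.resolution)
        half = 0.5 * np.array(arena.spans) - 2.0 * arena.resolution
        pts = []
        tries = 0
        while len(pts) < n:
            cand = rng.uniform(-half, half)
            if not arena.contains(cand[None, :])[0]:
                tries += 1
            elif pts and np.min(
                np.linalg.norm(np.asarray(pts) - cand, axis=1)
            ) < min_sep:
                tries += 1
            else:
                pts.append(cand)
                continue
            if tries > 10000:
                raise ValueError(
                    "could not place seeds with the requested separation; "
                    "reduce n or spacing"
                )
        pos = np.asarray(pts)
    if jitter > 0:
        if rng_seed is None:
            raise ValueError("jitter is stochastic: rng_seed is required")
        pos = pos + rng.normal(scale=jitter, size=pos.shape)

    if arena is not None:
        if pos.shape[1] != arena.dim:
            raise ValueError(f"{kind} preset is {pos.shape[1]}D but arena is {arena.dim}D")
        if not np.all(arena.contains(pos)):
            raise ValueError(
                f"{kind} arrangement with spacing {spacing} mm does not fit the arena"
            )
    if rates is None:
        rates = np.ones(pos.shape[0])
    return SeedConfig(positions=pos, rates=rates)


# ---------------------------------------------------------------------------
# pseudo-experimental rendering
# ---------------------------------------------------------------------------


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance in cell units: negative inside the mask."""
    outside = ndimage.distance_transform_edt(~mask)
    inside = ndimage.distance_transform_edt(mask)
    return outside - inside


def _angular_noise(theta: np.ndarray, sigma: float, corr_deg: float, rng) -> np.ndarray:
    """Smooth periodic perturbation delta(theta) with Var = sigma^2.

    Random Fourier series with a Gaussian angular spectrum of correlation
    length ``corr_deg``; mode 0 is excluded so the mean radius is preserved.
    """
    corr = np.deg2rad(max(corr_deg, 1.0))
    m_max = max(int(np.ceil(4.0 / corr)), 2)
    m = np.arange(1, m_max + 1)
    w = np.exp(-0.5 * (m * corr) ** 2)
    s2 = sigma**2 * w / w.sum()
    a = rng.normal(scale=np.sqrt(s2))
    b = rng.normal(scale=np.sqrt(s2))
    return (
        a[None, :] * np.cos(m[None, :] * theta[:, None])
        + b[None, :] * np.sin(m[None, :] * theta[:, None])
    ).sum(axis=1)


def _smooth_field_noise(shape, sigma: float, corr_cells: float, rng) -> np.ndarray:
    """Gaussian random field with std sigma (used for 3D fields)."""
    white = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(white, sigma=max(corr_cells, 1.0))
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth * (sigma / sd)


def _perturb_mask(
    mask: np.ndarray,
    center_idx: np.ndarray,
    params: SynthParams,
    resolution: float,
    rng,
) -> np.ndarray:
    """Displace a colony's boundary along its normal by correlated noise."""
    if params.boundary_sigma == 0:
        return mask.copy()
    sd = _signed_distance(mask) * resolution
    inradius = -sd.min()
    if params.boundary_sigma >= inradius:
        raise ValueError(
            f"boundary_sigma {params.boundary_sigma} mm exceeds the colony "
            f"inradius {inradius:.3g} mm"
        )
    if mask.ndim == 2:
        ii, jj = np.indices(mask.shape)
        theta = np.arctan2(jj - center_idx[1], ii - center_idx[0])
        delta = _angular_noise(theta.reshape(-1), params.boundary_sigma,
                               params.boundary_corr, rng).reshape(mask.shape)
    else:
        # correlation length mapped onto the grid via the colony mean radius
        r_mean = float(ndimage.distance_transform_edt(mask).max())
        corr_cells = np.deg2rad(max(params.boundary_corr, 1.0)) * max(r_mean, 1.0)
        delta = _smooth_field_noise(mask.shape, params.boundary_sigma, corr_cells, rng)
    return sd <= delta


def _carve_gap_masks(masks: dict, gap_width: float, resolution: float) -> dict:
    if gap_width <= 0:
        return masks
    half = 0.5 * gap_width
    out = {}
    for k, m in masks.items():
        other = np.zeros_like(m)
        for k2, m2 in masks.items():
            if k2 != k:
                other |= m2
        if other.any():
            d = ndimage.distance_transform_edt(~other, sampling=resolution)
            out[k] = m & (d > half)
        else:
            out[k] = m.copy()
    return out


@dataclass
class PseudoExperiment:
    """Noisy per-colony masks with their retained ground truth."""

    masks: dict  # label -> bool array
    truth: LabelField
    params: SynthParams
    manifest: dict = field(default_factory=dict)

    def labeled_frame(self) -> np.ndarray:
        """Combine masks into one label grid (overlaps -> lowest label)."""
        frame = np.zeros(self.truth.grid.shape, dtype=np.int32)
        for k in sorted(self.masks, reverse=True):
            frame[self.masks[k]] = k
        return frame

    def channel_images(
        self, channels: Sequence[str], smooth_sigma: float = 1.0
    ) -> dict:
        """Render per-channel intensity images in [0, 1].

        ``channels[k-1]`` names colony k's fluorophore; colonies sharing a
        tag land in the same channel (e.g. dTomato/sfGFP two-channel runs).
        """
        if len(channels) != len(self.masks):
            raise ValueError("one channel tag per colony required")
        out = {}
        for tag in dict.fromkeys(channels):
            img = np.zeros(self.truth.grid.shape, dtype=float)
            for k, m in self.masks.items():
                if channels[k - 1] == tag:
                    img[m] = 1.0
            if smooth_sigma > 0:
                img = ndimage.gaussian_filter(img, sigma=smooth_sigma)
                mx = img.max()
                if mx > 0:
                    img = img / mx
            out[tag] = img
        return out


def render_pseudo_experiment(
    labels: LabelField, params: SynthParams
) -> PseudoExperiment:
    """Turn a clean simulated partition into noisy per-colony masks.

    Per colony: the boundary is displaced along its normal by seeded
    correlated noise (std ``boundary_sigma`` mm, angular correlation
    ``boundary_corr`` degrees), the interface is eroded to ``gap_width``,
    and ``speckle_rate`` of cells are flipped. The clean field is retained
    as ground truth. With all parameters zero the masks equal the clean
    per-colony masks exactly.
    """
    rng = np.random.default_rng(params.rng_seed)
    raw = labels.raw_grid if labels.raw_grid is not None else labels.grid
    res = labels.resolution
    arena_meta = labels.meta.get("arena")
    inside = None
    if arena_meta is not None:
        inside = Arena.from_dict(arena_meta).inside_mask()

    masks = {}
    for k in sorted(int(v) for v in np.unique(raw) if v > 0):
        clean = raw == k
        center_idx = np.array(ndimage.center_of_mass(clean))
        noisy = _perturb_mask(clean, center_idx, params, res, rng)
        if inside is not None:
            noisy &= inside
        masks[k] = noisy

    masks = _carve_gap_masks(masks, params.gap_width, res)

    if params.speckle_rate > 0:
        for k in sorted(masks):
            flips = rng.random(masks[k].shape) < params.speckle_rate
            masks[k] = masks[k] ^ flips

    manifest = {
        "rng_seed": params.rng_seed,
        "boundary_sigma": params.boundary_sigma,
        "boundary_corr": params.boundary_corr,
        "gap_width": params.gap_width,
        "speckle_rate": params.speckle_rate,
    }
    return PseudoExperiment(masks=masks, truth=labels, params=params, manifest=manifest)


# ---------------------------------------------------------------------------
# time-lapses
# ---------------------------------------------------------------------------


@dataclass
class Timelapse:
    """Pseudo-experimental time-lapse with retained ground truth."""

    frames: list  # noisy labelled int arrays, one per time
    clean: list  # clean LabelField snapshots
    times: np.ndarray  # hours
    config: SeedConfig
    arena: Arena
    manifest: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def make_timelapse(
    config: SeedConfig,
    arena: Arena,
    times: Sequence[float],
    params: SynthParams,
    sim_params: Optional[SimParams] = None,
) -> Timelapse:
    """Simulate a run and render a noisy snapshot per acquisition time.

    Each frame gets independent noise drawn from per-frame child seeds of
    ``params.rng_seed``; the clean snapshots and all seeds are retained in
    the output (ground truth for inference tests).
    """
    times = np.asarray(list(times), dtype=float)
    if times.size < 1:
        raise ValueError("need at least one frame time")
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("frame times must be nonnegative")
    t_end = float(times[-1]) if times[-1] > 0 else 1.0
    if sim_params is None:
        sim_params = SimParams(t_max=t_end)
    elif sim_params.t_max < times[-1]:
        raise ValueError("sim_params.t_max must cover the last frame time")

    full_labels, full_arrivals = simulate_rgm(config, arena, sim_params)
    children = np.random.SeedSequence(params.rng_seed).spawn(times.size)
    frames = []
    clean = []
    for f, t in enumerate(times):
        snap = snapshot(full_labels, full_arrivals, float(t))
        clean.append(snap)
        noisy_any = params.boundary_sigma > 0 or params.speckle_rate > 0 or params.gap_width > 0
        if noisy_any and t > 0:
            frame_params = SynthParams(
                boundary_sigma=params.boundary_sigma,
                boundary_corr=params.boundary_corr,
                gap_width=params.gap_width,
                speckle_rate=params.speckle_rate,
                rng_seed=int(children[f].generate_state(1)[0] % (2**31)),
            )
            pe = render_pseudo_experiment(snap, frame_params)
            frames.append(pe.labeled_frame())
        else:
            frames.append(snap.grid.copy())
    manifest = {
        "rng_seed": params.rng_seed,
        "times_h": times.tolist(),
        "seed_positions": config.positions.tolist(),
        "rates": config.rates.tolist(),
        "arena": arena.to_dict(),
        "sim_params": sim_params.to_dict(),
        "synth_params": {
            "boundary_sigma": params.boundary_sigma,
            "boundary_corr": params.boundary_corr,
            "gap_width": params.gap_width,
            "speckle_rate": params.speckle_rate,
        },
    }
    return Timelapse(
        frames=frames, clean=clean, times=times, config=config, arena=arena,
        manifest=manifest,
    )
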