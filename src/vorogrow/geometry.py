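"""Domain geometry: arenas, seeding configurations, simulation parameters, grid fields.

World coordinates are in millimetres, times in hours. Grids are regular with
square/cubic cells of edge ``resolution`` mm; the centre of cell index
``(i, j[, k])`` sits at ``origin + (index + 0.5) * resolution``. Array axis 0
is the world x axis throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Arena",
    "SeedConfig",
    "SimParams",
    "LabelField",
    "ArrivalField",
    "INTERFACE",
    "UNREACHED",
]

#: label code for the low-density interface band between collided colonies
INTERFACE = -1
#: label code for cells no colony has reached (or outside the arena wall)
UNREACHED = 0

_SHAPES_2D = ("disk", "rectangle")
_SHAPES_3D = ("sphere", "box")


@dataclass(frozen=True)
class Arena:
    """Physical domain of the experiment: a petri dish (2D) or volume (3D).

    Parameters
    ----------
    dim : int
        2 or 3.
    shape : str
        ``"disk"`` or ``"rectangle"`` in 2D, ``"sphere"`` or ``"box"`` in 3D.
        Disk/sphere arenas model the petri-dish wall: cells outside the
        radius are permanently unclaimable.
    extent : float or sequence of float
        Radius (mm) for disk/sphere; side lengths per axis (mm) for
        rectangle/box. The domain is centred on the world origin.
    resolution : float
        Cell edge length, mm. Each axis must span at least 16 cells.
    """

    dim: int
    shape: str
    extent: object
    resolution: float

    def __post_init__(self):
        if self.dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.dim}")
        allowed = _SHAPES_2D if self.dim == 2 else _SHAPES_3D
        if self.shape not in allowed:
            raise ValueError(
                f"shape {self.shape!r} not valid for dim={self.dim}; allowed: {allowed}"
            )
        if not (self.resolution > 0):
            raise ValueError("resolution must be > 0")
        for span in self.spans:
            if span / self.resolution < 16:
                raise ValueError(
                    "extent/resolution must give at least 16 cells per axis"
                )

    # -- derived geometry -------------------------------------------------

    @property
    def is_radial(self) -> bool:
        return self.shape in ("disk", "sphere")

    @property
    def radius(self) -> float:
        if not self.is_radial:
            raise AttributeError(f"{self.shape} arena has no radius")
        return float(np.asarray(self.extent, dtype=float).reshape(-1)[0])

    @property
    def spans(self) -> tuple:
        """Full side length of the bounding box along each axis, mm."""
        if self.is_radial:
            return (2.0 * self.radius,) * self.dim
        ext = np.asarray(self.extent, dtype=float).reshape(-1)
        if ext.size == 1:
            ext = np.repeat(ext, self.dim)
        if ext.size != self.dim:
            raise ValueError("extent must give one length per axis")
        return tuple(float(e) for e in ext)

    @property
    def grid_shape(self) -> tuple:
        return tuple(int(round(s / self.resolution)) for s in self.spans)

    @property
    def origin(self) -> np.ndarray:
        """World coordinate of the corner of cell (0, ..., 0)."""
        return -0.5 * np.asarray(self.spans, dtype=float)

    def cell_centers(self) -> list:
        """Per-axis 1D arrays of cell-centre world coordinates."""
        org = self.origin
        return [
            org[a] + (np.arange(n) + 0.5) * self.resolution
            for a, n in enumerate(self.grid_shape)
        ]

    def coordinate_grids(self) -> list:
        """Broadcastable dense coordinate arrays (one per axis)."""
        return list(np.meshgrid(*self.cell_centers(), indexing="ij", sparse=True))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True for world points strictly inside the arena boundary."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.is_radial:
            ok = np.einsum("ij,ij->i", pts, pts) < self.radius**2
        else:
            half = 0.5 * np.asarray(self.spans)
            ok = np.all(np.abs(pts) < half, axis=1)
        return ok

    def inside_mask(self) -> np.ndarray:
        """Boolean grid: cell centres inside the arena boundary."""
        if self.is_radial:
            coords = self.coordinate_grids()
            r2 = sum(c**2 for c in coords)
            return r2 < self.radius**2
        return np.ones(self.grid_shape, dtype=bool)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor((pts - self.origin) / self.resolution).astype(np.int64)
        return np.clip(idx, 0, np.asarray(self.grid_shape) - 1)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + (idx + 0.5) * self.resolution

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        ext = self.extent
        if isinstance(ext, np.ndarray):
            ext = ext.tolist()
        return {
            "dim": self.dim,
            "shape": self.shape,
            "extent": ext,
            "resolution": self.resolution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Arena":
        return cls(
            dim=int(d["dim"]),
            shape=str(d["shape"]),
            extent=d["extent"],
            resolution=float(d["resolution"]),
        )


@dataclass(frozen=True)
class SeedConfig:
    """Ordered inoculation sites with per-colony expansion rates.

    ``positions`` is (K, dim) in mm; ``rates`` (K,) in mm/h; labels are
    implicitly 1..K in order; ``channels`` optionally tags each colony with a
    fluorophore/channel name (e.g. ``"dTomato"``/``"sfGFP"``).
    """

    positions: np.ndarray
    rates: np.ndarray
    channels: Optional[tuple] = None

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        rates = np.asarray(self.rates, dtype=float).reshape(-1)
        if pos.shape[0] != rates.shape[0]:
            raise ValueError("positions and rates must have one entry per colony")
        if np.any(rates <= 0):
            raise ValueError("all rates must be > 0")
        if self.channels is not None and len(self.channels) != pos.shape[0]:
            raise ValueError("channels must have one entry per colony")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "rates", rates)
        if self.channels is not None:
            object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def n_colonies(self) -> int:
        return self.positions.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return np.arange(1, self.n_colonies + 1)

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def validate_in(self, arena: Arena) -> None:
        """Check arena-dependent invariants; raise ValueError on violation."""
        if self.dim != arena.dim:
            raise ValueError(
                f"seed dimension {self.dim} != arena dimension {arena.dim}"
            )
        inside = arena.contains(self.positions)
        if not np.all(inside):
            bad = int(np.flatnonzero(~inside)[0])
            raise ValueError(f"seed {bad} lies outside the arena boundary")
        cells = arena.world_to_index(self.positions)
        _, counts = np.unique(cells, axis=0, return_counts=True)
        if np.any(counts > 1):
            raise ValueError(
                "two seeds fall in the same grid cell; increase resolution "
                "or separate the seeds"
            )

    def to_dict(self) -> dict:
        d = {
            "seeds": [
                {
                    "position": self.positions[i].tolist(),
                    "rate": float(self.rates[i]),
                    "label": int(i + 1),
                }
                for i in range(self.n_colonies)
            ]
        }
        if self.channels is not None:
            for i, entry in enumerate(d["seeds"]):
                entry["channel"] = self.channels[i]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SeedConfig":
        seeds = sorted(d["seeds"], key=lambda s: s.get("label", 0))
        pos = np.array([s["position"] for s in seeds], dtype=float)
        rates = np.array([s.get("rate", 1.0) for s in seeds], dtype=float)
        channels = None
        if any("channel" in s for s in seeds):
            channels = tuple(s.get("channel") for s in seeds)
        return cls(positions=pos, rates=rates, channels=channels)


@dataclass(frozen=True)
class SimParams:
    """Tunables of the radial-growth simulation.

    dmin : float
        Width of the low-cell-density interface band carved between collided
        colonies, mm. 0 gives a sharp partition (default).
    stencil_order : int or None
        Neighbourhood order of the front-propagation stencil: order r uses
        all coprime integer offsets with max-norm <= r. Order 1 is the
        classic 8-connected (2D) / 26-connected (3D) stencil with a
        worst-case metric overestimate of ~8%; order 2 adds knight moves and
        cuts this to ~2.7% (2D). None selects the package default (order 2).
    t_max : float
        Simulation horizon, hours.
    snapshot_times : tuple of float
        Optional strictly increasing times in [0, t_max] at which callers
        want intermediate snapshots.
    """

    t_max: float
    dmin: float = 0.0
    stencil_order: Optional[int] = None
    snapshot_times: tuple = ()

    def __post_init__(self):
        if not (self.t_max > 0):
            raise ValueError("t_max must be > 0")
        if self.dmin < 0:
            raise ValueError("dmin must be >= 0")
        if self.stencil_order is not None and self.stencil_order < 1:
            raise ValueError("stencil_order must be >= 1")
        st = tuple(float(t) for t in self.snapshot_times)
        if any(t < 0 or t > self.t_max for t in st):
            raise ValueError("snapshot_times must lie in [0, t_max]")
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("snapshot_times must be strictly increasing")
        object.__setattr__(self, "snapshot_times", st)

    def resolved_stencil(self, dim: int) -> int:
        return 2 if self.stencil_order is None else int(self.stencil_order)

    def to_dict(self) -> dict:
        return {
            "t_max": self.t_max,
            "dmin": self.dmin,
            "stencil_order": self.stencil_order,
            "snapshot_times": list(self.snapshot_times),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(
            t_max=float(d["t_max"]),
            dmin=float(d.get("dmin", 0.0)),
            stencil_order=d.get("stencil_order"),
            snapshot_times=tuple(d.get("snapshot_times", ())),
        )


@dataclass
class LabelField:
    """Grid of colony claims.

    ``grid`` holds 0 for unreached/out-of-arena cells, -1 for the interface
    band, and k >= 1 for cells claimed by colony k. ``raw_grid``, when
    present, is the same partition before interface carving (no -1 codes);
    it is what snapshotting and re-carving operate on.
    """

    grid: np.ndarray
    resolution: float
    origin: np.ndarray
    raw_grid: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def dim(self) -> int:
        return self.grid.ndim

    @property
    def n_labels(self) -> int:
        return int(self.grid.max(initial=0))

    @property
    def labels(self) -> np.ndarray:
        vals = np.unique(self.grid)
        return vals[vals > 0]

    def mask(self, label: int) -> np.ndarray:
        """Binary mask of cells claimed by ``label``."""
        label = int(label)
        present = self.raw_grid if self.raw_grid is not None else self.grid
        if label < 1 or label > int(present.max(initial=0)):
            raise ValueError(f"unknown label {label}")
        return self.grid == label

    def copy(self) -> "LabelField":
        return LabelField(
            grid=self.grid.copy(),
            resolution=self.resolution,
            origin=self.origin.copy(),
            raw_grid=None if self.raw_grid is None else self.raw_grid.copy(),
            meta=dict(self.meta),
        )


@dataclass
class ArrivalField:
    """First-arrival times (hours) aligned with a :class:`LabelField`.

    Unreached cells carry ``+inf``. For claimed cells the arrival time is the
    length of the shortest stencil path from the claiming seed divided by
    that colony's rate, so it is always >= straight-line distance / rate.
    """

    grid: np.ndarray
    resolution: float
    origin: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    def copy(self) -> "ArrivalField":
        return ArrivalField(
            self.grid.copy(), self.resolution, self.origin.copy(), dict(self.meta)
        )


def config_to_json(
    seeds: SeedConfig, arena: Arena, params: Optional[SimParams] = None
) -> str:
    """Serialise a full simulation configuration to a JSON string."""
    d = {"arena": arena.to_dict(), **seeds.to_dict()}
    if params is not None:
        d["sim_params"] = params.to_dict()
    return json.dumps(d, indent=2)


def config_from_json(text: str):
    """Inverse of :func:`config_to_json`; returns (SeedConfig, Arena, SimParams|None)."""
    d = json.loads(text)
    arena = Arena.from_dict(d["arena"])
    seeds = SeedConfig.from_dict(d)
    params = None
    if "sim_params" in d:
        params = SimParams.from_dict(d["sim_params"])
    return seeds, arena, params
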