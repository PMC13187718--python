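"""Reference Voronoi constructions, independent of the growth simulation.

These provide the oracle partitions the growth model is compared against:
classical (unweighted) Voronoi polygons in 2D, nearest-seed label grids in
any dimension, the multiplicatively weighted (Apollonius) partition for
heterogeneous rates, and convex hulls of 3D regions for rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from shapely.geometry import Point, Polygon

from .geometry import Arena, LabelField

__all__ = [
    "VoronoiDiagram2D",
    "voronoi_2d",
    "voronoi_label_grid",
    "weighted_arrival_label_grid",
    "region_hulls_3d",
    "RegionHull",
]


@dataclass
class VoronoiDiagram2D:
    """Clipped 2D Voronoi diagram: one polygon per seed plus adjacency.

    ``polygons[i]`` is the ordered (m_i, 2) vertex array of seed i+1's cell;
    ``adjacency`` lists 1-based label pairs whose cells share an edge of
    positive length.
    """

    seeds: np.ndarray
    polygons: list
    adjacency: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.polygons)

    def cell_areas(self) -> np.ndarray:
        return np.array([Polygon(p).area for p in self.polygons])

    def to_geojson(self) -> dict:
        feats = []
        for i, poly in enumerate(self.polygons):
            ring = np.vstack([poly, poly[:1]]).tolist()
            feats.append(
                {
                    "type": "Feature",
                    "properties": {
                        "label": i + 1,
                        "seed": self.seeds[i].tolist(),
                    },
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
        return {
            "type": "FeatureCollection",
            "features": feats,
            "properties": {
                "adjacency": [list(map(int, p)) for p in self.adjacency]
            },
        }


def _clip_polygon(clip, n_arc: int = 128) -> Polygon:
    """Normalise a clip-region description into a shapely polygon."""
    if isinstance(clip, Polygon):
        return clip
    if isinstance(clip, Arena):
        if clip.dim != 2:
            raise ValueError("2D diagrams need a 2D arena")
        if clip.shape == "disk":
            return Point(0.0, 0.0).buffer(clip.radius, quad_segs=max(n_arc // 4, 32))
        sx, sy = clip.spans
        return Polygon(
            [(-sx / 2, -sy / 2), (sx / 2, -sy / 2), (sx / 2, sy / 2), (-sx / 2, sy / 2)]
        )
    arr = np.asarray(clip, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return Polygon(arr)
    raise TypeError("clip must be an Arena, a shapely Polygon, or an (m,2) vertex array")


def _halfplane(si, sj, reach: float) -> Polygon:
    """Large polygon covering {x : |x-si| <= |x-sj|}."""
    si = np.asarray(si, float)
    sj = np.asarray(sj, float)
    mid = 0.5 * (si + sj)
    n = sj - si
    n = n / np.linalg.norm(n)
    t = np.array([-n[1], n[0]])
    L = reach
    return Polygon(
        [
            mid + L * t,
            mid - L * t,
            mid - L * t - 2 * L * n,
            mid + L * t - 2 * L * n,
        ]
    )


def voronoi_2d(seeds, clip) -> VoronoiDiagram2D:
    """Classical Voronoi diagram of ``seeds`` clipped to a region.

    Each cell is built by intersecting the clip region with the half-planes
    toward its seed against every other seed; this handles collinear and
    otherwise degenerate seed sets without perturbation. Unbounded cells are
    therefore clipped exactly to the region (disk arenas are clipped to a
    >=128-segment polygonal approximation of the circle).
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if seeds.shape[0] < 2:
        raise ValueError("voronoi_2d needs at least 2 seeds")
    if seeds.shape[1] != 2:
        raise ValueError("voronoi_2d expects 2D seed positions")
    uniq = np.unique(seeds, axis=0)
    if uniq.shape[0] != seeds.shape[0]:
        raise ValueError("seeds must be distinct")

    region = _clip_polygon(clip)
    if region.is_empty or region.area <= 0:
        raise ValueError("degenerate clip region")
    minx, miny, maxx, maxy = region.bounds
    reach = 4.0 * max(maxx - minx, maxy - miny) + 4.0 * float(
        np.abs(seeds).max(initial=1.0)
    )

    polygons = []
    cells = []
    for i in range(seeds.shape[0]):
        cell = region
        for j in range(seeds.shape[0]):
            if i == j:
                continue
            cell = cell.intersection(_halfplane(seeds[i], seeds[j], reach))
        if cell.is_empty:
            polygons.append(np.empty((0, 2)))
            cells.append(cell)
            continue
        if cell.geom_type == "MultiPolygon":  # numerical sliver; keep largest
            cell = max(cell.geoms, key=lambda g: g.area)
        cells.append(cell)
        xy = np.asarray(cell.exterior.coords)[:-1]
        polygons.append(xy)

    adjacency = []
    eps = 1e-9 * reach  # absorbs float jitter between independently clipped cells
    min_edge = 1e-6 * reach
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            if cells[i].is_empty or cells[j].is_empty:
                continue
            shared = cells[j].boundary.intersection(cells[i].buffer(eps))
            if shared.length > min_edge:
                adjacency.append((i + 1, j + 1))
    return VoronoiDiagram2D(seeds=seeds, polygons=polygons, adjacency=adjacency)


def _argmin_lowest_label(d2: np.ndarray) -> np.ndarray:
    """Row-wise argmin + 1 with mathematically exact ties (cells genuinely
    equidistant from several seeds) resolved to the lowest label, robust to
    float round-off in how each distance was accumulated."""
    dmin = d2.min(axis=1)
    tol = 1e-9 * np.maximum(dmin, 1.0)
    return np.argmax(d2 <= (dmin + tol)[:, None], axis=1).astype(np.int32) + 1


def _label_grid_from_assign(assign, arena: Arena, extra_meta=None) -> LabelField:
    inside = arena.inside_mask()
    grid = np.where(inside, assign, 0).astype(np.int32)
    meta = {"arena": arena.to_dict()}
    if extra_meta:
        meta.update(extra_meta)
    return LabelField(
        grid=grid,
        resolution=arena.resolution,
        origin=arena.origin,
        raw_grid=grid.copy(),
        meta=meta,
    )


def _cell_points(arena: Arena) -> np.ndarray:
    grids = np.meshgrid(*arena.cell_centers(), indexing="ij")
    return np.stack([g.reshape(-1) for g in grids], axis=1)


def voronoi_label_grid(
    seeds, arena: Arena, method: str = "brute", chunk: int = 1 << 18
) -> LabelField:
    """Label every in-arena cell by its nearest seed (ties -> lowest label).

    ``method="brute"`` evaluates all seed distances per cell in chunks
    (exact, deterministic tie-breaking via argmin); ``method="kdtree"`` uses
    a KD-tree with near-tie cells re-resolved brute-force so the two routes
    agree exactly.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if seeds.shape[0] < 1:
        raise ValueError("need at least 1 seed")
    if seeds.shape[1] != arena.dim:
        raise ValueError("seed dimension does not match arena")
    pts = _cell_points(arena)
    n = pts.shape[0]
    assign = np.empty(n, dtype=np.int32)
    if method == "brute":
        for start in range(0, n, chunk):
            block = pts[start : start + chunk]
            d2 = ((block[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
            assign[start : start + chunk] = _argmin_lowest_label(d2)
    elif method == "kdtree":
        tree = cKDTree(seeds)
        k = min(2, seeds.shape[0])
        dist, idx = tree.query(pts, k=k)
        if k == 1:
            assign[:] = idx + 1
        else:
            assign[:] = idx[:, 0] + 1
            scale = max(float(np.abs(seeds).max()), float(np.abs(pts).max()), 1.0)
            near = dist[:, 1] - dist[:, 0] <= 1e-9 * scale
            if near.any():
                block = pts[near]
                d2 = ((block[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
                assign[near] = _argmin_lowest_label(d2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _label_grid_from_assign(
        assign.reshape(arena.grid_shape), arena, {"partition": "voronoi"}
    )


def weighted_arrival_label_grid(
    seeds, rates, arena: Arena, chunk: int = 1 << 18
) -> LabelField:
    """Multiplicatively weighted (Apollonius) partition.

    Each cell is labelled ``argmin_i |x - c_i| / v_i`` — the straight-line
    first-arrival seed. Boundaries between unequal-rate seeds are circular
    arcs (Apollonius circles); the slow seed's region is bounded. Ties go to
    the lowest label. With equal rates this reduces to the classical
    nearest-seed partition.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    rates = np.asarray(rates, dtype=float).reshape(-1)
    if np.any(rates <= 0):
        raise ValueError("all rates must be > 0")
    if rates.shape[0] != seeds.shape[0]:
        raise ValueError("one rate per seed required")
    if seeds.shape[1] != arena.dim:
        raise ValueError("seed dimension does not match arena")
    pts = _cell_points(arena)
    n = pts.shape[0]
    assign = np.empty(n, dtype=np.int32)
    for start in range(0, n, chunk):
        block = pts[start : start + chunk]
        d = np.sqrt(((block[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2))
        assign[start : start + chunk] = _argmin_lowest_label(d / rates[None, :])
    return _label_grid_from_assign(
        assign.reshape(arena.grid_shape),
        arena,
        {"partition": "weighted_arrival", "rates": rates.tolist()},
    )


@dataclass
class RegionHull:
    """Convex hull of one labelled 3D region."""

    label: int
    vertices: Optional[np.ndarray]  # (m, 3) world coordinates, mm
    simplices: Optional[np.ndarray]  # (f, 3) triangle indices into vertices
    hull_volume: float  # mm^3 (0 if degenerate)
    voxel_volume: float  # cell count * resolution^3, mm^3
    degenerate: bool


def region_hulls_3d(labels: LabelField) -> dict:
    """Convex hull of each labelled region of a 3D field (for rendering).

    Regions with fewer than 4 non-coplanar cells are flagged degenerate
    rather than failing. Hull volume always >= voxel-count volume for exact
    convex regions; the ratio is a convexity diagnostic.
    """
    if labels.dim != 3:
        raise ValueError("region_hulls_3d needs a 3D label field")
    from scipy import ndimage

    res = labels.resolution
    corner_offs = np.array(
        [[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)], dtype=np.int64
    )
    out = {}
    for k in labels.labels:
        mask = labels.grid == k
        voxel_vol = int(mask.sum()) * res**3
        # hull over cell *corners* of the region's boundary shell, so the
        # hull encloses whole cells (hull volume >= voxel volume when convex)
        shell = mask & ~ndimage.binary_erosion(mask)
        idx = np.argwhere(shell if shell.any() else mask)
        corners = np.unique(
            (idx[:, None, :] + corner_offs[None, :, :]).reshape(-1, 3), axis=0
        )
        pts = labels.origin + corners * res
        try:
            hull = ConvexHull(pts)
            remap = np.full(pts.shape[0], -1, dtype=np.int64)
            remap[hull.vertices] = np.arange(hull.vertices.size)
            out[int(k)] = RegionHull(
                label=int(k),
                vertices=pts[hull.vertices],
                simplices=remap[hull.simplices],
                hull_volume=float(hull.volume),
                voxel_volume=float(voxel_vol),
                degenerate=False,
            )
        except Exception:
            out[int(k)] = RegionHull(
                label=int(k),
                vertices=None,
                simplices=None,
                hull_volume=0.0,
                voxel_volume=float(voxel_vol),
                degenerate=True,
            )
    return out
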