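import numpy as np
import pytest
from shapely.geometry import Polygon

from vorogrow import (
    Arena,
    SeedConfig,
    SimParams,
    jaccard,
    make_arrangement,
    region_hulls_3d,
    simulate_rgm,
    voronoi_2d,
    voronoi_label_grid,
    weighted_arrival_label_grid,
)
from vorogrow.geometry import LabelField

SQUARE_CLIP = np.array([[-20.0, -20.0], [20.0, -20.0], [20.0, 20.0], [-20.0, 20.0]])


class TestVoronoi2D:
    def test_two_seeds_split_by_perpendicular_bisector(self):
        d = voronoi_2d([[-4.0, 0.0], [4.0, 0.0]], SQUARE_CLIP)
        areas = d.cell_areas()
        assert areas == pytest.approx([800.0, 800.0])
        # every cell-1 vertex has x <= 0, every cell-2 vertex x >= 0
        assert d.polygons[0][:, 0].max() <= 1e-9
        assert d.polygons[1][:, 0].min() >= -1e-9
        assert d.adjacency == [(1, 2)]

    def test_equilateral_triangle_edges_meet_at_circumcenter(self):
        seeds = make_arrangement("triangle", 10.0).positions  # centroid at 0
        d = voronoi_2d(seeds, SQUARE_CLIP)
        # circumcenter of an equilateral triangle = centroid = origin;
        # it must be a vertex of all three cells
        for poly in d.polygons:
            dists = np.linalg.norm(poly, axis=1)
            assert dists.min() < 1e-6
        assert sorted(d.adjacency) == [(1, 2), (1, 3), (2, 3)]

    def test_polygons_partition_the_clip_region(self):
        rng = np.random.default_rng(7)
        seeds = rng.uniform(-15, 15, size=(6, 2))
        d = voronoi_2d(seeds, SQUARE_CLIP)
        total = d.cell_areas().sum()
        assert total == pytest.approx(1600.0, rel=1e-9)
        for i, poly in enumerate(d.polygons):
            assert Polygon(poly).contains_properly is not None  # simple polygon
            assert Polygon(poly).contains(
                __import__("shapely.geometry", fromlist=["Point"]).Point(seeds[i])
            )

    def test_every_point_maps_to_nearest_seed_polygon(self):
        rng = np.random.default_rng(3)
        seeds = rng.uniform(-12, 12, size=(4, 2))
        d = voronoi_2d(seeds, SQUARE_CLIP)
        from matplotlib.path import Path

        xs = np.linspace(-19.9, 19.9, 200)
        probe = np.stack(np.meshgrid(xs, xs, indexing="ij"), axis=-1).reshape(-1, 2)
        nearest = np.argmin(
            ((probe[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        inside = np.full(probe.shape[0], -1)
        for i, poly in enumerate(d.polygons):
            hit = Path(poly).contains_points(probe, radius=1e-9)
            inside[hit] = i
        ok = inside == nearest
        assert ok.mean() >= 0.999  # boundary points may fall either way

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            voronoi_2d([[0.0, 0.0]], SQUARE_CLIP)
        with pytest.raises(ValueError):
            voronoi_2d([[0.0, 0.0], [0.0, 0.0]], SQUARE_CLIP)

    def test_collinear_seeds_supported(self):
        d = voronoi_2d([[-5.0, 0.0], [0.0, 0.0], [5.0, 0.0]], SQUARE_CLIP)
        assert d.cell_areas().sum() == pytest.approx(1600.0, rel=1e-9)
        assert sorted(d.adjacency) == [(1, 2), (2, 3)]


class TestLabelGrids:
    def test_single_seed_claims_everything(self):
        arena = Arena(2, "disk", 10.0, 0.25)
        lf = voronoi_label_grid([[2.0, -1.0]], arena)
        assert np.array_equal(lf.grid > 0, arena.inside_mask())

    def test_accelerated_route_matches_brute_force_exactly(self):
        arena = Arena(3, "box", (16.0, 16.0, 16.0), 0.5)
        seeds = make_arrangement("cube", 8.0).positions  # symmetric: many ties
        brute = voronoi_label_grid(seeds, arena, method="brute")
        fast = voronoi_label_grid(seeds, arena, method="kdtree")
        assert np.array_equal(brute.grid, fast.grid)

    def test_grid_agrees_with_polygon_point_location(self):
        rng = np.random.default_rng(11)
        seeds = rng.uniform(-12, 12, size=(5, 2))
        arena = Arena(2, "rectangle", (40.0, 40.0), 0.25)
        lf = voronoi_label_grid(seeds, arena)
        d = voronoi_2d(seeds, SQUARE_CLIP)
        from matplotlib.path import Path

        pts = np.stack(
            np.meshgrid(*arena.cell_centers(), indexing="ij"), axis=-1
        ).reshape(-1, 2)
        poly_label = np.zeros(pts.shape[0], dtype=int)
        for i, poly in enumerate(d.polygons):
            hit = Path(poly).contains_points(pts, radius=1e-9)
            poly_label[hit] = i + 1
        located = poly_label > 0
        agree = (poly_label[located] == lf.grid.reshape(-1)[located]).mean()
        assert agree >= 0.995

    def test_scaling_invariance(self):
        rng = np.random.default_rng(5)
        seeds = rng.uniform(-8, 8, size=(6, 2))
        s = 3.7
        a1 = Arena(2, "rectangle", (24.0, 24.0), 0.5)
        a2 = Arena(2, "rectangle", (24.0 * s, 24.0 * s), 0.5 * s)
        l1 = voronoi_label_grid(seeds, a1)
        l2 = voronoi_label_grid(seeds * s, a2)
        assert np.array_equal(l1.grid, l2.grid)

    def test_cube_seeds_central_section_matches_2d_square(self):
        res = 0.5
        arena3 = Arena(3, "box", (24.0,) * 3, res)
        arena2 = Arena(2, "rectangle", (24.0,) * 2, res)
        cube = make_arrangement("cube", 12.0)
        lf3 = voronoi_label_grid(cube.positions, arena3)
        # seeds with z = +6: cube labels 2, 4, 6, 8 -> square labels 1..4
        pos2 = cube.positions[[1, 3, 5, 7]][:, :2]
        lf2 = voronoi_label_grid(pos2, arena2)
        k = int(np.floor((6.0 + 12.0) / res))
        section = lf3.grid[:, :, k]
        mapped = np.zeros_like(section)
        for m, (a, b) in enumerate(zip((2, 4, 6, 8), (1, 2, 3, 4))):
            mapped[section == a] = b
        agree = (mapped == lf2.grid).mean()
        assert agree >= 0.995


class TestWeightedPartition:
    def test_equal_rates_reduce_to_unweighted(self):
        rng = np.random.default_rng(2)
        seeds = rng.uniform(-8, 8, size=(5, 2))
        arena = Arena(2, "disk", 12.0, 0.25)
        w = weighted_arrival_label_grid(seeds, np.full(5, 1.7), arena)
        u = voronoi_label_grid(seeds, arena)
        assert np.array_equal(w.grid, u.grid)

    def test_two_seed_apollonius_circle(self):
        # v1/v2 = 2, seeds at (-3, 0), (3, 0): the slow region is the disk
        # |x - c1| = 2 |x - c2|, i.e. centre (5, 0), radius 4
        arena = Arena(2, "rectangle", (40.0, 40.0), 0.1)
        lf = weighted_arrival_label_grid(
            [[-3.0, 0.0], [3.0, 0.0]], [2.0, 1.0], arena
        )
        x, y = arena.coordinate_grids()
        inside_circle = (x - 5.0) ** 2 + y**2 < 16.0
        assert jaccard(lf.grid == 2, inside_circle) > 0.99
        # boundary crosses the seed segment 4 mm from the fast seed
        row = lf.grid[:, arena.world_to_index([[0.0, 0.0]])[0][1]]
        xc = arena.cell_centers()[0]
        first_slow = xc[np.argmax(row == 2)]
        assert first_slow == pytest.approx(1.0, abs=0.15)

    def test_slow_region_is_bounded(self):
        arena = Arena(2, "rectangle", (60.0, 60.0), 0.25)
        lf = weighted_arrival_label_grid(
            [[-3.0, 0.0], [3.0, 0.0]], [2.0, 1.0], arena
        )
        x, y = arena.coordinate_grids()
        r = np.sqrt(x**2 + y**2)
        ring = (r > 25.0) & (r < 28.0)
        assert set(np.unique(lf.grid[ring])) == {1}

    def test_nonpositive_rate_rejected(self):
        arena = Arena(2, "disk", 10.0, 0.5)
        with pytest.raises(ValueError, match="rates"):
            weighted_arrival_label_grid([[0.0, 0.0], [1.0, 1.0]], [1.0, 0.0], arena)


class TestRegionHulls:
    def _field(self, grid, res=1.0):
        return LabelField(
            grid=grid, resolution=res, origin=-0.5 * np.asarray(grid.shape) * res
        )

    def test_cube_region_hull_volume(self):
        grid = np.zeros((32, 32, 32), dtype=np.int32)
        grid[4:28, 4:28, 4:28] = 1
        hulls = region_hulls_3d(self._field(grid))
        h = hulls[1]
        assert not h.degenerate
        assert h.hull_volume == pytest.approx(h.voxel_volume, rel=0.05)
        assert h.hull_volume >= h.voxel_volume - 1e-9

    def test_voronoi_regions_are_convex(self):
        arena = Arena(3, "box", (16.0,) * 3, 0.125)
        rng = np.random.default_rng(4)
        seeds = rng.uniform(-6, 6, size=(4, 3))
        lf = voronoi_label_grid(seeds, arena)
        for h in region_hulls_3d(lf).values():
            assert not h.degenerate
            assert h.hull_volume >= h.voxel_volume - 1e-9
            assert h.hull_volume / h.voxel_volume <= 1.05

    def test_thin_region_hull_is_its_bounding_box(self):
        # hulls are built over cell corners, so even a single line of cells
        # has a well-defined box hull rather than a degenerate one
        grid = np.zeros((16, 16, 16), dtype=np.int32)
        grid[2, 2, 2:5] = 1
        grid[8:12, 8:12, 8:12] = 2
        hulls = region_hulls_3d(self._field(grid))
        assert not hulls[1].degenerate
        assert hulls[1].hull_volume == pytest.approx(hulls[1].voxel_volume)
        assert hulls[2].hull_volume == pytest.approx(hulls[2].voxel_volume)


class TestRgmVoronoiEquivalence:
    def test_equal_rate_rgm_matches_nearest_seed_partition(self):
        # the central identity, at reduced scale: collision boundaries of
        # equal-rate radial growth are the Voronoi tessellation of the seeds
        arena = Arena(2, "disk", 30.0, 0.2)
        config = make_arrangement("square", 25.0)
        labels, _ = simulate_rgm(config, arena, SimParams(t_max=80.0))
        oracle = voronoi_label_grid(config.positions, arena)
        claimed = labels.grid > 0
        for k in config.labels:
            jk = jaccard((labels.grid == k) & claimed, (oracle.grid == k) & claimed)
            assert jk >= 0.99
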