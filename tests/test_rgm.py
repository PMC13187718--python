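import numpy as np
import pytest

from vorogrow import (
    Arena,
    SeedConfig,
    SimParams,
    colony_mask,
    simulate_rgm,
    snapshot,
)
from conftest import hausdorff_cells


def _adjacent_diff_pairs(g):
    """Boolean mask of cells face-adjacent to a different positive label."""
    adj = np.zeros_like(g, dtype=bool)
    for ax in (0, 1):
        a = np.swapaxes(g, 0, ax)
        pair = (a[:-1] > 0) & (a[1:] > 0) & (a[:-1] != a[1:])
        m = np.zeros_like(a, dtype=bool)
        m[:-1] |= pair
        m[1:] |= pair
        adj |= np.swapaxes(m, 0, ax)
    return adj


def _disk_oracle(arena, center, radius_mm):
    coords = arena.coordinate_grids()
    r2 = sum((c - cc) ** 2 for c, cc in zip(coords, center))
    return r2 <= radius_mm**2


class TestUninhibitedGrowth:
    def test_single_colony_is_a_disk(self, disk_arena, single_colony_run):
        config, labels, arrivals = single_colony_run
        claimed = labels.grid == 1
        seed_center = disk_arena.index_to_world(
            disk_arena.world_to_index(config.positions)
        )[0]
        oracle = _disk_oracle(disk_arena, seed_center, 5.0)
        assert hausdorff_cells(claimed, oracle) <= 1.5

    def test_boundary_arrivals_near_t_max(self, disk_arena, single_colony_run):
        _, labels, arrivals = single_colony_run
        claimed = labels.grid == 1
        from scipy import ndimage

        boundary = claimed & ~ndimage.binary_erosion(claimed)
        assert arrivals.grid[boundary].min() > 4.5
        assert arrivals.grid[boundary].max() <= 5.0

    def test_arrival_at_least_distance_over_rate(self, disk_arena, single_colony_run):
        config, labels, arrivals = single_colony_run
        claimed = labels.grid == 1
        seed_center = disk_arena.index_to_world(
            disk_arena.world_to_index(config.positions)
        )[0]
        coords = disk_arena.coordinate_grids()
        dist = np.sqrt(sum((c - cc) ** 2 for c, cc in zip(coords, seed_center)))
        slack = disk_arena.resolution
        assert np.all(arrivals.grid[claimed] >= dist[claimed] - slack)


class TestCollision:
    def test_equal_rates_interface_on_perpendicular_bisector(self, disk_arena):
        config = SeedConfig(positions=[[-3.0, 0.0], [3.0, 0.0]], rates=[1.0, 1.0])
        labels, _ = simulate_rgm(config, disk_arena, SimParams(t_max=30.0))
        g = labels.grid
        # cells of label 1 adjacent (face) to label 2: must lie within 1.5
        # cells of the bisector x = 0 (up to the half-cell seed snap)
        adj = _adjacent_diff_pairs(g)
        x = disk_arena.coordinate_grids()[0]
        xs = np.broadcast_to(x, g.shape)[adj]
        assert np.abs(xs).max() <= 1.5 * disk_arena.resolution + disk_arena.resolution

    def test_unequal_rates_first_contact_time_and_place(self):
        # d = 6 mm, v1:v2 = 2:1 -> contact at t* = 6/3 = 2 h, 4 mm from the
        # fast seed along the seed segment
        arena = Arena(2, "disk", 12.0, 0.05)
        config = SeedConfig(positions=[[-3.0, 0.0], [3.0, 0.0]], rates=[2.0, 1.0])
        labels, arrivals = simulate_rgm(config, arena, SimParams(t_max=10.0))
        g, A = labels.grid, arrivals.grid
        best_t, best_idx = np.inf, None
        for ax in (0, 1):
            ga = np.swapaxes(g, 0, ax)
            Aa = np.swapaxes(A, 0, ax)
            pair = (ga[:-1] > 0) & (ga[1:] > 0) & (ga[:-1] != ga[1:])
            t = np.where(pair, np.maximum(Aa[:-1], Aa[1:]), np.inf)
            i = np.unravel_index(np.argmin(t), t.shape)
            if t[i] < best_t:
                best_t = t[i]
                best_idx = (i[0], i[1]) if ax == 0 else (i[1], i[0])
        step = arena.resolution * np.sqrt(5) / 1.0  # largest stencil step / v2
        assert best_t == pytest.approx(2.0, abs=step)
        contact = arena.index_to_world(np.array(best_idx))[0]
        assert np.linalg.norm(contact - [-3.0, 0.0]) == pytest.approx(
            4.0, abs=1.5 * arena.resolution + arena.resolution
        )

    def test_fast_colony_engulfs_slow_one(self):
        arena = Arena(2, "disk", 16.0, 0.1)
        config = SeedConfig(positions=[[-3.0, 0.0], [3.0, 0.0]], rates=[2.0, 1.0])
        labels, _ = simulate_rgm(config, arena, SimParams(t_max=40.0))
        g = labels.grid
        x, y = arena.coordinate_grids()
        r = np.sqrt(x**2 + y**2)
        ring = (r > 13.0) & (r < 13.5)
        assert set(np.unique(g[ring])) == {1}  # fast colony surrounds the slow
        slow = g == 2
        assert slow.any() and not (slow & (r > 13.0)).any()

    def test_claimed_cells_never_relabelled(self, coarse_disk_arena):
        config = SeedConfig(
            positions=[[-10.0, 0.0], [10.0, 0.0], [0.0, 12.0]], rates=[1.0, 1.3, 0.8]
        )
        labels, arrivals = simulate_rgm(config, coarse_disk_arena, SimParams(t_max=40.0))
        prev = None
        for t in (2.0, 5.0, 10.0, 20.0, 40.0):
            cur = snapshot(labels, arrivals, t).grid
            if prev is not None:
                had = prev > 0
                assert np.array_equal(prev[had], cur[had])
            prev = cur


class TestSnapshot:
    def test_snapshot_at_zero_is_seeds_only(self, coarse_disk_arena):
        config = SeedConfig(positions=[[-5.0, 0.0], [5.0, 0.0]], rates=[1.0, 1.0])
        labels, arrivals = simulate_rgm(config, coarse_disk_arena, SimParams(t_max=10.0))
        snap = snapshot(labels, arrivals, 0.0)
        assert np.count_nonzero(snap.grid) == 2
        assert sorted(np.unique(snap.grid[snap.grid > 0])) == [1, 2]

    def test_snapshot_at_t_max_is_identity(self, coarse_disk_arena):
        config = SeedConfig(positions=[[-5.0, 0.0], [5.0, 0.0]], rates=[1.0, 1.0])
        labels, arrivals = simulate_rgm(
            config, coarse_disk_arena, SimParams(t_max=10.0, dmin=0.8)
        )
        snap = snapshot(labels, arrivals, 10.0)
        assert np.array_equal(snap.grid, labels.grid)

    def test_before_contact_two_disjoint_disks_without_interface(self, coarse_disk_arena):
        d = 10.0
        config = SeedConfig(positions=[[-d / 2, 0.0], [d / 2, 0.0]], rates=[1.0, 1.0])
        labels, arrivals = simulate_rgm(
            config, coarse_disk_arena, SimParams(t_max=20.0, dmin=0.8)
        )
        t_contact = d / 2.0
        snap = snapshot(labels, arrivals, 0.6 * t_contact)
        assert not (snap.grid == -1).any()
        from scipy import ndimage

        n_comp = ndimage.label(snap.grid > 0)[1]
        assert n_comp == 2

    def test_snapshot_outside_range_rejected(self, single_colony_run):
        _, labels, arrivals = single_colony_run
        with pytest.raises(ValueError):
            snapshot(labels, arrivals, 7.0)
        with pytest.raises(ValueError):
            snapshot(labels, arrivals, -1.0)


class TestPartitionAndMasks:
    def test_masks_partition_the_arena(self, coarse_disk_arena):
        config = SeedConfig(
            positions=[[-8.0, -5.0], [8.0, -5.0], [0.0, 9.0]], rates=[1.0, 1.0, 1.0]
        )
        labels, _ = simulate_rgm(
            config, coarse_disk_arena, SimParams(t_max=60.0, dmin=0.6)
        )
        union = np.zeros_like(labels.grid, dtype=bool)
        for k in (1, 2, 3):
            m = colony_mask(labels, k)
            assert not (union & m).any()  # pairwise disjoint
            union |= m
        union |= labels.grid == -1
        union |= labels.grid == 0
        assert union.all()
        # codes are only {-1, 0, 1..K}
        assert set(np.unique(labels.grid)) <= {-1, 0, 1, 2, 3}

    def test_unknown_label_rejected(self, single_colony_run):
        _, labels, _ = single_colony_run
        with pytest.raises(ValueError, match="unknown label"):
            colony_mask(labels, 2)

    def test_disk_area_error_shrinks_with_stencil_order(self):
        # the claimed-area deficit is set by the stencil metric's anisotropy
        # (fractional, so nearly resolution-independent); it shrinks as the
        # stencil widens
        errs = []
        for order in (1, 2, 3):
            arena = Arena(2, "disk", 10.0, 0.1)
            config = SeedConfig(positions=[[0.0, 0.0]], rates=[1.0])
            labels, _ = simulate_rgm(
                config, arena, SimParams(t_max=6.0, stencil_order=order)
            )
            area = colony_mask(labels, 1).sum() * 0.1**2
            errs.append(abs(area / (np.pi * 6.0**2) - 1.0))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.02


class TestWallAndTies:
    def test_no_claimed_cell_outside_the_arena(self, disk_arena):
        config = SeedConfig(positions=[[15.0, 0.0]], rates=[1.0])
        labels, _ = simulate_rgm(config, disk_arena, SimParams(t_max=30.0))
        outside = ~disk_arena.inside_mask()
        assert not (labels.grid[outside] != 0).any()

    def test_colony_conforms_to_the_wall(self, disk_arena):
        # a colony given time to fill everything claims every in-dish cell,
        # i.e. its boundary becomes the dish wall
        config = SeedConfig(positions=[[15.0, 0.0]], rates=[1.0])
        labels, _ = simulate_rgm(config, disk_arena, SimParams(t_max=60.0))
        inside = disk_arena.inside_mask()
        assert np.array_equal(labels.grid == 1, inside)

    def test_equidistant_tie_goes_to_lowest_label(self):
        arena = Arena(2, "rectangle", (20.0, 20.0), 1.0)
        # seeds in cells 4 and 14 of row 10: cell 9 is exactly 5 steps from both
        config = SeedConfig(positions=[[-5.5, 0.5], [4.5, 0.5]], rates=[1.0, 1.0])
        labels, _ = simulate_rgm(config, arena, SimParams(t_max=30.0))
        assert labels.grid[9, 10] == 1

    def test_invalid_inputs_rejected(self, disk_arena):
        with pytest.raises(ValueError):
            SimParams(t_max=-1.0)
        bad = SeedConfig(positions=[[25.0, 0.0]], rates=[1.0])
        with pytest.raises(ValueError, match="seed 0"):
            simulate_rgm(bad, disk_arena, SimParams(t_max=1.0))


class TestThreeDimensional:
    def test_coplanar_seeds_reproduce_the_2d_run(self):
        res = 0.5
        arena3 = Arena(3, "box", (24.0, 24.0, 24.0), res)
        arena2 = Arena(2, "rectangle", (24.0, 24.0), res)
        # 4 seeds in the z = +0.25 cell plane (cell centres at 0.25 + k*0.5)
        pos2 = np.array([[-6.0, -6.0], [-6.0, 6.0], [6.0, -6.0], [6.0, 6.0]])
        pos3 = np.hstack([pos2, np.full((4, 1), 0.25)])
        lab3, _ = simulate_rgm(
            SeedConfig(pos3, np.ones(4)), arena3, SimParams(t_max=9.0)
        )
        lab2, _ = simulate_rgm(
            SeedConfig(pos2, np.ones(4)), arena2, SimParams(t_max=9.0)
        )
        k = int(np.floor((0.25 + 12.0) / res))
        section = lab3.grid[:, :, k]
        both = (section > 0) & (lab2.grid > 0)
        assert both.sum() > 1000
        agreement = (section[both] == lab2.grid[both]).mean()
        assert agreement >= 0.99

    def test_sphere_wall_arrest(self):
        arena = Arena(3, "sphere", 8.0, 0.5)
        config = SeedConfig(positions=[[0.0, 0.0, 0.0]], rates=[1.0])
        labels, _ = simulate_rgm(config, arena, SimParams(t_max=30.0))
        assert np.array_equal(labels.grid == 1, arena.inside_mask())
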