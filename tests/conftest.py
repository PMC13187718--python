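import numpy as np
import pytest

from vorogrow import Arena, SeedConfig, SimParams, simulate_rgm


@pytest.fixture(scope="session")
def disk_arena():
    """20 mm radius dish at 0.1 mm/cell (200 cells across the radius)."""
    return Arena(dim=2, shape="disk", extent=20.0, resolution=0.1)


@pytest.fixture(scope="session")
def coarse_disk_arena():
    """30 mm radius dish at 0.2 mm/cell — cheap multi-colony runs."""
    return Arena(dim=2, shape="disk", extent=30.0, resolution=0.2)


@pytest.fixture(scope="session")
def single_colony_run(disk_arena):
    """One colony at the centre, v = 1 mm/h, run to 5 h."""
    config = SeedConfig(positions=[[0.0, 0.0]], rates=[1.0])
    labels, arrivals = simulate_rgm(config, disk_arena, SimParams(t_max=5.0))
    return config, labels, arrivals


def hausdorff_cells(a: np.ndarray, b: np.ndarray) -> float:
    """Hausdorff distance between two cell sets, in cell units."""
    from scipy import ndimage

    if not a.any() or not b.any():
        return np.inf
    d_to_b = ndimage.distance_transform_edt(~b)
    d_to_a = ndimage.distance_transform_edt(~a)
    return max(float(d_to_b[a].max()), float(d_to_a[b].max()))
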