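import numpy as np
import pandas as pd
import pytest

from ernconn.netdef_atlas import FEATURE_KEYS, LabelVolume, NetworkDefinition
from ernconn.synthetic_data import SimulationConfig, simulate_cohort, simulate_features


@pytest.fixture
def toy_volume():
    """6x6x6 volume split into two parcels along the first axis, 1 mm voxels."""
    grid = np.ones((6, 6, 6), dtype=np.int32)
    grid[3:, :, :] = 2
    affine = np.eye(4)
    return LabelVolume(grid=grid, affine=affine)


@pytest.fixture
def toy_definition():
    rows = [
        {"network": "ERN1", "label": "a", "x": 1.0, "y": 2.0, "z": 2.0},
        {"network": "ERN2", "label": "b", "x": 4.0, "y": 2.0, "z": 2.0},
        {"network": "ERN3", "label": "c", "x": 1.0, "y": 4.0, "z": 4.0},
        {"network": "ERN4", "label": "d", "x": 4.0, "y": 4.0, "z": 4.0},
    ]
    return NetworkDefinition(table=pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_cohort():
    """800-family cohort with features, no planted effects, default batch effects."""
    cfg = SimulationConfig(n_families=800, seed=11)
    return simulate_features(simulate_cohort(cfg), cfg)


def brute_force_overlap(nets, vol, radius_mm):
    """Exhaustive per-voxel oracle for peak-mode overlap counting.

    Walks every voxel of the volume for every network, testing Euclidean
    distance from the voxel center to each ROI peak; a voxel is counted for
    a network if it is within radius of ANY of its peaks (union semantics).
    """
    counts = {}
    shape = vol.grid.shape
    for net in nets.networks:
        peaks = nets.table[nets.table["network"] == net][["x", "y", "z"]].to_numpy(float)
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    mm = vol.voxel_to_mm(np.array([i, j, k]))[0]
                    hit = any(
                        np.sum((mm - p) ** 2) <= radius_mm**2 + 1e-9 for p in peaks
                    )
                    if hit:
                        pid = int(vol.grid[i, j, k])
                        if pid > 0:
                            counts[(net, pid)] = counts.get((net, pid), 0) + 1
    return counts


def overlap_as_dict(table):
    return {
        (r.network_id, int(r.parcel_id)): int(r.voxel_count)
        for r in table.table.itertuples()
    }
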