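import numpy as np
import pytest

import muellertomo as mt
from muellertomo.phantoms import SpiralPhantomSpec, make_dataset, make_spiral
from muellertomo.recon import ReconConfig, proximity_metrics, reconstruct


@pytest.fixture(scope="session")
def geom6():
    """Small 6-projection dual-axis geometry for gradient/forward tests."""
    angles = np.deg2rad(
        [[0, 0], [45, 6.8], [90, -6.8], [150, 0], [222, 6.8], [300, 0]]
    )
    return mt.AcquisitionGeometry(angles=angles)


@pytest.fixture(scope="session")
def full_geom():
    """Default 78-projection scan (26 rotations x 3 tilts)."""
    return mt.AcquisitionGeometry()


@pytest.fixture(scope="session")
def reduced_spiral():
    """Reduced spiral phantom and its noisy 78-projection dataset."""
    spec = SpiralPhantomSpec(shape=(9, 15, 9), pitch_voxels=13, tube_radius=2)
    truth = make_spiral(spec)
    geometry = mt.AcquisitionGeometry()
    measured, _ = make_dataset(truth, geometry, noise=True, seed=7)
    return truth, measured, geometry


@pytest.fixture(scope="session")
def spiral_recoveries(reduced_spiral):
    """Four independent random-init reconstructions of the reduced spiral.

    Expensive (minutes); shared by the recovery and seed-robustness checks.
    Returns a list of (final eps_I, orientation proximity, index error).
    """
    truth, measured, geometry = reduced_spiral
    results = []
    for seed in range(4):
        config = ReconConfig(seed=seed)
        state = reconstruct(measured, geometry, config, shape=truth.shape)
        prox, ierr = proximity_metrics(state.grid, truth)
        results.append((float(state.traces["eps_I"][-1]), prox, ierr))
    return results
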