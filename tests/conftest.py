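"""Shared fixtures: small deterministic cohorts and volumes."""

from __future__ import annotations

import numpy as np
import pytest

from uafc.io import Volume4D
from uafc.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Desk-scale config: enough structure for structural tests, fast."""
    return SimConfig(
        n_pd=6, n_hc=6, grid_shape=(12, 14, 12), n_volumes=80, seed=11
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture()
def random_volume():
    """Small random 4D volume with a nonzero-variance mask."""
    rng = np.random.default_rng(7)
    data = rng.standard_normal((6, 7, 5, 40)).astype(np.float32)
    mask = np.ones((6, 7, 5), dtype=bool)
    mask[0, 0, 0] = False
    data[~mask] = 0.0
    return Volume4D(
        data=data,
        affine=np.diag([3.0, 3.0, 3.0, 1.0]),
        voxel_size_mm=(3.0, 3.0, 3.0),
        tr_s=2.0,
        mask=mask,
    )
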