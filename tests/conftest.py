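import numpy as np
import pytest

import callusmon as cm


@pytest.fixture(scope="session")
def truth():
    """Single default ground-truth animal (seed 42, no jitter)."""
    return cm.default_cohort(1, seed=42)[0]


@pytest.fixture(scope="session")
def noiseless_analysis(truth):
    """Full mechanical pipeline on a zero-noise simulated animal."""
    traces = cm.simulate_gait_series(truth, range(7, 91), noise_sigma=0.0)
    return cm.analyze_gait_traces(traces, truth.stiffness, truth.body_weight)


@pytest.fixture(scope="session")
def coarse_volume(truth):
    """Small noiseless treated volume at coarse spacing for fast CT tests."""
    return cm.simulate_ct_volume(truth, 65, spacing=0.6, hu_sigma=0.0, bmd_voxel_sigma=0.0)
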