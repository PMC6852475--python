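import warnings

import numpy as np
import pytest

from srcconn import (SimulationConfig, PlantedEffect, simulate_sources,
                     make_leadfield, band_by_name)

THETA = band_by_name("theta")
ALPHA = band_by_name("alpha")


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* (envelope|epochs)")
        warnings.filterwarnings("ignore", message="fewer than")
        warnings.filterwarnings("ignore", message="only .* valid samples")
        yield


@pytest.fixture(scope="session")
def small_null_dataset():
    """Eight subjects, 12 ROIs, theta+alpha, no planted effects."""
    cfg = SimulationConfig(n_per_group=4, n_rois=12, n_sensors=24, fs=128.0,
                           duration=120.0, n_blocks=1,
                           bands=(THETA, ALPHA), seed=42)
    subs, truth = simulate_sources(cfg)
    return cfg, subs, truth


@pytest.fixture(scope="session")
def coupled_pair():
    """Long two-ROI recording with a planted 0.6 envelope correlation."""
    eff = PlantedEffect("envelope_correlation", THETA, (0, 1), 0.0,
                        baseline=0.6)
    cfg = SimulationConfig(n_per_group=2, n_rois=2, n_sensors=8, fs=128.0,
                           duration=600.0, n_blocks=1, bands=(THETA,),
                           planted_effects=(eff,), seed=7)
    subs, truth = simulate_sources(cfg)
    return subs, truth


@pytest.fixture(scope="session")
def toy_leadfield():
    return make_leadfield(32, 12, seed=3)
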