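import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("repro")

from irsyn.pipeline import RunConfig, run_pipeline
from irsyn.synthetic_data import default_cohort_config, default_grid


@pytest.fixture
def grid():
    return default_grid()


@pytest.fixture
def gaussian_spectrum(grid):
    from irsyn.spectra_io import Spectrum

    a = np.exp(-4 * np.log(2) * ((grid - 1650.0) / 40.0) ** 2)
    return Spectrum(grid.copy(), a)


@pytest.fixture(scope="session")
def noiseless_config():
    """Deterministic forward model: no noise, no jitter, no vapor drift."""
    cfg = default_cohort_config(seed=7, n_positive=10, n_control=10)
    return dataclasses.replace(
        cfg, noise_sd=0.0, center_jitter_sd=0.0, vapor_fluctuation=0.0,
        amplitude_log_sd=0.0, baseline_slope_range=(0.0, 0.0),
        baseline_offset_range=(0.0, 0.0), vapor_amplitude_range=(0.0, 0.0),
    )


@pytest.fixture(scope="session")
def default_report():
    """One full study-scale pipeline run shared across tests."""
    return run_pipeline(RunConfig.default(seed=123))
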