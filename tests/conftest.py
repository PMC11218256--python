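import numpy as np
import pytest

import fbtmsi as fb


@pytest.fixture
def rng():
    return np.random.default_rng(20240702)


@pytest.fixture(scope="session")
def bank40():
    """Default 40-target bank at 250 Hz, 1 s windows, N_h = 4."""
    return fb.build_reference_bank(fb.default_frequency_grid(), 4, 250, 250.0)


@pytest.fixture(scope="session")
def small_bank():
    """Five-target bank for cheap scans."""
    return fb.build_reference_bank([9.0, 10.0, 11.0, 12.0, 13.0], 3, 250, 250.0)


@pytest.fixture(scope="session")
def noiseless_epoch():
    cfg = fb.SimConfig(noise_sigma=0.0, duration=1.5, seed=7)
    return fb.simulate_epoch(12.6, cfg, seed=7), cfg
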