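import numpy as np
import pytest

from vigsa import RunConfig, simulate_design


@pytest.fixture(scope="session")
def prosail_blocks():
    """Shared PROSAIL simulation at the standard 2000 samples per variable
    (20,000 model runs); reused by every test that needs real spectra."""
    cfg = RunConfig(model="PROSAIL", N=2000, scheme="uniform-sobol")
    return cfg, simulate_design(cfg)


@pytest.fixture(scope="session")
def proinform_blocks():
    """Shared forest-model simulation at 2000 samples per variable
    (28,000 model runs)."""
    cfg = RunConfig(model="PROINFORM", N=2000, scheme="uniform-sobol")
    return cfg, simulate_design(cfg)


@pytest.fixture(scope="session")
def leaf_rt():
    """One representative leaf reflectance/transmittance pair."""
    from vigsa.rtm import LeafParams, prospect4, synthetic_coefficients

    coeffs = synthetic_coefficients()
    return prospect4(LeafParams(1.5, 40.0, 0.01, 0.009), coeffs)


@pytest.fixture(scope="session")
def soil():
    from vigsa.rtm import synthetic_soil_spectrum

    return synthetic_soil_spectrum()
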