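import numpy as np
import pytest

from dibkit import permeability, synthetic_data as sd


@pytest.fixture(scope="session")
def control_conditions():
    """Pure-water droplet 1 against a 0.2 osmol/L droplet 2."""
    return permeability.OsmoticConditions(osmolality_1=0.0, osmolality_2=0.2)


@pytest.fixture(scope="session")
def control_trajectory():
    """Noiseless 60 s trajectory at the pure-DOPC control permeability."""
    cfg = sd.DIBSimConfig(true_Pf=74.0, duration=60.0, sample_interval=1.0)
    return sd.simulate_dib_trajectory(cfg)


@pytest.fixture(scope="session")
def control_bands():
    """C-H band amplitudes tuned to the control packing ratios (0.84, 0.90)."""
    return sd.calibrate_ch_band_amplitudes(0.84, 0.90)


@pytest.fixture(scope="session")
def gen_bands():
    """C-H band amplitudes tuned to the 10:1 GEN ratios (0.88, 0.96)."""
    return sd.calibrate_ch_band_amplitudes(0.88, 0.96)


@pytest.fixture(scope="session")
def control_thermogram():
    """Noiseless control endotherm on a linear instrument baseline."""
    cfg = sd.DSCSimConfig(
        Tm_true=-17.08,
        dH_true=8.76,
        dT_half_true=2.04,
        baseline_slope=0.01,
        baseline_intercept=0.05,
    )
    return sd.simulate_thermogram(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
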