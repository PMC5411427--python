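import numpy as np
import pytest

from vvlung.lung_sim import MechParams, VentSettings, simulate_breath


@pytest.fixture
def default_settings():
    return VentSettings()  # 6 mL/kg, 0.526 kg, 40/min, PEEP 2, FiO2 0.4, 1:2, 200 Hz


@pytest.fixture
def nonlinear_params():
    return MechParams(r_rs=0.15, e1_rs=2.0, e2_rs=0.15, p0=2.0)


@pytest.fixture
def linear_params():
    return MechParams(r_rs=0.1, e1_rs=2.5, e2_rs=0.0, p0=2.0)


@pytest.fixture
def noiseless_cycle(nonlinear_params, default_settings):
    return simulate_breath(nonlinear_params, default_settings, 6.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
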