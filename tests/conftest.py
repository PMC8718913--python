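import numpy as np
import pytest
from hypothesis import settings

from cpetvt import GasExchangeSeries, ProtocolSpec, SimParams, simulate_test

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


def make_series(vo2, vco2, ve, t0=10.0, **extra):
    """Small series on the canonical 10-s grid from explicit channel values."""
    vo2 = np.asarray(vo2, dtype=float)
    time = t0 + 10.0 * np.arange(len(vo2))
    return GasExchangeSeries(time=time, vo2=vo2, vco2=np.asarray(vco2, float),
                             ve=np.asarray(ve, float), **extra)


@pytest.fixture(scope="session")
def nominal():
    return ProtocolSpec.nominal()


@pytest.fixture(scope="session")
def sim_default():
    """One simulated test at default parameters, seed 1, with its truth."""
    params = SimParams(seed=1)
    series, truth = simulate_test(params)
    return params, series, truth


@pytest.fixture(scope="session")
def ramp_series(nominal):
    """A 600-s noise-free ramp-like series (60 samples) for data-handling tests."""
    time = 10.0 * np.arange(1, 61)
    vo2 = 0.5 + 0.004 * time
    vco2 = 0.85 * vo2
    ve = 27.0 * vco2
    return GasExchangeSeries(time=time, vo2=vo2, vco2=vco2, ve=ve)
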