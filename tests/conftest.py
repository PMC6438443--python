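import numpy as np
import pytest

from moranwave import SpatioTemporalSeries, WaveletConfig, standardize, two_driver_scenario

LONG_BAND = (4.0, 30.0)


@pytest.fixture(scope="session")
def cfg() -> WaveletConfig:
    return WaveletConfig()


@pytest.fixture(scope="session")
def scenario():
    """One reference realisation of the two-driver construction (phi = 0)."""
    return two_driver_scenario(0.0, seed=12345)


@pytest.fixture(scope="session")
def scenario_std(scenario):
    """Standardized panels of the reference realisation."""
    return {name: standardize(p) for name, p in scenario.panels.items()}


def noise_panel(n: int, t: int, seed: int) -> SpatioTemporalSeries:
    rng = np.random.default_rng(seed)
    return SpatioTemporalSeries(
        rng.standard_normal((n, t)), tuple(f"l{i}" for i in range(n)), np.arange(t)
    )
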