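import pytest

from ifnfate import SwitchingRates
from ifnfate.imaging import SyntheticImageConfig, generate_image_set


@pytest.fixture(scope="session")
def fitted_rates() -> SwitchingRates:
    """The fitted off-rate with the rounded steady-state fraction f=2%."""
    return SwitchingRates.from_f(0.29, 0.02)


@pytest.fixture(scope="session")
def baseline_rates() -> SwitchingRates:
    """The fitted off-rate with the measured steady-state fraction 2.134%."""
    return SwitchingRates.from_f(0.29, 0.02134)


@pytest.fixture(scope="session")
def default_image_set():
    """One default 500-cell synthetic field (session-cached: rendering and
    segmenting it dominates imaging-test runtime)."""
    return generate_image_set(SyntheticImageConfig(seed=1))
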