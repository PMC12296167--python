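import pytest

from bubston.dynamics import MediumProperties
from bubston.units import ELEMENTARY_CHARGE


@pytest.fixture(scope="session")
def water() -> MediumProperties:
    """Air-saturated water at room conditions (package defaults)."""
    return MediumProperties()


@pytest.fixture(scope="session")
def charge_60e() -> float:
    """Magnitude of the compound-species slipping-surface charge, esu."""
    return 60.0 * ELEMENTARY_CHARGE
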