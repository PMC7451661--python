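import hypothesis
import pytest

from aboin import DesignSpec

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture
def design_03() -> DesignSpec:
    """Fixed-boundary design at target 30% with the recommended defaults."""
    return DesignSpec(phi=0.3)


@pytest.fixture
def design_02() -> DesignSpec:
    return DesignSpec(phi=0.2)


@pytest.fixture
def worked_pi0():
    """The five-dose H0 confidence vector of the packaged prior study."""
    return (0.2, 0.45, 0.7, 0.45, 0.2)
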