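import pytest

from ckdcea import reference_parameter_set
from ckdcea.synthetic import GeneratorConfig, random_parameter_set


@pytest.fixture
def ref_ps():
    """The packaged reference inputs (fresh copy per test)."""
    return reference_parameter_set()


@pytest.fixture
def synth_ps():
    """A seed-fixed random parameter set."""
    return random_parameter_set(GeneratorConfig(seed=7))
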