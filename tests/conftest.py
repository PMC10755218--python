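import pytest

from psilocea import paper_fixture, random_parameter_set


@pytest.fixture(scope="session")
def base_params():
    """The base-case parameter fixture (session-scoped; treat as read-only)."""
    return paper_fixture()


@pytest.fixture
def params():
    """A fresh, mutable copy of the base-case parameters."""
    return paper_fixture()


@pytest.fixture(scope="session")
def synthetic_sets():
    """A small bank of random valid parameter sets for property checks."""
    return [random_parameter_set(seed) for seed in range(40)]
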