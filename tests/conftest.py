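import pytest

from crosswise import RandomizationDesign, reconstruct_counts
from crosswise.pipeline import STUDY_ATTRIBUTES


@pytest.fixture(scope="session")
def p1():
    return RandomizationDesign(0.158, "p1")


@pytest.fixture(scope="session")
def p2():
    return RandomizationDesign(0.842, "p2")


@pytest.fixture(scope="session")
def study_attrs():
    """Packaged printed quantities, keyed by attribute name."""
    return {a.attribute: a for a in STUDY_ATTRIBUTES}


@pytest.fixture(scope="session")
def study_arms(study_attrs, p1, p2):
    """Integer answer counts recovered from the printed estimates."""

    def rebuild(name):
        a = study_attrs[name]
        return (
            reconstruct_counts(a.pi1 / 100, p1, a.n1),
            reconstruct_counts(a.pi2 / 100, p2, a.n2),
            reconstruct_counts(a.dq / 100, None, a.n_dq),
        )

    return {name: rebuild(name) for name in study_attrs}
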