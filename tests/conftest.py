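import pytest

from taskstruct.agents import default_populations, simulate_cohort
from taskstruct.designs import enumerate_versions


@pytest.fixture(scope="session")
def exp2_versions():
    return enumerate_versions(2)


@pytest.fixture(scope="session")
def exp2_clustered(exp2_versions):
    return next(d for d in exp2_versions if d.mapping.clustered)


@pytest.fixture(scope="session")
def exp2_nonclustered(exp2_versions):
    return next(d for d in exp2_versions if not d.mapping.clustered)


@pytest.fixture(scope="session")
def small_cohort():
    """A small Experiment-2 cohort shared across read-only tests."""
    pops = default_populations(("age", "gender"))
    return simulate_cohort(6, pops, 2, seed=11)
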