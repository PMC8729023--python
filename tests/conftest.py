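import pytest

from anisoprev import (RefractiveCriteria, SimulationConfig, classify_frame,
                       make_fixture, simulate_cohort)
from anisoprev.cohort_io import average_frame


@pytest.fixture(scope="session")
def criteria():
    return RefractiveCriteria()


@pytest.fixture(scope="session")
def fixture_cohort():
    return make_fixture()


@pytest.fixture(scope="session")
def labeled_fixture(fixture_cohort, criteria):
    labeled = classify_frame(average_frame(fixture_cohort.data), criteria)
    return labeled.merge(fixture_cohort.truth[
        ["id", "category", "compound_astigmat", "is_ta", "aniso_type",
         "severity", "re_state", "le_state"]], on="id", suffixes=("", "_exp"))


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-size noisy study-shaped cohort shared across tests."""
    return simulate_cohort(SimulationConfig(n=3000), seed=11)


@pytest.fixture(scope="session")
def sim_labeled(sim_cohort, criteria):
    return classify_frame(average_frame(sim_cohort.data), criteria)
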