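import pytest

from esindicator import SimulationConfig, dongjiang_fixture, run_study
from esindicator.analysis import _retained_frame

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """The full Monte-Carlo study under default conditions (10,000 tables)."""
    return run_study(SimulationConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_frame(study):
    """Retained tables of the default study, as a DataFrame."""
    return _retained_frame(study)


@pytest.fixture()
def dongjiang():
    return dongjiang_fixture()
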