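import numpy as np
import pytest

from reekit import Subject, SyntheticConfig, fixture_cohort, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Frozen 12-subject fixture covering both sexes and all strata."""
    return fixture_cohort()


@pytest.fixture(scope="session")
def study_cohort():
    """One default-condition synthetic cohort, study-sized (n=284)."""
    return generate_cohort(SyntheticConfig(n=284, seed=20240729))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_subject(
    sex="male", age=30.0, weight=70.0, height=170.0, ree=None, sid="s"
) -> Subject:
    return Subject(id=sid, sex=sex, age=age, weight=weight, height=height, ree_measured=ree)
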