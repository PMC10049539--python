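import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from argmet import (
    CohortTable,
    SubjectRecord,
    default_cross_sectional_cohort,
    default_intervention_cohort,
)


def make_record(subject_id="s1", group="long_covid", arm="active",
                timepoint="baseline", arginine=200.0, citrulline=40.0,
                ornithine=120.0, adma=0.6, mma=0.13, sdma=0.7):
    return SubjectRecord(
        subject_id=subject_id, group=group, arm=arm, timepoint=timepoint,
        arginine=arginine, citrulline=citrulline, ornithine=ornithine,
        adma=adma, mma=mma, sdma=sdma,
    )


@pytest.fixture
def toy_cohort():
    return CohortTable([
        make_record("lc1", "long_covid", "active", "baseline"),
        make_record("lc2", "long_covid", "placebo", "baseline", arginine=180.0),
        make_record("hc1", "control", "none", "baseline",
                    arginine=220.0, citrulline=30.0, ornithine=83.0,
                    adma=0.48, mma=0.10, sdma=0.53),
    ])


@pytest.fixture(scope="session")
def cohort57():
    """Published baseline parameterisation: 46 long COVID vs 11 controls."""
    return default_cross_sectional_cohort(seed=7)


@pytest.fixture(scope="session")
def paired_cohort():
    """Published intervention parameterisation: 23 active / 23 placebo, paired."""
    return default_intervention_cohort(seed=7)


@pytest.fixture(scope="session")
def cohort57_xy(cohort57):
    X = cohort57.matrix()
    y = (cohort57.labels("group") == "long_covid").astype(int)
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
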