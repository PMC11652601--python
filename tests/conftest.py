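import numpy as np
import pytest

from quetipk.data import DoseEvent, EventDataset, Observation, SubjectRecord
from quetipk.synthetic_cohort import default_paper_spec, sample_cohort


@pytest.fixture(scope="session")
def paper_cohort():
    """One n=99 cohort from the default study spec (fixed seed)."""
    return sample_cohort(default_paper_spec(), 20240)


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-subject cohort for fast likelihood comparisons."""
    from dataclasses import replace

    spec = replace(default_paper_spec(), n_subjects=20, n_male=13)
    return sample_cohort(spec, 7)


def make_subject(
    sid="S1",
    weight=70.0,
    dose=210.0,
    interval=12.0,
    obs=((12.0, 150.0),),
    covariates=None,
):
    return SubjectRecord(
        id=sid,
        weight=weight,
        doses=(DoseEvent(time=0.0, amount=dose, interval=interval, ss=True),),
        observations=tuple(Observation(t, v) for t, v in obs),
        covariates=covariates or {},
    )


@pytest.fixture
def two_subject_dataset():
    return EventDataset(
        (
            make_subject("A", 70.0, 210.0, obs=((12.0, 150.0), (24.0, 180.0))),
            make_subject("B", 90.0, 300.0, obs=((12.0, 230.0),)),
        )
    )
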