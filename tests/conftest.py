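import numpy as np
import pandas as pd
import pytest

from gswitch.core_data import (
    BaselineCovariates,
    SubjectRecord,
    expand_to_person_time,
)
from gswitch.synthetic_trial import default_config, generate_person_time


def make_baseline(age=60.0, **kw) -> BaselineCovariates:
    return BaselineCovariates(age=age, **kw)


def make_subject(
    subject_id="s1",
    arm=0,
    progression_month=None,
    switch_month=None,
    censor_month=None,
    death_month=None,
    max_followup_months=48,
    **kw,
) -> SubjectRecord:
    return SubjectRecord(
        subject_id=subject_id,
        arm=arm,
        baseline=make_baseline(),
        progression_month=progression_month,
        switch_month=switch_month,
        censor_month=censor_month,
        death_month=death_month,
        max_followup_months=max_followup_months,
        **kw,
    )


@pytest.fixture(scope="session")
def small_cohort_table() -> pd.DataFrame:
    """A 150-subject feedback-config cohort shared across fast tests."""
    cfg = default_config(n_control=75, n_experimental=75, seed=11)
    return generate_person_time(cfg)


@pytest.fixture(scope="session")
def medium_cohort_table() -> pd.DataFrame:
    """A 700-subject feedback-config cohort for model-fitting tests."""
    cfg = default_config(n_control=350, n_experimental=350, seed=12)
    return generate_person_time(cfg)
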