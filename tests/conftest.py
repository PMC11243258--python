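import numpy as np
import pytest

from steatoscore import default_spec, generate_cohort
from steatoscore.records import SubjectRecord


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-per-sex synthetic cohort for fast structural tests."""
    return generate_cohort(default_spec(300, 300), seed=11)


@pytest.fixture(scope="session")
def study_cohort():
    """Default-size synthetic cohort (the study's sex splits)."""
    return generate_cohort(default_spec(), seed=42)


@pytest.fixture
def male_means_record():
    """A subject at the male cohort means of the printed descriptives."""
    return SubjectRecord(
        sex="male", age=42, height=175.8, weight=81.2, waist=89.8, hip=101.8,
        sbp=128.6, dbp=79.9, glucose=93.4, total_chol=191.8, hdl=49.2,
        triglycerides=107.8, ggt=31.5, ast=24.4, alt=29.3,
        body_fat_pct=19.6, visceral_fat_rating=8, diabetes=False)


@pytest.fixture
def female_means_record():
    return SubjectRecord(
        sex="female", age=42, height=162.5, weight=63.9, waist=77.0, hip=99.6,
        sbp=117.2, dbp=74.9, glucose=88.9, total_chol=189.0, hdl=59.5,
        triglycerides=81.5, ggt=18.5, ast=18.2, alt=17.3,
        body_fat_pct=29.0, visceral_fat_rating=5, diabetes=False)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
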