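import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from chargeaf.synthetic import GeneratorConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BASELINE = dt.date(2014, 1, 1)


def make_covariates(**overrides):
    """A complete-case covariate row with neutral defaults."""
    row = {
        "age_years": 60.0,
        "sex": "male",
        "ethnicity_white": True,
        "height_cm": 170.0,
        "weight_kg": 80.0,
        "sbp_mmHg": 130.0,
        "dbp_mmHg": 80.0,
        "current_smoking": False,
        "antihypertensive_use": False,
        "diabetes": False,
        "heart_failure": False,
        "myocardial_infarction": False,
        "hypertension": False,
        "stroke": False,
        "tia": False,
        "atherosclerosis": False,
        "angina": False,
    }
    row.update(overrides)
    return row


@pytest.fixture(scope="session")
def synth_cohort():
    """One moderately sized default-config cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n=20_000, seed=20140101))


@pytest.fixture(scope="session")
def synth_complete(synth_cohort):
    return synth_cohort.complete.reset_index(drop=True)


def random_survival_fixture(rng, n, tie_times=True, tie_markers=True):
    """Small censored-survival dataset with deliberate ties."""
    if tie_times:
        times = rng.integers(1, max(3, n // 2), n).astype(float)
    else:
        times = rng.random(n) * 5 + 0.01
    events = rng.random(n) < 0.7
    if tie_markers:
        marker = rng.integers(0, max(3, n // 3), n).astype(float)
    else:
        marker = rng.random(n)
    return marker, times, events
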