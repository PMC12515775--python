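import numpy as np
import pandas as pd
import pytest

from t2dsim.catalogs import (
    default_biomarker_catalog,
    default_cost_catalog,
    default_risk_catalog,
    default_utility_catalog,
)
from t2dsim.cohort import CohortProfile, generate_cohort, impute_missing
from t2dsim.risk import COMPLICATIONS


@pytest.fixture(scope="session")
def risk_catalog():
    return default_risk_catalog()


@pytest.fixture(scope="session")
def biomarker_catalog():
    return default_biomarker_catalog()


@pytest.fixture(scope="session")
def utility_catalog():
    return default_utility_catalog()


@pytest.fixture(scope="session")
def cost_catalog():
    return default_cost_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """1 000-person imputed default cohort, shared read-only across tests."""
    return impute_missing(generate_cohort(CohortProfile(n=1000, seed=42)))


@pytest.fixture(scope="session")
def mid_cohort():
    """5 000-person imputed default cohort for accounting-identity runs."""
    return impute_missing(generate_cohort(CohortProfile(n=5000, seed=11)))


def make_cohort_frame(rows: list[dict]) -> pd.DataFrame:
    """Hand-built cohort frame with all required columns defaulted."""
    df = pd.DataFrame(rows)
    defaults = {
        "age": 65.0,
        "sex": "female",
        "diabetes_duration": 5.0,
        "bmi": 25.0,
        "hba1c": 7.5,
        "sbp": 135.0,
        "dbp": 78.0,
        "ldl": 2.4,
        "smoker": False,
        "prior_cvd": False,
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    if "person_id" not in df.columns:
        df["person_id"] = [f"T{i:04d}" for i in range(len(df))]
    for comp in COMPLICATIONS:
        col = f"hist_{comp}"
        if col not in df.columns:
            df[col] = False
    for b in ("bmi", "hba1c", "sbp", "dbp", "ldl"):
        col = f"{b}_missing"
        if col not in df.columns:
            df[col] = df[b].isna() if df[b].isna().any() else False
    return df


@pytest.fixture
def cohort_factory():
    return make_cohort_frame
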