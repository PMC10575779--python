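import numpy as np
import pandas as pd
import pytest

from pfciron.cohort_io import ALL_COLUMNS, Cohort
from pfciron.harmonize import build_zscore_table
from pfciron.synthetic_cohort import default_paper_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_paper_config(seed=42))


@pytest.fixture(scope="session")
def default_ztable(default_cohort):
    return build_zscore_table(default_cohort)


def make_cohort(df: pd.DataFrame, provenance="test") -> Cohort:
    """Build a Cohort from a partial frame, filling absent columns."""
    df = df.copy()
    for col in ALL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return Cohort(df[list(ALL_COLUMNS)].reset_index(drop=True), provenance)


def simple_onebank_cohort(n_control, n_case, iron_fn, seed=0, ferritin_fn=None,
                          age_lo=18.0, age_hi=80.0):
    """Single-bank cohort with user-supplied analyte rules.

    ``iron_fn(rng, age, is_case)`` returns iron values; ``ferritin_fn``
    likewise (defaults to iron-independent noise).
    """
    rng = np.random.default_rng(seed)
    n = n_control + n_case
    is_case = np.array([False] * n_control + [True] * n_case)
    age = rng.uniform(age_lo, age_hi, n)
    iron = iron_fn(rng, age, is_case)
    ferritin = (ferritin_fn(rng, iron, is_case) if ferritin_fn is not None
                else rng.normal(10, 1, n))
    df = pd.DataFrame({
        "subject_id": [f"T{i:04d}" for i in range(n)],
        "bank": "NSW-BTRC",
        "diagnosis": np.where(is_case, "schizophrenia", "control"),
        "age_death": age,
        "sex": rng.choice(["F", "M"], n),
        "ancestry": rng.choice(["Caucasian", "non-Caucasian"], n, p=[0.8, 0.2]),
        "ph": rng.normal(6.5, 0.3, n).clip(5.5, 7.5),
        "pmi": rng.uniform(5, 60, n),
        "death_mode": "natural",
        "iron": iron,
        "ferritin": ferritin,
    })
    return make_cohort(df)
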