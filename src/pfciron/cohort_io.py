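"""Cohort table I/O, validation, and group-comparison summaries.

The cohort is a per-subject table, one row per postmortem specimen, with
diagnosis, source brain bank, demographics, tissue-quality covariates,
protein-normalized metal levels (µmol/g protein), ferritin (arbitrary
western-blot units) and optional antipsychotic-medication variables.

CSV dialect: comma-separated, UTF-8, "." decimal, empty cell = missing,
header mandatory, booleans encoded ``yes``/``no``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BANKS = ("NSW-BTRC", "VBBN", "NIMH-HBCC")
DIAGNOSES = ("control", "schizophrenia")
SEXES = ("F", "M")
ANCESTRIES = ("Caucasian", "non-Caucasian")
DEATH_MODES = ("natural", "non-natural")
AP_TYPICALITY = ("typical", "atypical", "mixed")

#: mandatory columns, in canonical order
MANDATORY_COLUMNS = (
    "subject_id", "bank", "diagnosis", "age_death", "sex", "ancestry",
    "ph", "pmi", "death_mode",
)
#: optional columns (missing cells allowed; whole column may be absent)
OPTIONAL_COLUMNS = (
    "smoker", "alcohol_user", "bmi",
    "iron", "copper", "zinc", "ferritin",
    "ap_mean_daily_dose", "ap_lifetime_exposure", "ap_duration",
    "ap_typicality", "ap_tox_positive", "lithium_tox_positive", "age_onset",
)
ALL_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

BOOL_COLUMNS = ("smoker", "alcohol_user", "ap_tox_positive", "lithium_tox_positive")
ANALYTE_COLUMNS = ("iron", "copper", "zinc", "ferritin")
MEDICATION_COLUMNS = (
    "ap_mean_daily_dose", "ap_lifetime_exposure", "ap_duration",
    "ap_typicality", "ap_tox_positive", "lithium_tox_positive", "age_onset",
)

_CATEGORICAL_LEVELS = {
    "bank": BANKS,
    "diagnosis": DIAGNOSES,
    "sex": SEXES,
    "ancestry": ANCESTRIES,
    "death_mode": DEATH_MODES,
    "ap_typicality": AP_TYPICALITY,
}


class CohortError(ValueError):
    """Raised on malformed cohort files or invalid cohort contents."""


@dataclass
class Cohort:
    """An ordered collection of subject records plus a provenance tag.

    ``df`` holds one row per subject in the canonical column schema;
    extra input columns are preserved in ``metadata``.
    """

    df: pd.DataFrame
    provenance: str = ""
    metadata: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.df)

    def counts(self) -> dict[str, int]:
        d = self.df["diagnosis"]
        return {
            "control": int((d == "control").sum()),
            "schizophrenia": int((d == "schizophrenia").sum()),
        }

    def per_bank_control_counts(self) -> dict[str, int]:
        ctrl = self.df[self.df["diagnosis"] == "control"]
        return {b: int((ctrl["bank"] == b).sum()) for b in sorted(self.df["bank"].unique())}

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), self.provenance,
                      None if self.metadata is None else self.metadata.copy())


@dataclass
class DemographicsTable:
    """Table-1-style per-variable group comparison."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def _decode_bool(series: pd.Series, col: str) -> pd.Series:
    def conv(v):
        if pd.isna(v) or v == "":
            return np.nan
        s = str(v).strip().lower()
        if s in ("yes", "true", "1"):
            return True
        if s in ("no", "false", "0"):
            return False
        raise CohortError(f"column {col!r}: cannot decode boolean value {v!r}")
    return series.map(conv)


def read_cohort(path) -> Cohort:
    """Read and validate a cohort CSV.

    Header matching is case-insensitive; extra columns are preserved as
    metadata.  Empty strings become missing values.  Raises
    :class:`CohortError` on unknown category codes (with row number),
    duplicate subject ids, or a missing mandatory column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortError(f"missing mandatory column(s): {', '.join(missing)}")
    if len(raw) == 0:
        logger.warning("cohort file %s contains a header but no rows", path)
        return Cohort(pd.DataFrame(columns=list(ALL_COLUMNS)), provenance=str(path))

    known = [c for c in ALL_COLUMNS if c in raw.columns]
    extra = [c for c in raw.columns if c not in ALL_COLUMNS]
    df = raw[known].replace("", np.nan).copy()

    for col, levels in _CATEGORICAL_LEVELS.items():
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = ~vals.isin(levels)
        if bad.any():
            row = int(vals.index[bad][0]) + 2  # 1-based + header line
            raise CohortError(
                f"row {row}: unknown {col} code {vals[bad].iloc[0]!r} "
                f"(expected one of {levels})")

    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise CohortError(f"duplicate subject_id {dup.iloc[0]!r}")

    for col in df.columns:
        if col in BOOL_COLUMNS:
            df[col] = _decode_bool(df[col], col)
        elif col not in _CATEGORICAL_LEVELS and col != "subject_id":
            df[col] = pd.to_numeric(df[col], errors="raise")

    for col in ALL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(ALL_COLUMNS)]

    cohort = Cohort(df.reset_index(drop=True), provenance=str(path),
                    metadata=raw[extra] if extra else None)
    violations = validate_cohort(cohort)
    if violations:
        raise CohortError("invalid cohort: " + "; ".join(violations[:10]))
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort in the canonical CSV dialect (booleans as yes/no)."""
    df = cohort.df.copy()
    for col in BOOL_COLUMNS:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else ("yes" if v else "no"))
    df.to_csv(path, index=False, na_rep="")


def validate_cohort(cohort: Cohort) -> list[str]:
    """Return every invariant violation as a human-readable string.

    An empty list means the cohort is valid.  Violations are data, not
    exceptions: ids and field names are included for triage.
    """
    df = cohort.df
    out: list[str] = []
    dup = df["subject_id"][df["subject_id"].duplicated()]
    for sid in dup.unique():
        out.append(f"subject_id {sid!r} duplicated")
    for _, r in df.iterrows():
        sid = r["subject_id"]
        for col in ANALYTE_COLUMNS:
            v = r.get(col)
            if pd.notna(v) and v < 0:
                out.append(f"{sid}: {col} must be non-negative (got {v})")
        if pd.notna(r["age_death"]) and not (0 < r["age_death"] < 120):
            out.append(f"{sid}: age_death outside (0, 120) (got {r['age_death']})")
        if pd.notna(r["ph"]) and not (5.0 < r["ph"] < 8.0):
            out.append(f"{sid}: ph outside (5.0, 8.0) (got {r['ph']})")
        if pd.notna(r["pmi"]) and r["pmi"] < 0:
            out.append(f"{sid}: pmi must be non-negative (got {r['pmi']})")
        if r["diagnosis"] == "control":
            for col in MEDICATION_COLUMNS:
                if col == "age_onset":
                    continue
                if pd.notna(r.get(col)):
                    out.append(f"{sid}: medication field {col} present on a control")
            if pd.notna(r.get("age_onset")):
                out.append(f"{sid}: age_onset present on a control")
    return out


# ---------------------------------------------------------------------------
# Table-1-style demographics


def _ttest(a, b, welch: bool = False):
    return stats.ttest_ind(a, b, equal_var=not welch)


def chi2_2way(table: np.ndarray, correction: bool = False):
    """Pearson chi-square on an r×c contingency table, no continuity
    correction by default (Yates configurable)."""
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return chi2, p, dof


_CONTINUOUS_VARS = ("age_death", "ph", "pmi", "bmi")
_CATEGORICAL_VARS = ("bank", "sex", "ancestry", "smoker", "alcohol_user", "death_mode")


def summarize_demographics(cohort: Cohort, welch: bool = False,
                           correction: bool = False) -> DemographicsTable:
    """Compare demographic and tissue-quality variables across groups.

    Continuous variables use an independent-samples t-test (pooled
    variance; Welch optional); categorical variables use a Pearson
    chi-square test.  Missing values are excluded pairwise.
    """
    df = cohort.df
    ctrl = df[df["diagnosis"] == "control"]
    case = df[df["diagnosis"] == "schizophrenia"]
    if len(ctrl) == 0 or len(case) == 0:
        raise CohortError("both diagnostic groups must be non-empty")

    rows = []
    rows.append({
        "variable": "n", "control": str(len(ctrl)), "schizophrenia": str(len(case)),
        "test": "", "statistic": np.nan, "p": np.nan,
    })
    for var in _CATEGORICAL_VARS:
        a, b = ctrl[var].dropna(), case[var].dropna()
        if len(a) == 0 or len(b) == 0:
            continue
        levels = sorted(set(a) | set(b), key=str)
        tab = np.array([[int((g == lv).sum()) for lv in levels] for g in (a, b)])
        chi2, p, _ = chi2_2way(tab, correction=correction)
        fmt = lambda g: "/".join(f"{lv}:{int((g == lv).sum())}" for lv in levels)
        rows.append({
            "variable": var, "control": fmt(a), "schizophrenia": fmt(b),
            "test": "pearson-chi2", "statistic": chi2, "p": p,
        })
    for var in _CONTINUOUS_VARS:
        a, b = ctrl[var].dropna().astype(float), case[var].dropna().astype(float)
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = _ttest(a, b, welch=welch)
        rows.append({
            "variable": var,
            "control": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
            "schizophrenia": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
            "test": "welch-t" if welch else "student-t", "statistic": t, "p": p,
        })
    return DemographicsTable(pd.DataFrame(rows))
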