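"""Cross-bank harmonization and distributional checks.

Banks process tissue with different extraction protocols, so raw
analyte levels are on bank-specific scales.  Measurements are made
commensurable by control-anchored z-scoring: within each bank,
z = (raw − bank control mean) / bank control SD, applied to every
subject of that bank.  The per-subject iron-to-ferritin ratio is formed
on the raw scale first and then z-scored the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pfciron.cohort_io import Cohort

Z_ANALYTES = ("iron", "ferritin", "copper", "zinc", "ratio")


class HarmonizeError(ValueError):
    pass


@dataclass
class ZScoreTable:
    """Per-subject bank-harmonized z-scores plus the control-derived
    scaling constants (per bank × analyte)."""

    df: pd.DataFrame          # index: subject_id; columns z_iron, ..., z_ratio
    scaling: pd.DataFrame     # columns: bank, analyte, control_mean, control_sd, n_control

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=True, index_label="subject_id")


def protein_normalize(metal_conc: float, dilution_factor: float,
                      protein_conc: float) -> float:
    """µmol/L in the measured solution → µmol/g protein in the extract.

    ``metal_conc × dilution_factor ÷ protein_conc`` with protein from a
    BCA assay in g/L.
    """
    if protein_conc <= 0:
        raise ValueError("protein_conc must be > 0")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be ≥ 1")
    return metal_conc * dilution_factor / protein_conc


def _zscore_column(df: pd.DataFrame, values: pd.Series, analyte: str,
                   min_controls: int = 3):
    z = pd.Series(np.nan, index=df.index, dtype=float)
    scaling = []
    for bank, idx in df.groupby("bank").groups.items():
        sub = values.loc[idx]
        ctrl = sub[(df.loc[idx, "diagnosis"] == "control") & sub.notna()]
        if len(ctrl) < min_controls:
            raise HarmonizeError(
                f"bank {bank!r} has only {len(ctrl)} measured controls for "
                f"{analyte!r} (need ≥ {min_controls})")
        m, s = ctrl.mean(), ctrl.std(ddof=1)
        if s == 0:
            raise HarmonizeError(f"bank {bank!r}: zero control SD for {analyte!r}")
        z.loc[idx] = (sub - m) / s
        scaling.append({"bank": bank, "analyte": analyte,
                        "control_mean": m, "control_sd": s, "n_control": len(ctrl)})
    return z, scaling


def bank_zscores(cohort: Cohort, analyte: str) -> ZScoreTable:
    """Control-anchored z-scores of one raw analyte, per bank.

    Sample SD uses the n−1 denominator.  z is missing iff the raw value
    is missing.  Raises on banks with < 3 measured controls or zero
    control SD.
    """
    df = cohort.df
    if analyte not in df.columns:
        raise HarmonizeError(f"unknown analyte {analyte!r}")
    z, scaling = _zscore_column(df, df[analyte].astype(float), analyte)
    out = pd.DataFrame({f"z_{analyte}": z.values}, index=df["subject_id"].values)
    return ZScoreTable(out, pd.DataFrame(scaling))


def iron_ferritin_ratio(cohort: Cohort) -> ZScoreTable:
    """Per-subject raw iron ÷ ferritin, then bank z-scored against controls.

    The ratio is a proxy for iron not safely stored in ferritin.  It is
    formed within subject on the raw scale (bank scale factors cancel in
    the ratio only if they are common to both analytes; z-scoring removes
    whatever remains).  Subjects with missing or non-positive ferritin
    get a missing ratio.
    """
    df = cohort.df
    iron = df["iron"].astype(float)
    ferr = df["ferritin"].astype(float)
    raw = pd.Series(np.nan, index=df.index, dtype=float)
    ok = iron.notna() & ferr.notna() & (ferr > 0)
    raw[ok] = iron[ok] / ferr[ok]
    z, scaling = _zscore_column(df, raw, "ratio")
    out = pd.DataFrame({"ratio_raw": raw.values, "z_ratio": z.values},
                       index=df["subject_id"].values)
    return ZScoreTable(out, pd.DataFrame(scaling))


def build_zscore_table(cohort: Cohort,
                       analytes=("iron", "ferritin", "copper", "zinc")) -> ZScoreTable:
    """Harmonize several analytes plus the iron-to-ferritin ratio into a
    single table keyed by subject_id."""
    frames, scalings = [], []
    for analyte in analytes:
        t = bank_zscores(cohort, analyte)
        frames.append(t.df)
        scalings.append(t.scaling)
    if "iron" in analytes and "ferritin" in analytes:
        t = iron_ferritin_ratio(cohort)
        frames.append(t.df)
        scalings.append(t.scaling)
    return ZScoreTable(pd.concat(frames, axis=1), pd.concat(scalings, ignore_index=True))


def test_distribution(values) -> dict:
    """Skewness/kurtosis omnibus normality check (D'Agostino–Pearson).

    Returns sample skewness, excess kurtosis, the omnibus K² statistic
    and its p-value.  Requires n ≥ 8 (the test is undefined below that).
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(x) < 8:
        raise ValueError(f"normality test requires n ≥ 8 (got {len(x)})")
    k2, p = stats.normaltest(x)
    return {
        "n": len(x),
        "skewness": float(stats.skew(x)),
        "kurtosis": float(stats.kurtosis(x)),
        "statistic": float(k2),
        "p": float(p),
    }


@dataclass
class VarianceComparison:
    control_variance: float
    case_variance: float
    variance_ratio: float     # case ÷ control, sample-variance scale
    f_statistic: float
    f_p: float
    bf_statistic: float       # Brown–Forsythe (median-centred Levene)
    bf_p: float


def compare_variance(control_values, case_values) -> VarianceComparison:
    """Two-sided variance-ratio F test plus the robust Brown–Forsythe
    test on median-centred absolute deviations."""
    a = np.asarray(pd.Series(control_values).dropna(), dtype=float)
    b = np.asarray(pd.Series(case_values).dropna(), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n ≥ 3")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("degenerate (zero-variance) group")
    f = vb / va
    dfn, dfd = len(b) - 1, len(a) - 1
    cdf = stats.f.cdf(f, dfn, dfd)
    f_p = 2 * min(cdf, 1 - cdf)
    bf_stat, bf_p = stats.levene(a, b, center="median")
    return VarianceComparison(va, vb, vb / va, f, float(f_p),
                              float(bf_stat), float(bf_p))
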