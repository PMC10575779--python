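"""ROC analysis, optimal cutoffs, risk flags, and the combined classifier.

Discrimination is quantified per marker (covariate-adjusted iron in the
young subcohort, ferritin in the low-iron subcohort, iron-to-ferritin
ratio in the full cohort) by the ROC AUC with a bias-corrected (BC)
stratified-bootstrap CI; operating cutoffs maximize Youden's
J = sensitivity + specificity − 1.  The three resulting high-risk flags
feed a logistic model whose probability cutoff (again by Youden) yields
the combined sensitivity / specificity / accuracy with exact
Clopper–Pearson CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from pfciron.logistic_scan import (
    LogisticFit, SeparationError, fit_logistic, fit_logistic_firth,
)


@dataclass
class RocResult:
    auc: float
    ci_low: float | None
    ci_high: float | None
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_case: int
    n_control: int
    direction: str = "greater"        # flagged = score above cutoff
    optimal_threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None


def roc_auc(scores, labels, direction: str = "greater") -> RocResult:
    """ROC curve and AUC (rank / Mann–Whitney formulation, ties = 0.5).

    ``direction="greater"`` treats higher scores as case-like; ``"less"``
    flips the orientation (e.g. ferritin, lower in cases).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(np.unique(s)) < 2:
        raise ValueError("need at least 2 distinct scores")
    oriented = s if direction == "greater" else -s
    auc = float(roc_auc_score(y, oriented))
    fpr, tpr, thr = roc_curve(y, oriented)
    return RocResult(auc, None, None, fpr, tpr, thr,
                     int((y == 1).sum()), int((y == 0).sum()), direction)


def auc_bootstrap_ci(scores, labels, B: int = 2000, level: float = 0.95,
                     seed: int = 0, direction: str = "greater",
                     max_retries: int = 100):
    """Bias-corrected (BC) stratified-bootstrap percentile CI for the AUC.

    Resampling is within class, so both classes are always present;
    resamples with a single distinct score are redrawn (retry cap).
    """
    if B < 100:
        raise ValueError("need B ≥ 100 bootstrap replicates")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    oriented = s if direction == "greater" else -s
    point = float(roc_auc_score(y, oriented))
    rng = np.random.default_rng(seed)
    i1, i0 = np.where(y == 1)[0], np.where(y == 0)[0]
    reps = np.empty(B)
    for b in range(B):
        for attempt in range(max_retries):
            idx = np.concatenate([rng.choice(i1, len(i1)), rng.choice(i0, len(i0))])
            if len(np.unique(oriented[idx])) > 1:
                break
        else:
            reps[b] = point  # degenerate: resampled scores are constant
            continue
        reps[b] = roc_auc_score(y[idx], oriented[idx])
    if np.all(reps == point):
        return point, point
    frac_below = np.mean(reps < point)
    frac_below = min(max(frac_below, 1.0 / (B + 1)), 1 - 1.0 / (B + 1))
    z0 = stats.norm.ppf(frac_below)
    alpha = 1 - level
    lo_q = stats.norm.cdf(2 * z0 + stats.norm.ppf(alpha / 2))
    hi_q = stats.norm.cdf(2 * z0 + stats.norm.ppf(1 - alpha / 2))
    lo, hi = np.quantile(reps, [lo_q, hi_q])
    return float(lo), float(hi)


def optimal_cutoff(roc: RocResult, scores, labels, criterion: str = "youden"):
    """Operating cutoff maximizing Youden J (or accuracy), enumerated over
    midpoints between adjacent distinct scores; ties break toward higher
    specificity.  Mutates ``roc`` in place and returns it."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    oriented = s if roc.direction == "greater" else -s
    uniq = np.unique(oriented)
    mids = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]])
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    best = None
    for m in mids:
        pred = oriented > m
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        sens, spec = tp / n1, tn / n0
        acc = (tp + tn) / len(y)
        j = sens + spec - 1 if criterion == "youden" else acc
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and spec > best[2]):
            best = (j, sens, spec, acc, m)
    _, sens, spec, acc, m = best
    roc.optimal_threshold = float(m if roc.direction == "greater" else -m)
    roc.sensitivity, roc.specificity, roc.accuracy = sens, spec, acc
    return roc


def _clopper_pearson(k: int, n: int, level: float = 0.95):
    if n == 0:
        return (np.nan, np.nan)
    res = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return float(res.low), float(res.high)


FLAG_NAMES = ("high_iron_young", "low_ferritin_low_iron", "high_ratio")


def build_risk_flags(ztable, cohort, age_cutoff: float, iron_cutoff: float,
                     marker_cutoffs: dict, adjusted: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject boolean high-risk flags with domain markers.

    * ``high_iron_young`` — defined for age < ``age_cutoff``: adjusted
      iron above its optimal cutoff;
    * ``low_ferritin_low_iron`` — defined for z_iron < ``iron_cutoff``:
      adjusted ferritin below its optimal cutoff;
    * ``high_ratio`` — defined for all: adjusted ratio above its cutoff.

    Out-of-domain flags are False (domain recorded in ``*_applicable``)
    so the combined model can use every subject with complete markers.
    ``marker_cutoffs`` maps flag name → cutoff on the adjusted scale.
    ``adjusted`` optionally supplies covariate-adjusted marker columns
    (``iron``, ``ferritin``, ``ratio``); raw z-scores are used otherwise.
    """
    df = cohort.df.set_index("subject_id")
    if adjusted is not None:
        iron, ferr, ratio = (adjusted[c].reindex(df.index) for c in ("iron", "ferritin", "ratio"))
    else:
        iron = ztable.df["z_iron"].reindex(df.index)
        ferr = ztable.df["z_ferritin"].reindex(df.index)
        ratio = ztable.df["z_ratio"].reindex(df.index)
    z_iron = ztable.df["z_iron"].reindex(df.index)
    age = df["age_death"]

    out = pd.DataFrame(index=df.index)
    young = age < age_cutoff
    out["high_iron_young"] = (young & (iron > marker_cutoffs["high_iron_young"])).fillna(False)
    out["high_iron_young_applicable"] = young & iron.notna()
    low_iron = z_iron < iron_cutoff
    out["low_ferritin_low_iron"] = (low_iron & (ferr < marker_cutoffs["low_ferritin_low_iron"])).fillna(False)
    out["low_ferritin_low_iron_applicable"] = low_iron & ferr.notna()
    out["high_ratio"] = (ratio > marker_cutoffs["high_ratio"]).fillna(False)
    out["high_ratio_applicable"] = ratio.notna()
    # a subject is classifiable if every marker needed is measured
    out["classifiable"] = iron.notna() & ferr.notna() & ratio.notna() & age.notna()
    return out


@dataclass
class ClassificationReport:
    fit: LogisticFit
    probability_cutoff: float
    confusion: dict                  # tp, fp, tn, fn
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple
    specificity_ci: tuple
    accuracy_ci: tuple
    cases_perturbed_fraction: float
    controls_intact_fraction: float
    n_classified: int
    flags_used: tuple = FLAG_NAMES


def combined_classifier(flags: pd.DataFrame, labels: pd.Series,
                        flag_names=FLAG_NAMES) -> ClassificationReport:
    """Logistic model of diagnosis on the three risk flags; probability
    cutoff by Youden J on the fitted probabilities."""
    keep = flags["classifiable"] if "classifiable" in flags else pd.Series(True, index=flags.index)
    F = flags.loc[keep, list(flag_names)].astype(float)
    y = labels.reindex(F.index).astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need ≥ 2 subjects per class with complete flags")
    X = np.column_stack([np.ones(len(F))] + [F[c].values for c in flag_names])
    # a rare flag with a zero cell quasi-separates a small cohort; fall
    # back to the Firth bias-reduced fit, which stays finite
    try:
        fit = fit_logistic(X, y.values, names=["intercept", *flag_names])
    except SeparationError:
        fit = fit_logistic_firth(X, y.values, names=["intercept", *flag_names])
    prob = 1 / (1 + np.exp(-(X @ fit.params)))

    uniq = np.unique(prob)
    mids = np.concatenate([[uniq[0] - 1e-9], (uniq[:-1] + uniq[1:]) / 2]) \
        if len(uniq) > 1 else np.array([uniq[0] - 1e-9])
    best = None
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    for m in mids:
        pred = prob > m
        tp = int((pred & (y == 1)).sum()); tn = int((~pred & (y == 0)).sum())
        sens, spec = tp / n1, tn / n0
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and spec > best[2]):
            best = (j, sens, spec, m)
    _, _, _, cutoff = best
    pred = prob > cutoff
    tp = int((pred & (y == 1)).sum()); fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum()); fp = int((pred & (y == 0)).sum())
    n = len(y)
    sens, spec, acc = tp / n1, tn / n0, (tp + tn) / n
    return ClassificationReport(
        fit, float(cutoff), {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        sens, spec, acc,
        _clopper_pearson(tp, n1), _clopper_pearson(tn, n0),
        _clopper_pearson(tp + tn, n),
        cases_perturbed_fraction=tp / n1,
        controls_intact_fraction=tn / n0,
        n_classified=n,
    )


def compare_nested_models(full: LogisticFit, reduced: LogisticFit):
    """Likelihood-ratio test of nested logistic fits (same observations)."""
    if full.n_used != reduced.n_used:
        raise ValueError("fits use different observations; LR test invalid")
    if full.names and reduced.names and not set(reduced.names) <= set(full.names):
        raise ValueError("models are not nested")
    df = len(full.params) - len(reduced.params)
    if df < 0:
        raise ValueError("'full' has fewer predictors than 'reduced'")
    lr = max(2 * (full.llf - reduced.llf), 0.0)
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    aic_full = 2 * len(full.params) - 2 * full.llf
    aic_reduced = 2 * len(reduced.params) - 2 * reduced.llf
    return {"lr": float(lr), "df": df, "p": p,
            "aic_full": aic_full, "aic_reduced": aic_reduced}
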