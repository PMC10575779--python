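"""Confounder-robustness machinery.

Three checks that the diagnosis–iron association reflects the disease
rather than something else:

* propensity-score matching (1:1 greedy nearest-neighbour on the logit
  propensity, caliper-limited, followed by regression adjustment on the
  matched set);
* a single-mediator path model (iron → zinc → diagnosis) with a
  bootstrap CI on the indirect effect a·b;
* medication-association tests among cases (antipsychotic dose,
  lifetime exposure, duration, typicality, toxicology) with seeded
  permutation p-values alongside parametric ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pfciron.logistic_scan import fit_logistic
from pfciron.robust_linear import encode_covariates, fit_mm, group_difference


@dataclass
class MatchResult:
    pairs: pd.DataFrame            # case_id, control_id, distance
    smd_pre: pd.Series             # standardized mean differences, pre-match
    smd_post: pd.Series
    caliper: float                 # on the logit-propensity scale
    fit: object | None = None      # post-matching group-difference fit


def _smd(df, covariates, case_mask):
    out = {}
    for c in covariates:
        a, b = df.loc[case_mask, c], df.loc[~case_mask, c]
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        out[c] = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    return pd.Series(out)


def propensity_match(cohort, covariates, caliper: float = 0.2,
                     seed: int = 0, analyte: str | None = None,
                     ztable=None) -> MatchResult:
    """1:1 propensity matching with regression adjustment.

    The propensity model is logistic diagnosis ~ covariates; matching is
    nearest-neighbour on the logit propensity without replacement,
    greedy in a seeded random case order, with the caliper expressed in
    SDs of the logit propensity (default 0.2).  When ``analyte`` and
    ``ztable`` are given, the matched-set group difference is estimated
    by :func:`~pfciron.robust_linear.group_difference` (regression
    adjustment on the same covariates).
    """
    df = cohort.df.set_index("subject_id")
    cov = encode_covariates(df, covariates)
    keep = cov.notna().all(axis=1)
    df, cov = df[keep], cov[keep]
    case_mask = df["diagnosis"] == "schizophrenia"
    if case_mask.sum() == 0 or (~case_mask).sum() == 0:
        raise ValueError("both groups must be non-empty")

    X = np.column_stack([np.ones(len(df))] + [cov[c].values for c in cov.columns])
    fit = fit_logistic(X, case_mask.values.astype(int))
    logit_ps = X @ fit.params
    ps = pd.Series(logit_ps, index=df.index)
    cal = caliper * ps.std(ddof=1)

    rng = np.random.default_rng(seed)
    case_ids = list(ps[case_mask].index)
    rng.shuffle(case_ids)
    available = dict(ps[~case_mask])
    pairs = []
    for cid in case_ids:
        if not available:
            break
        ctrl_ids = list(available)
        d = np.abs(np.array([available[k] for k in ctrl_ids]) - ps[cid])
        j = int(np.argmin(d))
        if d[j] <= cal:
            pairs.append({"case_id": cid, "control_id": ctrl_ids[j],
                          "distance": float(d[j])})
            del available[ctrl_ids[j]]
    if not pairs:
        raise ValueError(
            "no matches within caliper; pre-match standardized differences: "
            + _smd(cov, cov.columns, case_mask.values).round(3).to_dict().__repr__())

    pairs_df = pd.DataFrame(pairs)
    matched_ids = list(pairs_df["case_id"]) + list(pairs_df["control_id"])
    sub = df.loc[matched_ids]
    sub_cov = cov.loc[matched_ids]
    smd_pre = _smd(cov, cov.columns, case_mask.values)
    smd_post = _smd(sub_cov, sub_cov.columns,
                    (sub["diagnosis"] == "schizophrenia").values)

    gd = None
    if analyte is not None and ztable is not None:
        from pfciron.cohort_io import Cohort
        matched_cohort = Cohort(sub.reset_index(), provenance="matched")
        gd = group_difference(ztable, analyte, covariates, matched_cohort)
    return MatchResult(pairs_df, smd_pre, smd_post, float(cal), gd)


@dataclass
class MediationResult:
    path_a: float                  # exposure → mediator (linear, robust)
    path_a_se: float
    path_b: float                  # mediator → outcome (log-odds / SD, adj. exposure)
    path_b_se: float
    direct_effect: float           # c′: exposure → outcome given mediator
    indirect_effect: float         # a·b
    indirect_ci: tuple
    proportion_mediated: float | None
    n: int
    B: int


def mediation(exposure, mediator, outcome, covariates=None,
              B: int = 1000, seed: int = 0, level: float = 0.95) -> MediationResult:
    """Single-mediator product-of-coefficients path model with a logistic
    outcome.

    Path a: robust linear regression of mediator on exposure (+cov).
    Paths b, c′: logistic outcome ~ exposure + mediator (+cov).
    Indirect effect a·b with a seeded percentile-bootstrap CI.
    Proportion mediated is reported only when a·b and c′ share a sign.
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=int)
    C = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if C is not None and C.shape[0] != len(x):
        C = C.T
    ok = np.isfinite(x) & np.isfinite(m)
    if C is not None:
        ok &= np.isfinite(C).all(axis=1)
    x, m, y = x[ok], m[ok], y[ok]
    C = None if C is None else C[ok]
    if np.var(m) == 0:
        raise ValueError("degenerate mediator (zero variance)")
    n = len(x)

    def paths(x, m, y, C):
        cols = [] if C is None else [*C.T]
        Xa = np.column_stack([np.ones(len(x)), x] + cols)
        a = fit_mm(Xa, m)
        Xb = np.column_stack([np.ones(len(x)), x, m] + cols)
        b = fit_logistic(Xb, y)
        return a, b

    fa, fb = paths(x, m, y, C)
    a, a_se = float(fa.params[1]), float(fa.bse[1])
    cprime, b_coef, b_se = float(fb.params[1]), float(fb.params[2]), float(fb.bse[2])
    indirect = a * b_coef

    rng = np.random.default_rng(seed)
    reps = []
    tries = 0
    while len(reps) < B and tries < 4 * B:
        tries += 1
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2 or np.var(m[idx]) == 0:
            continue
        try:
            ra, rb = paths(x[idx], m[idx], y[idx], None if C is None else C[idx])
            reps.append(float(ra.params[1]) * float(rb.params[2]))
        except Exception:
            continue
    alpha = 1 - level
    ci = tuple(np.quantile(reps, [alpha / 2, 1 - alpha / 2])) if reps else (np.nan, np.nan)
    total = indirect + cprime
    prop = indirect / total if (indirect * cprime > 0 and total != 0) else None
    return MediationResult(a, a_se, b_coef, b_se, cprime, indirect, ci, prop, n, len(reps))


def _permutation_p(stat_fn, x, y, observed, n_perm, rng):
    """Two-sided permutation p on the grid (k+1)/(B+1)."""
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if abs(stat_fn(x, perm)) >= abs(observed) - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def medication_association(cohort, ztable, exposures=None, adjusters=None,
                           n_perm: int = 10000, seed: int = 0,
                           method: str = "pearson") -> pd.DataFrame:
    """Associations between harmonized iron and medication exposures,
    among cases only.

    Continuous exposures: correlation (Pearson default, Spearman option)
    with a seeded permutation p alongside the parametric one, and a
    partial (adjusted) correlation when adjusters are given.
    Categorical exposures (typicality, toxicology flags): robust group
    contrast of iron via the MM estimator.
    """
    if exposures is None:
        exposures = ("ap_mean_daily_dose", "ap_lifetime_exposure", "ap_duration",
                     "ap_typicality", "ap_tox_positive", "lithium_tox_positive")
    df = cohort.df.set_index("subject_id")
    cases = df[df["diagnosis"] == "schizophrenia"]
    z = ztable.df["z_iron"].reindex(cases.index)
    rng = np.random.default_rng(seed)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    rows = []
    for exp_name in exposures:
        col = cases[exp_name]
        row = {"exposure": exp_name, "n": 0, "type": "", "estimate": np.nan,
               "p_parametric": np.nan, "p_permutation": np.nan,
               "estimate_adjusted": np.nan, "p_adjusted": np.nan,
               "available": False}
        if col.notna().sum() == 0:
            rows.append(row)
            continue
        if col.dtype == object and exp_name == "ap_typicality" or col.map(
                lambda v: isinstance(v, (bool, np.bool_))).any():
            ok = col.notna() & z.notna()
            xs, zz = col[ok], z[ok]
            if ok.sum() < 10 or xs.nunique() < 2:
                rows.append(row)
                continue
            levels = sorted(xs.unique(), key=str)
            dummies = [(xs == lv).astype(float).values for lv in levels[1:]]
            X = np.column_stack([np.ones(ok.sum())] + dummies)
            fit = fit_mm(X, zz.values, names=["intercept"] + [str(l) for l in levels[1:]])
            row.update({"n": int(ok.sum()), "type": "categorical",
                        "estimate": float(fit.params[1]),
                        "p_parametric": float(fit.pvalues[1]),
                        "available": True})
            rows.append(row)
            continue
        ok = col.notna() & z.notna()
        if ok.sum() < 10:
            rows.append(row)
            continue
        xs = col[ok].astype(float).values
        zz = z[ok].values
        r, p = corr(xs, zz)
        stat = lambda a, b: corr(a, b)[0]
        p_perm = _permutation_p(stat, xs, zz, r, n_perm, rng)
        row.update({"n": int(ok.sum()), "type": "continuous",
                    "estimate": float(r), "p_parametric": float(p),
                    "p_permutation": float(p_perm), "available": True})
        if adjusters:
            adj = cases.loc[ok.index[ok], list(adjusters)].astype(float)
            ok2 = adj.notna().all(axis=1).values
            if ok2.sum() >= 10:
                A = np.column_stack([np.ones(ok2.sum())] + [adj[c].values[ok2] for c in adj])
                rx = xs[ok2] - A @ np.linalg.lstsq(A, xs[ok2], rcond=None)[0]
                rz = zz[ok2] - A @ np.linalg.lstsq(A, zz[ok2], rcond=None)[0]
                ra, pa = corr(rx, rz)
                row.update({"estimate_adjusted": float(ra), "p_adjusted": float(pa)})
        rows.append(row)
    return pd.DataFrame(rows)
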