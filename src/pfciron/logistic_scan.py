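"""Logistic diagnosis models, influence pruning, and serial cutoff scans.

The scans ask *where* a marker carries diagnostic information: a serial
sequence of logistic fits over nested subcohorts (all subjects younger
than an age cutoff; all subjects below an iron cutoff), each reporting
the odds ratio of a schizophrenia diagnosis per 1 SD of the
covariate-adjusted marker.  "Covariate-adjusted" means the marker is
robustly residualized on the covariates within the analysis subset and
re-standardized to SD 1, so the OR unit is exactly 1 SD; entering the
covariates directly into the logistic model is available as an option.

Highly influential observations are pruned by Pregibon delta-beta
(standardized Pearson residual² × h/(1−h)²) above a threshold, refit
once — no iterative cascade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from pfciron.robust_linear import encode_covariates, fit_mm

AGE_SCAN_COVARIATES = ("sex", "ancestry", "ph", "pmi")
IRON_SCAN_COVARIATES = ("age", "sex", "ancestry", "ph", "pmi")


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


@dataclass
class LogisticFit:
    params: np.ndarray            # log-odds scale
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    llf: float
    n_used: int
    names: list = field(default_factory=list)
    excluded_ids: list = field(default_factory=list)

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "or": np.exp(self.params),
            "ci_low": np.exp(self.params - q * self.bse),
            "ci_high": np.exp(self.params + q * self.bse),
            "p": self.pvalues,
        }, index=self.names or [f"x{i}" for i in range(len(self.params))])


def fit_logistic(design, labels, names=None) -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton/IRLS) with Wald inference.

    Raises :class:`SeparationError` on (quasi-)complete separation
    instead of returning silently huge coefficients, and ``ValueError``
    if only one class is present.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic MLE failed to converge")
    eta = X @ res.params
    p = 1 / (1 + np.exp(-eta))
    if np.all((p > 0.999) == (y == 1)) and np.all((p < 0.001) == (y == 0)) \
            and (np.abs(eta) > 10).all():
        raise SeparationError("complete separation detected")
    return LogisticFit(np.asarray(res.params), np.asarray(res.bse),
                       np.asarray(res.tvalues), np.asarray(res.pvalues),
                       float(res.llf), len(y),
                       list(names) if names is not None else [])


def fit_logistic_firth(design, labels, names=None, max_iter: int = 200,
                       tol: float = 1e-10) -> LogisticFit:
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    Finite estimates exist even under (quasi-)complete separation, e.g.
    a risk flag with a zero cell in a small cohort.  The modified score
    is X'(y − p + h(½ − p)) with h the weighted-hat-matrix diagonal;
    SEs come from the Fisher information at the penalized optimum.
    ``llf`` is the Jeffreys-penalized log-likelihood.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is rank deficient")
    n, p = X.shape
    beta = np.zeros(p)

    def penalized_ll(beta):
        eta = X @ beta
        pr = 1 / (1 + np.exp(-eta))
        W = np.clip(pr * (1 - pr), 1e-12, None)
        info = X.T @ (X * W[:, None])
        sign, logdet = np.linalg.slogdet(info)
        ll = np.sum(y * eta - np.logaddexp(0, eta))
        return ll + 0.5 * logdet

    ll_old = penalized_ll(beta)
    for _ in range(max_iter):
        eta = X @ beta
        pr = 1 / (1 + np.exp(-eta))
        W = np.clip(pr * (1 - pr), 1e-12, None)
        XW = X * W[:, None]
        info = X.T @ XW
        info_inv = np.linalg.inv(info)
        Xs = X * np.sqrt(W)[:, None]
        h = np.einsum("ij,jk,ik->i", Xs, info_inv, Xs)
        score = X.T @ (y - pr + h * (0.5 - pr))
        step = info_inv @ score
        # step-halving on the penalized likelihood
        lam = 1.0
        for _ in range(20):
            ll_new = penalized_ll(beta + lam * step)
            if ll_new >= ll_old - 1e-12:
                break
            lam /= 2
        beta = beta + lam * step
        if np.max(np.abs(lam * step)) < tol * (1 + np.max(np.abs(beta))):
            ll_old = ll_new
            break
        ll_old = ll_new
    eta = X @ beta
    pr = 1 / (1 + np.exp(-eta))
    W = np.clip(pr * (1 - pr), 1e-12, None)
    info_inv = np.linalg.inv(X.T @ (X * W[:, None]))
    bse = np.sqrt(np.diag(info_inv))
    z = beta / bse
    pvals = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(beta, bse, z, pvals, float(penalized_ll(beta)), n,
                       list(names) if names is not None else [])


def pregibon_dbeta(design, labels, fit: LogisticFit) -> np.ndarray:
    """Per-observation coefficient-displacement (delta-beta) diagnostic."""
    X = np.asarray(design, dtype=float)
    y = np.asarray(labels, dtype=float)
    p = 1 / (1 + np.exp(-(X @ fit.params)))
    w = p * (1 - p)
    Xw = X * np.sqrt(w)[:, None]
    H = Xw @ np.linalg.inv(X.T @ (X * w[:, None])) @ Xw.T
    h = np.clip(np.diag(H), 0, 1 - 1e-10)
    chi = (y - p) / np.sqrt(np.maximum(w, 1e-12))
    rsp = chi / np.sqrt(1 - h)          # standardized Pearson residual
    return rsp ** 2 * h / (1 - h)


def influence_prune(design, labels, ids=None, threshold: float = 1.0,
                    cap: float = 0.05, names=None):
    """Fit, exclude observations with delta-beta > ``threshold`` (at most
    ``cap`` of rows, most influential first), refit once.

    Returns ``(pruned_fit, initial_fit, excluded_ids)``.  If pruning
    would empty a class, no pruning is applied.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(labels, dtype=float)
    ids = np.asarray(ids if ids is not None else np.arange(len(y)))
    fit0 = fit_logistic(X, y, names=names)
    dbeta = pregibon_dbeta(X, y, fit0)
    flagged = np.where(dbeta > threshold)[0]
    max_n = int(np.floor(cap * len(y)))
    if len(flagged) > max_n:
        flagged = flagged[np.argsort(dbeta[flagged])[::-1][:max_n]]
    if len(flagged) == 0:
        return fit0, fit0, []
    keep = np.ones(len(y), dtype=bool)
    keep[flagged] = False
    if len(np.unique(y[keep])) < 2:
        return fit0, fit0, []
    fit1 = fit_logistic(X[keep], y[keep], names=names)
    fit1.excluded_ids = list(ids[flagged])
    return fit1, fit0, list(ids[flagged])


def adjusted_predictor(values: pd.Series, cov_df: pd.DataFrame) -> pd.Series:
    """Robustly residualize a marker on covariates and re-standardize to
    SD 1 (the scan's '1 SD of covariate-adjusted marker' unit)."""
    if cov_df.shape[1] == 0:
        resid = values - values.mean()
    else:
        X = np.column_stack([np.ones(len(values))] + [cov_df[c].values for c in cov_df])
        fit = fit_mm(X, values.values)
        resid = pd.Series(values.values - X @ fit.params, index=values.index)
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate adjusted predictor (zero variance)")
    return resid / sd


@dataclass
class ScanProfile:
    entries: pd.DataFrame     # cutoff, n, or_, ci_low, ci_high, p, n_excluded
    axis: str                 # "age_years" | "iron_sd"
    start: float
    step: float
    selected_cutoff: float | None = None
    selection_rule: str = ""

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def _scan_grid(start: float, step: float, data_max: float) -> np.ndarray:
    """Cutoffs start, start+step, … ending at the first value whose
    subcohort (strictly below the cutoff) is the full cohort."""
    grid = [start]
    # float-safe stepping on a decimal grid
    k = 1
    while grid[-1] <= data_max:
        grid.append(round(start + k * step, 10))
        k += 1
    return np.asarray(grid)


def _scan(values: pd.Series, labels: pd.Series, cov_df: pd.DataFrame,
          axis_values: pd.Series, grid, axis_name: str, step: float,
          min_n: int = 10, min_per_class: int = 3,
          adjust_mode: str = "residualize") -> ScanProfile:
    # the marker is adjusted and standardized once over the scan
    # population, so every entry's OR is per the same 1-SD unit
    if adjust_mode == "residualize":
        adjusted = adjusted_predictor(values, cov_df)
    else:
        adjusted = values / values.std(ddof=1)
    rows = []
    for cutoff in grid:
        mask = axis_values < cutoff
        sub_v, sub_y, sub_c = adjusted[mask], labels[mask], cov_df[mask]
        row = {"cutoff": cutoff, "n": int(mask.sum()), "or": np.nan,
               "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "n_excluded": 0}
        if (len(sub_v) >= min_n
                and (sub_y == 1).sum() >= min_per_class
                and (sub_y == 0).sum() >= min_per_class):
            try:
                if adjust_mode == "residualize":
                    X = np.column_stack([np.ones(len(sub_v)), sub_v.values])
                    names = ["intercept", "marker"]
                else:
                    X = np.column_stack(
                        [np.ones(len(sub_v)), sub_v.values]
                        + [sub_c[c].values for c in sub_c])
                    names = ["intercept", "marker"] + list(sub_c.columns)
                fit, _, excl = influence_prune(X, sub_y.values,
                                               ids=sub_v.index.values, names=names)
                or_tab = fit.odds_ratios().loc["marker"]
                row.update({"or": or_tab["or"], "ci_low": or_tab["ci_low"],
                            "ci_high": or_tab["ci_high"], "p": or_tab["p"],
                            "n_excluded": len(excl)})
            except (SeparationError, ValueError, np.linalg.LinAlgError):
                pass
        rows.append(row)
    return ScanProfile(pd.DataFrame(rows), axis_name, float(grid[0]), step)


def _complete_case(df, series_list, cov_df):
    keep = np.ones(len(df), dtype=bool)
    for s in series_list:
        keep &= s.notna().values
    for c in cov_df.columns:
        keep &= cov_df[c].notna().values
    return keep


def scan_age_cutoffs(ztable, cohort, covariates=AGE_SCAN_COVARIATES,
                     start: float = 31.0, step: float = 2.0,
                     adjust_mode: str = "residualize") -> ScanProfile:
    """Serial age-cutoff OR scan: diagnosis ~ adjusted iron among
    subjects strictly younger than each cutoff (two-year steps from 31)."""
    df = cohort.df.set_index("subject_id")
    z = ztable.df["z_iron"].reindex(df.index)
    cov = encode_covariates(df, covariates)
    keep = _complete_case(df, [z, df["age_death"]], cov)
    df, z, cov = df[keep], z[keep], cov[keep]
    labels = (df["diagnosis"] == "schizophrenia").astype(int)
    grid = _scan_grid(start, step, float(df["age_death"].max()))
    prof = _scan(z, labels, cov, df["age_death"], grid, "age_years", step,
                 adjust_mode=adjust_mode)
    return prof


def scan_iron_cutoffs(ztable, cohort, covariates=IRON_SCAN_COVARIATES,
                      start: float = -1.0, step: float = 0.1,
                      adjust_mode: str = "residualize") -> ScanProfile:
    """Serial iron-cutoff OR scan: diagnosis ~ adjusted ferritin among
    subjects with harmonized iron strictly below each cutoff
    (0.1 SD steps from −1 SD)."""
    df = cohort.df.set_index("subject_id")
    z_iron = ztable.df["z_iron"].reindex(df.index)
    z_ferr = ztable.df["z_ferritin"].reindex(df.index)
    cov = encode_covariates(df, covariates)
    keep = _complete_case(df, [z_iron, z_ferr], cov)
    df, z_iron, z_ferr, cov = df[keep], z_iron[keep], z_ferr[keep], cov[keep]
    labels = (df["diagnosis"] == "schizophrenia").astype(int)
    grid = _scan_grid(start, step, float(z_iron.max()))
    return _scan(z_ferr, labels, cov, z_iron, grid, "iron_sd", step,
                 adjust_mode=adjust_mode)


def select_cutoff(profile: ScanProfile, rule: str = "max_lcb",
                  alpha: float = 0.05, min_n: int = 10,
                  lcb_penalty: float = 3.0) -> float:
    """Select the scan cutoff among entries with p < alpha and n ≥ min_n;
    ties break toward the smaller cutoff.

    Rules:

    * ``max_lcb`` (default) — maximize the penalized lower confidence
      bound |ln OR| − ``lcb_penalty``·SE.  The raw |ln OR| argmax is
      dominated by noisy small-n entries of a nested scan, while the
      Wald-z argmax drifts past the true boundary once the diluted
      effect is still significant at large n; the penalized bound is
      stable against both.  The penalty ≈3 corresponds to a ~0.1%
      two-sided normal point, a Bonferroni-style guard for the ~30
      correlated entries of a typical profile.
    * ``max_abs_lnor`` — maximize |ln OR| (treats protective and risk
      effects symmetrically).
    * ``max_or`` — maximize OR.
    * ``min_p`` — maximize the Wald z (smallest p).
    """
    e = profile.entries
    ok = e["or"].notna() & (e["p"] < alpha) & (e["n"] >= min_n)
    lnor = np.abs(np.log(e["or"]))
    with np.errstate(invalid="ignore", divide="ignore"):
        se = (np.log(e["ci_high"]) - np.log(e["ci_low"])) / (2 * stats.norm.ppf(0.975))
    if rule == "max_or":
        key = e["or"]
    elif rule == "max_abs_lnor":
        key = lnor
    elif rule == "min_p":
        key = lnor / se
    elif rule == "max_lcb":
        key = lnor - lcb_penalty * se
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    if not ok.any():
        raise ValueError("no scan entry satisfies the selection rule; relax it")
    idx = key[ok].idxmax()  # idxmax returns the first (smallest cutoff) maximum
    cutoff = float(e.loc[idx, "cutoff"])
    profile.selected_cutoff = cutoff
    profile.selection_rule = rule
    return cutoff


def subcohort_contrast(ztable, cohort, split, analyte: str, covariates,
                       efficiency: float = 0.85):
    """Group difference of the covariate-adjusted analyte within each
    side of a split (e.g. age < 35 vs age ≥ 35).

    ``split`` is ``(axis, cutoff)`` with axis ``"age"`` or ``"iron"``.
    Returns ``{"below": RobustFitResult, "above": RobustFitResult}``.
    """
    axis, cutoff = split
    df = cohort.df.set_index("subject_id")
    z = ztable.df[f"z_{analyte}"].reindex(df.index)
    cov = encode_covariates(df, covariates) if covariates else pd.DataFrame(index=df.index)
    if axis == "age":
        axis_vals = df["age_death"]
    elif axis == "iron":
        axis_vals = ztable.df["z_iron"].reindex(df.index)
    else:
        raise ValueError(f"unknown split axis {axis!r}")
    keep = _complete_case(df, [z, axis_vals], cov)
    df, z, cov, axis_vals = df[keep], z[keep], cov[keep], axis_vals[keep]
    out = {}
    for name, mask in (("below", axis_vals < cutoff), ("above", axis_vals >= cutoff)):
        sub = df[mask]
        n_case = (sub["diagnosis"] == "schizophrenia").sum()
        n_ctrl = (sub["diagnosis"] == "control").sum()
        if n_case == 0 or n_ctrl == 0:
            raise ValueError(f"stratum {name!r} ({axis} {'<' if name == 'below' else '≥'} "
                             f"{cutoff}) lacks a diagnostic group "
                             f"(controls={n_ctrl}, cases={n_case})")
        # covariate adjustment by direct inclusion: residualizing within
        # a stratum lets the robust stage treat the minority diagnostic
        # group as outliers and crush the contrast
        diag = (sub["diagnosis"] == "schizophrenia").astype(float)
        sub_cov = cov[mask]
        X = np.column_stack([np.ones(mask.sum()), diag.values]
                            + [sub_cov[c].values for c in sub_cov.columns])
        out[name] = fit_mm(X, z[mask].values, efficiency=efficiency,
                           names=["intercept", "diagnosis", *sub_cov.columns])
    return out


def subcohort_odds_ratios(ztable, cohort, split, analyte: str, covariates,
                          adjust_mode: str = "residualize") -> dict:
    """Diagnosis odds ratio per 1 SD of the covariate-adjusted analyte,
    fit separately within each side of a split (with influence pruning).

    Mirrors the subcohort prediction models: the marker is adjusted over
    the whole population (common 1-SD unit), then one pruned logistic
    fit runs per stratum.  Returns ``{"below": LogisticFit, "above":
    LogisticFit}``.
    """
    axis, cutoff = split
    df = cohort.df.set_index("subject_id")
    z = ztable.df[f"z_{analyte}"].reindex(df.index)
    cov = encode_covariates(df, covariates) if covariates else pd.DataFrame(index=df.index)
    if axis == "age":
        axis_vals = df["age_death"]
    elif axis == "iron":
        axis_vals = ztable.df["z_iron"].reindex(df.index)
    else:
        raise ValueError(f"unknown split axis {axis!r}")
    keep = _complete_case(df, [z, axis_vals], cov)
    df, z, cov, axis_vals = df[keep], z[keep], cov[keep], axis_vals[keep]
    adj = adjusted_predictor(z, cov)
    labels = (df["diagnosis"] == "schizophrenia").astype(int)
    out = {}
    for name, mask in (("below", axis_vals < cutoff), ("above", axis_vals >= cutoff)):
        sub_a, sub_y = adj[mask], labels[mask]
        if (sub_y == 1).sum() < 3 or (sub_y == 0).sum() < 3:
            raise ValueError(f"stratum {name!r} lacks class representation")
        X = np.column_stack([np.ones(len(sub_a)), sub_a.values])
        try:
            fit, _, _ = influence_prune(X, sub_y.values, ids=sub_a.index.values,
                                        names=["intercept", "marker"])
        except SeparationError:
            fit = None
        # small strata quasi-separate easily; Firth keeps the OR finite
        if fit is None or abs(fit.params[1]) > 8 or fit.bse[1] > 10:
            fit = fit_logistic_firth(X, sub_y.values,
                                     names=["intercept", "marker"])
        out[name] = fit
    return out


def predicted_probability_curve(fit: LogisticFit, grid) -> pd.DataFrame:
    """Inverse-logit of the linear predictor over a 1-D marker grid
    (intercept + marker coefficient; other covariates at 0)."""
    grid = np.asarray(grid, dtype=float)
    eta = fit.params[0] + fit.params[1] * grid if len(fit.params) > 1 \
        else np.full_like(grid, fit.params[0])
    return pd.DataFrame({"marker": grid, "probability": 1 / (1 + np.exp(-eta))})
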