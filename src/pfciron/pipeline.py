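"""End-to-end convenience driver: cohort → harmonized z-scores → group
differences → cutoff scans → subcohort contrasts → ROC/classifier.

This is the composition the numbered analysis scripts and the
acceptance machinery run; each stage is importable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pfciron.cohort_io import Cohort
from pfciron.discriminate import (
    FLAG_NAMES, auc_bootstrap_ci, build_risk_flags, combined_classifier,
    optimal_cutoff, roc_auc,
)
from pfciron.harmonize import build_zscore_table, compare_variance
from pfciron.logistic_scan import (
    AGE_SCAN_COVARIATES, IRON_SCAN_COVARIATES, adjusted_predictor,
    scan_age_cutoffs, scan_iron_cutoffs, select_cutoff, subcohort_contrast,
    subcohort_odds_ratios,
)
from pfciron.robust_linear import encode_covariates, group_difference


@dataclass
class PipelineResult:
    ztable: object
    effects: dict                      # analyte → RobustFitResult
    variance: object                   # VarianceComparison for iron
    age_scan: object
    iron_scan: object
    age_cutoff: float
    iron_cutoff: float
    age_contrast: dict                 # below/above RobustFitResult
    iron_contrast: dict
    rocs: dict                         # marker → RocResult
    classifier: object
    extras: dict = field(default_factory=dict)


def _adjusted_subset(ztable, cohort, column, covariates, mask=None):
    """Covariate-adjusted marker over (a subset of) the cohort."""
    df = cohort.df.set_index("subject_id")
    z = ztable.df[column].reindex(df.index)
    cov = encode_covariates(df, covariates)
    keep = z.notna() & cov.notna().all(axis=1)
    if mask is not None:
        keep &= mask.reindex(df.index).fillna(False)
    adj = adjusted_predictor(z[keep], cov[keep])
    labels = (df.loc[keep, "diagnosis"] == "schizophrenia").astype(int)
    return adj, labels


def run_pipeline(cohort: Cohort, seed: int = 0, B_auc: int = 500,
                 fallback_age_cutoff: float = 35.0,
                 fallback_iron_cutoff: float = 0.0,
                 age_split: float | None = None,
                 iron_split: float | None = None) -> PipelineResult:
    """Run every analysis stage on one cohort.

    ``seed`` drives the bootstrap CIs.  The subcohort boundaries default
    to the scan-selected cutoffs; ``age_split`` / ``iron_split`` pin
    them instead (e.g. the conventional age-35 / control-mean-iron
    splits), which keeps subcohort quantities comparable across
    cohorts.  If a scan has no significant entry the split falls back
    to the conventional boundary (age 35; iron z = 0).
    """
    ztable = build_zscore_table(cohort)
    df = cohort.df.set_index("subject_id")

    effects = {
        a: group_difference(ztable, a, (), cohort)
        for a in ("iron", "ferritin", "ratio", "zinc", "copper")
    }
    z_iron = ztable.df["z_iron"].reindex(df.index)
    ctrl = df["diagnosis"] == "control"
    variance = compare_variance(z_iron[ctrl], z_iron[~ctrl])

    age_scan = scan_age_cutoffs(ztable, cohort)
    iron_scan = scan_iron_cutoffs(ztable, cohort)
    try:
        age_cutoff = select_cutoff(age_scan)
    except ValueError:
        age_cutoff = fallback_age_cutoff
    try:
        iron_cutoff = select_cutoff(iron_scan)
    except ValueError:
        iron_cutoff = fallback_iron_cutoff
    if age_split is not None:
        age_cutoff = age_split
    if iron_split is not None:
        iron_cutoff = iron_split

    # a scan-selected boundary can leave a near-empty stratum on small
    # cohorts; both subcohort analyses need ≥3 per class per side, so
    # such cutoffs fall back to the conventional split (age 35; iron at
    # the control mean)
    diag = df["diagnosis"] == "schizophrenia"

    def _stratified_ok(axis_vals, cutoff):
        below = axis_vals < cutoff
        return all(((m & diag).sum() >= 3 and (m & ~diag).sum() >= 3)
                   for m in (below, ~below & axis_vals.notna()))

    if not _stratified_ok(df["age_death"], age_cutoff):
        age_cutoff = fallback_age_cutoff
    if not _stratified_ok(z_iron, iron_cutoff):
        iron_cutoff = fallback_iron_cutoff

    age_contrast = subcohort_contrast(ztable, cohort, ("age", age_cutoff),
                                      "iron", AGE_SCAN_COVARIATES)
    iron_contrast = subcohort_contrast(ztable, cohort, ("iron", iron_cutoff),
                                       "ferritin", IRON_SCAN_COVARIATES)
    age_ors = subcohort_odds_ratios(ztable, cohort, ("age", age_cutoff),
                                    "iron", AGE_SCAN_COVARIATES)
    iron_ors = subcohort_odds_ratios(ztable, cohort, ("iron", iron_cutoff),
                                     "ferritin", IRON_SCAN_COVARIATES)

    # ROC per marker over its relevant subcohort
    age_mask = df["age_death"] < age_cutoff
    lowiron_mask = z_iron < iron_cutoff
    roc_specs = {
        "iron_young": ("z_iron", AGE_SCAN_COVARIATES, age_mask, "greater"),
        "ferritin_lowiron": ("z_ferritin", IRON_SCAN_COVARIATES, lowiron_mask, "less"),
        "ratio_all": ("z_ratio", IRON_SCAN_COVARIATES, None, "greater"),
    }
    rocs, marker_cutoffs, adjusted_cols = {}, {}, {}
    for name, (col, covs, mask, direction) in roc_specs.items():
        adj, labels = _adjusted_subset(ztable, cohort, col, covs, mask)
        roc = roc_auc(adj, labels, direction=direction)
        roc.ci_low, roc.ci_high = auc_bootstrap_ci(
            adj, labels, B=B_auc, seed=seed, direction=direction)
        optimal_cutoff(roc, adj, labels)
        rocs[name] = roc
        adjusted_cols[name] = adj

    # adjusted full-cohort markers for the flags
    adj_full = pd.DataFrame({
        "iron": _adjusted_subset(ztable, cohort, "z_iron", AGE_SCAN_COVARIATES)[0],
        "ferritin": _adjusted_subset(ztable, cohort, "z_ferritin", IRON_SCAN_COVARIATES)[0],
        "ratio": _adjusted_subset(ztable, cohort, "z_ratio", IRON_SCAN_COVARIATES)[0],
    })
    flag_cutoffs = {
        "high_iron_young": rocs["iron_young"].optimal_threshold,
        "low_ferritin_low_iron": rocs["ferritin_lowiron"].optimal_threshold,
        "high_ratio": rocs["ratio_all"].optimal_threshold,
    }
    flags = build_risk_flags(ztable, cohort, age_cutoff, iron_cutoff,
                             flag_cutoffs, adjusted=adj_full)
    labels_full = (df["diagnosis"] == "schizophrenia").astype(int)
    classifier = combined_classifier(flags, labels_full)

    return PipelineResult(ztable, effects, variance, age_scan, iron_scan,
                          age_cutoff, iron_cutoff, age_contrast, iron_contrast,
                          rocs, classifier,
                          extras={"flags": flags, "flag_cutoffs": flag_cutoffs,
                                  "age_subcohort_ors": age_ors,
                                  "iron_subcohort_ors": iron_ors})
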