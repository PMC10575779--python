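#!/usr/bin/env python
"""Age–iron trajectories and the serial age-cutoff odds-ratio scan.

Fits linear vs linear-logarithmic robust models of iron on age within
each diagnostic group, runs the two-year-step age-cutoff scan of the
diagnosis OR per 1 SD covariate-adjusted iron, selects a cutoff, and
contrasts iron between groups within the young and older subcohorts.
"""

from pathlib import Path

import numpy as np

from pfciron.cohort_io import read_cohort
from pfciron.harmonize import build_zscore_table
from pfciron.logistic_scan import (
    AGE_SCAN_COVARIATES, scan_age_cutoffs, select_cutoff, subcohort_contrast,
    subcohort_odds_ratios,
)
from pfciron.robust_linear import fit_linlog_comparison

RESULTS = Path(__file__).resolve().parents[1] / "results"
CONVENTIONAL_SPLIT = 35.0


def main():
    cohort = read_cohort(RESULTS / "cohort.csv")
    ztable = build_zscore_table(cohort)
    df = cohort.df.set_index("subject_id")
    z = ztable.df["z_iron"]

    for group in ("control", "schizophrenia"):
        sel = (df["diagnosis"] == group) & z.notna() & df["age_death"].notna()
        mc = fit_linlog_comparison(df.loc[sel, "age_death"].values,
                                   z[sel].values)
        print(f"{group}: {mc.selected} model preferred; "
              f"ln(age) term t={mc.lnterm_t:.2f}, p={mc.lnterm_p:.3f}")

    profile = scan_age_cutoffs(ztable, cohort)
    try:
        cutoff = select_cutoff(profile)
        print(f"scan-selected age cutoff: {cutoff:.0f} y")
    except ValueError:
        cutoff = CONVENTIONAL_SPLIT
        print(f"no significant scan entry; using conventional {cutoff:.0f} y")
    profile.to_tsv(RESULTS / "age_scan.tsv")

    split = ("age", CONVENTIONAL_SPLIT)
    contrast = subcohort_contrast(ztable, cohort, split, "iron",
                                  AGE_SCAN_COVARIATES)
    ors = subcohort_odds_ratios(ztable, cohort, split, "iron",
                                AGE_SCAN_COVARIATES)
    for name, label in (("below", f"age<{CONVENTIONAL_SPLIT:.0f}"),
                        ("above", f"age≥{CONVENTIONAL_SPLIT:.0f}")):
        fit = contrast[name]
        lo, hi = fit.conf_int()[1]
        orr = ors[name].odds_ratios().loc["marker"]
        print(f"  {label}: iron difference {fit.params[1]:+.2f} "
              f"[{lo:.2f}, {hi:.2f}] SD (n={fit.n_used}); "
              f"OR per SD {orr['or']:.2f} [{orr['ci_low']:.2f}, {orr['ci_high']:.2f}]")


if __name__ == "__main__":
    main()
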