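#!/usr/bin/env python
"""Confounder robustness: propensity matching, zinc mediation, medication.

Checks that the diagnosis effect on iron survives regression-adjusted
propensity matching, that zinc does not mediate the iron–diagnosis
association, and that antipsychotic exposure variables are not
associated with cortical iron among cases.
"""

from pathlib import Path

import pandas as pd

from pfciron.cohort_io import read_cohort
from pfciron.confounds import mediation, medication_association, propensity_match
from pfciron.harmonize import build_zscore_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1
MATCH_COVARIATES = ("age", "sex", "ph", "pmi")


def main():
    cohort = read_cohort(RESULTS / "cohort.csv")
    ztable = build_zscore_table(cohort)
    df = cohort.df.set_index("subject_id")

    m = propensity_match(cohort, MATCH_COVARIATES, seed=SEED,
                         analyte="iron", ztable=ztable)
    balance = pd.DataFrame({"smd_pre": m.smd_pre, "smd_post": m.smd_post})
    balance.to_csv(RESULTS / "matching_balance.tsv", sep="\t")
    lo, hi = m.fit.conf_int()[1]
    print(f"propensity matching: {len(m.pairs)} pairs; "
          f"max |SMD| {balance['smd_pre'].abs().max():.2f} → "
          f"{balance['smd_post'].abs().max():.2f}")
    print(f"  post-match iron effect {m.fit.params[1]:+.2f} "
          f"[{lo:.2f}, {hi:.2f}] SD (p={m.fit.pvalues[1]:.4f})")

    med = mediation(
        ztable.df["z_iron"].reindex(df.index).values,
        ztable.df["z_zinc"].reindex(df.index).values,
        (df["diagnosis"] == "schizophrenia").astype(int).values,
        B=1000, seed=SEED)
    verdict = "covers 0 (no mediation)" \
        if med.indirect_ci[0] <= 0 <= med.indirect_ci[1] else "excludes 0"
    print(f"zinc mediation: a={med.path_a:+.3f}, b={med.path_b:+.3f}, "
          f"indirect a·b={med.indirect_effect:+.4f} "
          f"[{med.indirect_ci[0]:+.4f}, {med.indirect_ci[1]:+.4f}] — {verdict}")

    assoc = medication_association(cohort, ztable, n_perm=10000, seed=SEED,
                                   adjusters=("age_onset", "ap_duration"))
    assoc.to_csv(RESULTS / "medication_associations.tsv", sep="\t", index=False)
    cont = assoc[assoc["type"] == "continuous"]
    print("medication associations with PFC iron (cases only):")
    for _, r in cont.iterrows():
        print(f"  {r['exposure']}: r={r['estimate']:+.3f} "
              f"(perm p={r['p_permutation']:.3f}, n={r['n']})")


if __name__ == "__main__":
    main()
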