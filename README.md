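# pfciron

Case-control analysis of prefrontal-cortex (PFC) iron biology in
schizophrenia, built as a tested, reusable pipeline.

Postmortem studies of cortical trace metals face three statistical
obstacles: specimens come from multiple brain banks whose extraction
protocols put raw measurements (ICP-MS metals in µmol/g protein,
western-blot ferritin in arbitrary units) on incompatible scales; a few
specimens carry gross outlying values that wreck least-squares
estimates; and the biologically interesting effects are concentrated in
subcohorts (young adults, low-iron individuals) rather than uniform
across the cohort. `pfciron` packages the full analysis chain that
addresses all three, together with a seeded synthetic-cohort generator
that emulates the statistical structure of a three-bank schizophrenia
case-control study (85 controls / 86 cases), so every stage is testable
without any external data.

## What the pipeline computes

1. **Harmonization** — control-anchored z-scores per bank:
   z = (x − μ̂_ctrl,bank)/σ̂_ctrl,bank, applied to every subject, making
   banks commensurable; the within-subject iron-to-ferritin ratio is
   formed on the raw scale and z-scored the same way.
2. **Robust group differences** — MM-estimator regression: a
   high-breakdown S-estimate of the residual scale (Tukey bisquare,
   c_S = 1.5476, finite-sample consistency target b = ((n−p)/2n)·c²/6,
   seeded elemental-set subsampling) followed by an IRWLS M-step tuned
   to 85% Gaussian efficiency (c_M ≈ 3.4437), with sandwich standard
   errors. The diagnosis coefficient on z-scored analytes is the group
   difference in control-SD units.
3. **Trajectory models** — robust linear vs linear-logarithmic fits of
   iron on age (controls accumulate iron ∝ ln(age); cases are age-flat)
   and of ferritin on iron.
4. **Serial cutoff scans** — nested logistic fits of diagnosis on the
   covariate-adjusted marker: age cutoffs in 2-year steps from 31
   (subjects younger than the cutoff), iron cutoffs in 0.1-SD steps
   from −1 (subjects below the cutoff), each with Pregibon delta-beta
   influence pruning; a pluggable rule selects the operating cutoff.
5. **Discrimination** — ROC analysis per marker in its informative
   subcohort with bias-corrected stratified-bootstrap AUC CIs,
   Youden-optimal cutoffs, three high-risk flags, and a combined
   logistic classifier (Firth bias-reduction as a separation fallback)
   reporting sensitivity/specificity/accuracy with Clopper–Pearson CIs.
6. **Confounder machinery** — greedy caliper propensity matching with
   regression adjustment, a single-mediator path model
   (iron → zinc → diagnosis) with bootstrap CI on a·b, and
   medication-association tests with permutation p-values.

## Worked example

```sh
python analysis/01_simulate_cohort.py   # cohort + Table-1 comparison
python analysis/02_harmonize.py         # z-scores, normality, variance
python analysis/03_group_differences.py # robust diagnosis effects
python analysis/04_age_iron.py          # age trajectories + age scan
python analysis/05_iron_ferritin.py     # ferritin coupling + iron scan
python analysis/06_classification.py    # ROC + combined classifier
python analysis/07_confounders.py       # matching, mediation, medication
```

On the default seed the drivers print (abridged):

```
headline (unadjusted): iron +0.57 SD, ferritin -0.59 SD, ratio +0.74 SD
case/control iron variance ratio 2.29 (F p=0.0002, Brown–Forsythe p=0.0001)
control: linear-logarithmic model preferred; ln(age) term t=2.65, p=0.010
schizophrenia: linear-logarithmic model preferred; ln(age) term t=-0.97, p=0.336
  age<35: iron difference +1.31 [-0.29, 2.90] SD (n=30); OR per SD 3.38 [1.08, 10.62]
  age≥35: iron difference +0.41 [-0.06, 0.88] SD (n=141); OR per SD 1.52 [1.06, 2.17]
  low-iron (z<0): ferritin difference -1.09 [-1.65, -0.53] SD (n=69); OR per SD 0.413
combined classifier (n=170): accuracy 72% [65, 79]
zinc mediation: indirect a·b=+0.0532 [-0.0148, +0.1424] — covers 0 (no mediation)
```

Read: cases carry ~0.6 control-SDs more PFC iron yet ~0.6 SDs less
ferritin, with more than double the iron variance; the iron excess is
concentrated in subjects who died young (where iron confers an odds
ratio of ~3.4 per SD vs ~1.5 in older subjects), while the ferritin
deficit matters most when iron is below the control mean; combining
high-iron-young, low-ferritin-low-iron and high-ratio flags classifies
diagnosis at ~72% accuracy. Zinc does not mediate the iron effect and
antipsychotic dose/exposure show no association with cortical iron.

A `pfciron` CLI exposes the same stages (`simulate`, `summarize`,
`harmonize`, `fit`, `scan-age`, `scan-iron`, `classify`, `confounds`).

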