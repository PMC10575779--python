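# Methods

This note documents the statistical models implemented in `pfciron`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Cohort model and harmonization

A cohort is one row per postmortem specimen: diagnosis (control /
schizophrenia), source bank (NSW-BTRC, VBBN, NIMH-HBCC), demographics
(age at death in years, sex, ancestry), tissue quality (pH, postmortem
interval in hours), lifestyle (smoking, alcohol, BMI; partially
observed), analytes (iron, copper, zinc in µmol/g protein; ferritin in
arbitrary western-blot units), and, for cases only, antipsychotic
exposure variables in chlorpromazine equivalents.

Banks process tissue with different extraction buffers, so raw analyte
levels are on bank-specific multiplicative scales. Harmonization is
control-anchored z-scoring within bank: z = (x − μ̂)/σ̂ with μ̂, σ̂ the
mean and sample SD (n−1) of that bank's measured controls, applied to
all subjects of the bank. This makes bank controls exactly mean-0/SD-1
and is invariant to any affine rescaling of a bank's raw values, which
is the property that justifies pooling. It deliberately does *not*
correct higher-order batch structure (no empirical-Bayes shrinkage);
with ≥20 controls per bank the first two moments are the dominant
batch effect. Each bank needs ≥3 measured controls with nonzero SD or
harmonization refuses to run.

The iron-to-ferritin ratio — a proxy for iron not safely stored — is
computed within subject on the raw scale (iron ÷ ferritin, missing when
ferritin ≤ 0) and then z-scored per bank like any other analyte. We
chose the raw-ratio-then-z route over a ratio of z-scores because the
latter is undefined near zero and has no physical unit.

## Robust regression (MM estimator)

Group differences and trajectory models use an MM estimator, which
combines a high-breakdown scale estimate with an efficient M-step:

1. **S-stage.** Candidate coefficient vectors come from exact fits on
   random p-point elemental subsets (default 500, seeded by a
   row-order-invariant hash of the data, so repeated calls are
   deterministic and row order does not matter). Each candidate is
   scored by the M-scale σ̂ solving (1/n)Σρ(r_i/σ̂) = b with the Tukey
   bisquare ρ at c_S = 1.5476. We use the finite-sample consistency
   target b = ((n−p)/2n)·(c_S²/6) rather than the asymptotic
   b = (c_S²/6)/2: with many parameters relative to n, the asymptotic
   50%-breakdown target lets the S-stage fit an overfit hyperplane
   through a bare majority and discard a genuine data mode (observed in
   22-subject strata with 6 parameters, where the higher-variance case
   group was treated wholesale as outliers). The finite-sample b
   converges to the asymptotic one as n/p grows. Candidate screening
   uses the standard fast-S trick (a candidate can only beat the
   incumbent scale if its mean ρ at that scale is below b); the best
   three candidates are refined by IRWLS to a local S minimum. If a
   majority of residuals is exactly zero the fit is flagged degenerate
   and returned as an exact fit.
2. **M-stage.** With σ̂ frozen, IRWLS with bisquare ψ at the constant
   implied by the target Gaussian efficiency (85% default, c ≈ 3.4437;
   95% optional, c ≈ 4.6851), iterated from the S coefficients to
   relative change < 1e-8 (max 500 iterations; non-convergence is
   flagged, never silent).

Standard errors use the M-estimator sandwich
σ̂²·mean(ψ²)/mean(ψ′)²·(XᵀX)⁻¹ with an n/(n−p) small-sample factor;
p-values refer t = β̂/SE to a t distribution with n−p degrees of
freedom. Model comparison (linear vs linear-logarithmic in age or
iron) uses the robust deviance Σρ(r/σ) at the smaller of the two
S-scales; parameter counts are equal, ties prefer the linear model.

## Serial cutoff scans and cutoff selection

The scans ask *where* a marker is diagnostic. For each cutoff on a
fixed grid (ages 31, 33, 35, … until the subcohort is the full cohort;
iron z from −1.0 in 0.1 steps) the scan restricts to subjects strictly
below the cutoff and fits a logistic model of diagnosis on the
covariate-adjusted marker. Covariate adjustment is residualization:
the marker is robustly regressed on the covariates **once over the
whole scan population** and the residuals standardized to SD 1, so
every entry's odds ratio is per the same 1-SD unit (adjusting within
each subset would change the unit entry by entry). Entering the
covariates directly into each logistic model is available as an
option. Entries with n < 10 or fewer than 3 subjects per class are
recorded as missing. Each fit applies Pregibon delta-beta influence
pruning: observations with χ²·h/(1−h)² > 1 (standardized Pearson
residual χ, leverage h) are removed — at most 5% of rows — and the
model is refit once.

Cutoff selection is a pluggable rule over the profile's significant
entries (p < 0.05, n ≥ 10). The default maximizes the penalized lower
confidence bound |ln OR| − 3·SE. The two simpler rules fail in
characteristic ways on nested profiles: the raw |ln OR| argmax is
dominated by noisy small-n entries at the start of the grid, and the
Wald-z argmax (min p) drifts past the true boundary because a diluted
effect stays significant as n grows. The penalized bound is stable
against both; the penalty 3 is a Bonferroni-style guard corresponding
to a ~0.1% two-sided normal point for the ~30 correlated entries of a
typical profile. Monte-Carlo localization experiments (effects planted
with a known boundary) recover the boundary within ±5 years / ±0.3 SD
in ≳90% of seeds under this rule.

Subcohort contrasts (e.g. iron by diagnosis within age<35 vs ≥35) fit
z ~ diagnosis + covariates robustly within each stratum, reporting the
diagnosis coefficient in control-SD units. Here the covariates enter
the model directly: residualizing first and refitting on residuals
lets the robust stage treat the stratum's minority diagnostic group as
outliers, collapsing a real contrast. Subcohort odds-ratio models keep
the residualized 1-SD unit for comparability with the scans.

## Discrimination

Per-marker ROC analysis runs in the marker's informative subcohort
(iron among subjects younger than the age split; ferritin among
subjects below the iron split, oriented so low ferritin is case-like;
ratio in the full cohort). AUC is the rank (Mann–Whitney) statistic
with ties counted half. CIs are bias-corrected (BC, not BCa)
percentile intervals from a stratified bootstrap (resampling within
class; B = 2000 default, 500 in the replicated acceptance runs),
seeded; degenerate resamples are redrawn with a retry cap. Operating
cutoffs maximize Youden's J over midpoints between adjacent distinct
scores, ties toward higher specificity; accuracy-maximizing selection
is available.

The three binary risk flags are: high iron among the young (defined
only for age < age split), low ferritin among the low-iron (defined
only below the iron split), and high ratio (defined everywhere).
Out-of-domain flags are false, with an explicit applicability column,
so the combined logistic model can use every subject with complete
markers. The combined model's probability cutoff is chosen by Youden
on the fitted probabilities; sensitivity, specificity and accuracy get
exact Clopper–Pearson CIs. Because three dichotomized flags at n ≈ 170
can produce a zero cell, the combined fit falls back to Firth's
bias-reduced logistic (Jeffreys-prior penalized score) when the plain
MLE is separated; the plain fitter itself reports separation as an
error rather than returning divergent coefficients. Nested classifier
comparisons use the likelihood-ratio test with χ² reference and AIC.

## Confounder machinery

Propensity matching: logistic propensity of case status on the chosen
covariates; 1:1 greedy nearest-neighbour matching on the logit
propensity without replacement, in seeded random case order, caliper
0.2 SD of the logit propensity; balance is reported as standardized
mean differences before/after; the matched-set group difference is
re-estimated by the robust regression (regression adjustment). Greedy
rather than optimal matching keeps the procedure deterministic under
seed; at n ≈ 170 the difference is negligible.

Mediation (iron → zinc → diagnosis) is a single-mediator
product-of-coefficients path model: path a from a robust linear fit of
the mediator on the exposure, paths b and c′ from a logistic fit of
the outcome on exposure + mediator; the indirect effect is exactly
a·b, with a seeded percentile bootstrap CI (B = 1000). A full
latent-variable SEM engine is out of scope — one exposure, one
mediator, one binary outcome is all the analysis requires.

Medication associations (cases only): Pearson correlation (Spearman
optional) for continuous exposures with a seeded permutation p-value
(10,000 permutations, p on the (k+1)/(B+1) grid) next to the
parametric one, partial correlations given adjusters (age of onset,
treatment duration), and robust group contrasts for categorical
exposures (typicality, toxicology flags).

## Synthetic cohort generator

The generator emulates the study's statistical structure, not its raw
instrument output. Defaults encode the study conditions:

* n = 85 controls / 86 cases; banks at 0.44/0.21/0.35; ages truncated
  normal 54.4 ± 14.9 [17, 85] (controls) and 52.6 ± 16.2 [17, 84]
  (cases); pH 6.54 ± 0.29 / 6.49 ± 0.28; PMI 33.1 ± 15.3 /
  36.5 ± 18.4 h; smoking 33%/74%; alcohol 22%/47%; non-natural death
  7%/36%; BMI 29.3 ± 6.1 / 27.9 ± 6.2.
* Control iron: intercept −3.905 + 4.203·ln(age) µmol/g with Gaussian
  residual SD 4.503, giving marginal mean 12.7 µmol/g and SD
  4.655 µmol/g (the SD back-derived from a printed 95% CI half-width
  of 1.5 µmol/g at n = 37) and an age–iron correlation of 0.254
  (t ≈ 2.4 at n = 85). Case iron is age-flat with mean shifted +0.58
  control-SDs and variance ×2.2; draws are truncated at a small
  positive floor with the location solved so the truncated mean equals
  the planted one.
* Ferritin: 8.622 + 0.562·ln(iron) a.u. with residual SD 0.960
  (control marginal SD 1 a.u., iron–ferritin correlation 0.279) and a
  case offset of −0.552 a.u., solved so the *marginal* case-control
  ferritin difference is −0.45 control-SDs after the iron-mediated
  uplift. Consequence: the conditional ferritin deficit at fixed iron
  is ≈ −0.55 SD, so low-iron subcohort contrasts are expected somewhat
  weaker than in a cohort whose conditional deficit is larger; the
  within-group ferritin noise scale is a free parameter with no
  published anchor.
* Zinc (+0.28 SD case shift) and copper (no shift) are correlated with
  the subject's within-group iron deviation (r = 0.3 each).
* Bank scale factors (1.0 / 0.6 / 1.5) multiply all raw analytes;
  harmonization must cancel them exactly.
* Medication variables exist for a random half of cases (missing
  completely at random); other missingness rates follow the observed
  per-variable availability (copper 20%, smoking 34%, alcohol 68%,
  BMI 40%, ferritin 1%, iron 0.5%).

Noise is Gaussian on the raw scale; heavy-tailed contamination is
added only explicitly via `inject_outliers` (each record's iron
inflated by a chosen number of SDs with a chosen probability, flagged
in a provenance column). Passing tests on these cohorts therefore
demonstrates correctness of the estimators and the pipeline's operating
characteristics under the planted structure — not that real cortical
iron is Gaussian, that real banks differ only by a scale factor, or
that real missingness is random. Influence pruning, in particular,
excludes ≈0 observations on clean synthetic cohorts; the ~1% exclusion
rate reported for real data reflects contamination the default
generator deliberately omits.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of n = 171 (the
study size), with Monte-Carlo loops of 25–200 replicates and bootstrap
sizes of 200–2000 chosen so each suite completes in minutes on one
CPU. The acceptance script averages the pipeline over six replicate
cohorts so reported values reflect the planted conditions rather than
one cohort's noise, and pins the subcohort splits at the conventional
boundaries (age 35; iron at the control mean) for cross-replicate
comparability. Scale root-finding uses bracketed Brent iteration
(xtol 1e-12); logistic fits are Newton/IRLS via statsmodels with
explicit separation detection; all bootstrap, permutation, matching
and subsampling randomness is seeded, with the S-stage seed derived
from the data so identical inputs give identical fits.

## Known limitations

* The harmonization corrects only location and scale per bank.
* The exact robust-regression settings of the original analyses
  (efficiency, tuning constants, influence threshold) are not
  published; coefficients from other implementations may differ in the
  second decimal.
* The combined classifier is evaluated in-sample, as in the source
  analysis; no cross-validation is claimed.
* The scan selection rule is a design choice; all rules are exposed
  and profiles are emitted in full so any rule can be re-applied.

One subtlety of the planted conditions: case iron is a positivity-
truncated Gaussian (location solved so the truncated mean equals the
planted one), which is mildly right-skewed. The MM estimator targets
the bisquare location, which for a right-skewed distribution sits
slightly below the mean, so the robust group effect under these
conditions centers a few hundredths of an SD below the planted mean
shift — an estimand difference, not an estimator defect; OLS on the
same cohorts recovers the planted shift.
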