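"""Logistic fits, influence pruning, serial cutoff scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pfciron.harmonize import build_zscore_table
from pfciron.logistic_scan import (
    ScanProfile, SeparationError, _scan_grid, fit_logistic, influence_prune,
    predicted_probability_curve, scan_age_cutoffs, scan_iron_cutoffs,
    select_cutoff, subcohort_contrast,
)
from conftest import simple_onebank_cohort


def _design(x):
    x = np.asarray(x, dtype=float)
    return np.column_stack([np.ones(len(x)), x])


class TestFitLogistic:
    def test_two_by_two_or_closed_form(self):
        """Single binary predictor: fitted OR equals ad/bc = (30·30)/(10·10)."""
        x = np.array([1] * 40 + [0] * 40)
        y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
        fit = fit_logistic(_design(x), y, names=["intercept", "exposed"])
        assert np.exp(fit.params[1]) == pytest.approx(9.0, rel=1e-6)

    def test_null_predictor_ci_covers_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        y = rng.integers(0, 2, 2000)
        fit = fit_logistic(_design(x), y, names=["intercept", "x"])
        or_row = fit.odds_ratios().iloc[1]
        assert or_row["ci_low"] < 1 < or_row["ci_high"]

    def test_matches_brute_force_likelihood_grid(self):
        """MLE agrees with direct likelihood maximization on a 12-point toy."""
        x = np.array([-2.1, -1.5, -1.0, -0.6, -0.2, 0.1, 0.4, 0.8, 1.2, 1.7, 2.0, 2.4])
        y = np.array([0, 0, 0, 1, 0, 0, 1, 1, 0, 1, 1, 1])
        fit = fit_logistic(_design(x), y)

        def nll(b):
            eta = b[0] + b[1] * x
            return -(y * eta - np.log1p(np.exp(eta))).sum()

        opt = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12}).x
        np.testing.assert_allclose(fit.params, opt, atol=1e-4)

    def test_label_swap_inverts_or(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 300)
        y = (rng.random(300) < 1 / (1 + np.exp(-x))).astype(int)
        a = fit_logistic(_design(x), y)
        b = fit_logistic(_design(x), 1 - y)
        assert np.exp(b.params[1]) == pytest.approx(1 / np.exp(a.params[1]), rel=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(_design([1, 2, 3]), [1, 1, 1])

    def test_complete_separation_flagged(self):
        x = np.array([-3.0, -2, -1, 1, 2, 3])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(SeparationError):
            fit_logistic(_design(x), y)


class TestInfluencePrune:
    def test_clean_balanced_data_no_exclusions(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 400)
        y = (rng.random(400) < 1 / (1 + np.exp(-x))).astype(int)
        fit, fit0, excluded = influence_prune(_design(x), y)
        assert excluded == []
        assert fit is fit0

    def test_planted_influential_point_excluded(self):
        """A high-leverage, label-discordant point is excluded, and
        leave-one-out confirms it moves the coefficients the most."""
        rng = np.random.default_rng(3)
        n = 80
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
        x = np.append(x, 8.0)
        y = np.append(y, 0)          # discordant extreme point
        ids = np.arange(len(x))
        fit, fit0, excluded = influence_prune(_design(x), y, ids=ids)
        assert len(x) - 1 in excluded

        full = fit_logistic(_design(x), y).params
        shifts = []
        for i in range(len(x)):
            keep = np.ones(len(x), bool)
            keep[i] = False
            shifts.append(np.linalg.norm(
                fit_logistic(_design(x)[keep], y[keep]).params - full))
        assert int(np.argmax(shifts)) == len(x) - 1

    def test_cap_respected(self):
        rng = np.random.default_rng(4)
        n = 100
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        _, _, excluded = influence_prune(_design(x), y, threshold=0.0, cap=0.05)
        assert len(excluded) <= 5


class TestScanGrid:
    def test_age_grid_spec(self):
        grid = _scan_grid(31.0, 2.0, 84.6)
        assert grid[0] == 31.0
        assert np.allclose(np.diff(grid), 2.0)
        assert grid[-2] <= 84.6 < grid[-1]

    def test_iron_grid_spec(self):
        grid = _scan_grid(-1.0, 0.1, 2.34)
        np.testing.assert_allclose(grid[:4], [-1.0, -0.9, -0.8, -0.7], atol=1e-12)
        assert grid[-1] > 2.34 >= grid[-2]


def _confined_effect_cohort(seed, boundary=40.0, shift=1.8):
    """Iron mean-shift confined to young cases (age < boundary)."""
    def iron_fn(rng, age, is_case):
        base = rng.normal(12, 3, len(age))
        return base + np.where(is_case & (age < boundary), shift * 3, 0.0)
    return simple_onebank_cohort(85, 86, iron_fn, seed=seed)


def _planted_or_age_cohort(seed, boundary=40.0, lnor=np.log(4), n=171,
                           age_hi=60.0):
    """Diagnosis drawn from a logistic model: OR 4 per SD iron below the
    age boundary, OR 1 above it."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(18, age_hi, n)
    z = rng.normal(0, 1, n)
    p = np.where(age < boundary, 1 / (1 + np.exp(-lnor * z)), 0.5)
    is_case = rng.random(n) < p
    df = pd.DataFrame({
        "subject_id": [f"T{i}" for i in range(n)], "bank": "NSW-BTRC",
        "diagnosis": np.where(is_case, "schizophrenia", "control"),
        "age_death": age, "sex": "M", "ancestry": "Caucasian",
        "ph": 6.5, "pmi": 30.0, "death_mode": "natural",
        "iron": 12 + 3 * z, "ferritin": rng.normal(10, 1, n)})
    from conftest import make_cohort
    return make_cohort(df)


def _planted_or_iron_cohort(seed, lnor=np.log(4), n=171):
    """Protective ferritin effect (OR 1/4 per SD) confined to subjects
    with below-mean iron (z_iron < 0)."""
    rng = np.random.default_rng(seed)
    zi, zf = rng.normal(0, 1, n), rng.normal(0, 1, n)
    p = np.where(zi < 0, 1 / (1 + np.exp(lnor * zf)), 0.5)
    is_case = rng.random(n) < p
    df = pd.DataFrame({
        "subject_id": [f"T{i}" for i in range(n)], "bank": "NSW-BTRC",
        "diagnosis": np.where(is_case, "schizophrenia", "control"),
        "age_death": rng.uniform(18, 80, n), "sex": "M",
        "ancestry": "Caucasian", "ph": 6.5, "pmi": 30.0,
        "death_mode": "natural",
        "iron": 12 + 3 * zi, "ferritin": 10 + zf})
    from conftest import make_cohort
    return make_cohort(df)


class TestAgeScan:
    def test_all_old_cohort_has_leading_missing_entries(self):
        coh = simple_onebank_cohort(40, 40, lambda r, a, c: r.normal(12, 3, len(a)),
                                    seed=5, age_lo=50.0, age_hi=80.0)
        zt = build_zscore_table(coh, analytes=("iron",))
        prof = scan_age_cutoffs(zt, coh, covariates=())
        e = prof.entries
        assert e.loc[e["cutoff"] <= 50, "or"].isna().all()
        assert e["or"].notna().any()

    def test_localizes_planted_age_boundary(self):
        """OR-4 iron effect confined to age<40 ⇒ selected cutoff lands in
        [35,45] in ≥80% of seeds."""
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            coh = _planted_or_age_cohort(seed)
            zt = build_zscore_table(coh, analytes=("iron",))
            prof = scan_age_cutoffs(zt, coh, covariates=())
            try:
                cutoff = select_cutoff(prof)
            except ValueError:
                continue
            hits += 35.0 <= cutoff <= 45.0
        assert hits / n_seeds >= 0.8


class TestIronScan:
    def test_localizes_low_iron_ferritin_deficit(self):
        """Protective ferritin effect confined to below-mean iron ⇒
        selected cutoff within 0.3 SD of the boundary in ≥80% of seeds."""
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            coh = _planted_or_iron_cohort(seed)
            zt = build_zscore_table(coh, analytes=("iron", "ferritin"))
            prof = scan_iron_cutoffs(zt, coh, covariates=())
            try:
                cutoff = select_cutoff(prof)
            except ValueError:
                continue
            hits += abs(cutoff - 0.0) <= 0.3
        assert hits / n_seeds >= 0.8


class TestSelectCutoff:
    def _profile(self, ors, ps, ns=None):
        e = pd.DataFrame({
            "cutoff": np.arange(len(ors), dtype=float),
            "n": ns if ns is not None else [50] * len(ors),
            "or": ors, "ci_low": np.nan, "ci_high": np.nan, "p": ps,
            "n_excluded": 0})
        return ScanProfile(e, "age_years", 0.0, 1.0)

    def test_monotone_profile_selects_last(self):
        prof = self._profile([1.5, 2.0, 3.0, 4.0], [0.01] * 4)
        assert select_cutoff(prof, rule="max_abs_lnor") == 3.0

    def test_single_significant_entry(self):
        prof = self._profile([2.0, 5.0, 1.5], [0.2, 0.01, 0.3])
        assert select_cutoff(prof, rule="max_abs_lnor") == 1.0

    def test_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            ors = np.exp(rng.normal(0, 1, 15))
            ps = rng.random(15)
            ns = rng.integers(5, 100, 15)
            prof = self._profile(ors, ps, ns)
            ok = (ps < 0.05) & (ns >= 10)
            if not ok.any():
                with pytest.raises(ValueError):
                    select_cutoff(prof, rule="max_abs_lnor")
                continue
            brute = np.where(ok, np.abs(np.log(ors)), -np.inf).argmax()
            assert select_cutoff(prof, rule="max_abs_lnor") == float(brute)

    def test_protective_or_counts_by_distance_from_one(self):
        prof = self._profile([0.1, 2.0], [0.01, 0.01])
        assert select_cutoff(prof, rule="max_abs_lnor") == 0.0   # |ln 0.1| > |ln 2|


class TestSubcohortContrast:
    def test_confined_effect_contrast(self):
        coh = _confined_effect_cohort(0)
        zt = build_zscore_table(coh, analytes=("iron",))
        res = subcohort_contrast(zt, coh, ("age", 40.0), "iron", ())
        assert res["below"].params[1] > res["above"].params[1] + 0.5

    def test_empty_stratum_errors(self):
        coh = simple_onebank_cohort(30, 30, lambda r, a, c: r.normal(12, 3, len(a)),
                                    seed=7, age_lo=50.0, age_hi=80.0)
        zt = build_zscore_table(coh, analytes=("iron",))
        with pytest.raises(ValueError, match="below"):
            subcohort_contrast(zt, coh, ("age", 30.0), "iron", ())


class TestPredictedProbabilities:
    def test_closed_form(self):
        from pfciron.logistic_scan import LogisticFit
        fit = LogisticFit(np.array([-0.5, 1.2]), np.zeros(2), np.zeros(2),
                          np.zeros(2), 0.0, 10)
        grid = np.linspace(-3, 3, 7)
        curve = predicted_probability_curve(fit, grid)
        np.testing.assert_allclose(
            curve["probability"], 1 / (1 + np.exp(-(-0.5 + 1.2 * grid))), rtol=1e-12)
        assert ((curve["probability"] > 0) & (curve["probability"] < 1)).all()

    def test_intercept_only_predicts_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_logistic(np.ones((100, 1)), y)
        curve = predicted_probability_curve(fit, [0.0, 1.0])
        np.testing.assert_allclose(curve["probability"], 0.3, rtol=1e-6)


class TestFirth:
    def test_finite_under_complete_separation(self):
        from pfciron.logistic_scan import fit_logistic_firth
        x = np.array([-3.0, -2, -1, 1, 2, 3])
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_logistic_firth(_design(x), y)
        assert np.all(np.isfinite(fit.params))
        assert np.all(np.isfinite(fit.bse))
        assert abs(fit.params[1]) < 10

    def test_close_to_mle_when_well_behaved(self):
        from pfciron.logistic_scan import fit_logistic_firth
        rng = np.random.default_rng(12)
        n = 2000
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(int)
        mle = fit_logistic(_design(x), y)
        firth = fit_logistic_firth(_design(x), y)
        np.testing.assert_allclose(firth.params, mle.params, atol=0.05)
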