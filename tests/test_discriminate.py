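"""ROC/AUC, bootstrap CIs, cutoffs, risk flags, combined classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pfciron.discriminate import (
    auc_bootstrap_ci, build_risk_flags, combined_classifier,
    compare_nested_models, optimal_cutoff, roc_auc,
)
from pfciron.harmonize import build_zscore_table
from pfciron.logistic_scan import fit_logistic
from conftest import simple_onebank_cohort


def brute_force_auc(scores, labels):
    """All-pairs probability that a case outranks a control, ties 0.5."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    cases, ctrls = s[y == 1], s[y == 0]
    wins = sum(1.0 if c > k else (0.5 if c == k else 0.0)
               for c, k in itertools.product(cases, ctrls))
    return wins / (len(cases) * len(ctrls))


class TestAuc:
    def test_printed_toy_triple(self):
        scores = [2, 3, 4, 1, 2, 3]
        labels = [1, 1, 1, 0, 0, 0]
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(7 / 9, rel=1e-12)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_perfect_separation(self):
        r = roc_auc([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert r.auc == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(2, 25), st.integers(2, 25), st.integers(0, 10 ** 6))
    def test_matches_all_pairs_brute_force(self, n1, n0, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(0, 1, n1 + n0), 1)  # rounding forces ties
        labels = np.array([1] * n1 + [0] * n0)
        if len(np.unique(scores)) < 2:
            return
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_label_swap_complement(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        a = roc_auc(scores, labels)
        b = roc_auc(scores, 1 - labels)
        assert b.auc == pytest.approx(1 - a.auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestBootstrapCI:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        s = rng.normal(0, 1, 80)
        y = rng.integers(0, 2, 80)
        a = auc_bootstrap_ci(s, y, B=200, seed=5)
        b = auc_bootstrap_ci(s, y, B=200, seed=5)
        assert a == b

    def test_degenerate_scores_collapse_to_point(self):
        s = np.array([1.0] * 10 + [2.0] * 10)
        y = np.array([0] * 10 + [1] * 10)
        lo, hi = auc_bootstrap_ci(s, y, B=150, seed=0)
        assert lo == hi == 1.0

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            y = np.array([1] * 40 + [0] * 40)
            s = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
            from sklearn.metrics import roc_auc_score
            point = roc_auc_score(y, s)
            lo, hi = auc_bootstrap_ci(s, y, B=300, seed=seed)
            assert lo <= point <= hi

    def test_coverage_near_nominal(self):
        """BC interval coverage ≈ 95% ± 4% at true AUC 0.75 (binormal
        model), 200 Monte-Carlo reps, B=500."""
        delta = np.sqrt(2) * 0.6744897501960817  # Φ(δ/√2)=0.75
        rng = np.random.default_rng(4)
        cover = 0
        reps = 200
        for i in range(reps):
            s = np.concatenate([rng.normal(delta, 1, 50), rng.normal(0, 1, 50)])
            y = np.array([1] * 50 + [0] * 50)
            lo, hi = auc_bootstrap_ci(s, y, B=500, seed=i)
            cover += lo <= 0.75 <= hi
        assert cover / reps == pytest.approx(0.95, abs=0.04)


class TestOptimalCutoff:
    def test_perfect_separation_midpoint(self):
        s = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        r = optimal_cutoff(roc_auc(s, y), s, y)
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 3.0 < r.optimal_threshold < 10.0
        assert r.optimal_threshold == pytest.approx(6.5)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = np.round(rng.normal(0, 1, 40), 1)
            y = rng.integers(0, 2, 40)
            if y.sum() in (0, 40) or len(np.unique(s)) < 2:
                continue
            r = optimal_cutoff(roc_auc(s, y), s, y)
            best_j = max(
                ((s > t) & (y == 1)).sum() / (y == 1).sum()
                + (~(s > t) & (y == 0)).sum() / (y == 0).sum() - 1
                for t in np.concatenate([s - 1e-9, [s.max() + 1]]))
            got_j = r.sensitivity + r.specificity - 1
            assert got_j == pytest.approx(best_j, abs=1e-9)

    def test_direction_convention(self):
        """For a marker lower in cases the flag is score *below* cutoff."""
        s = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        y = np.array([1, 1, 1, 0, 0, 0])
        r = optimal_cutoff(roc_auc(s, y, direction="less"), s, y)
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 3.0 < r.optimal_threshold < 10.0

    def test_accuracy_identity(self):
        rng = np.random.default_rng(6)
        s = rng.normal(0, 1, 50)
        y = rng.integers(0, 2, 50)
        if y.sum() in (0, 50):
            y[0] = 1 - y[0]
        r = optimal_cutoff(roc_auc(s, y), s, y)
        pred = s > r.optimal_threshold
        tp = (pred & (y == 1)).sum()
        tn = (~pred & (y == 0)).sum()
        assert r.accuracy == pytest.approx((tp + tn) / len(y))


class TestRiskFlags:
    def _fixture(self):
        rng = np.random.default_rng(7)
        n = 20
        df = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "age_death": rng.uniform(20, 80, n),
        })
        z = pd.DataFrame({
            "z_iron": rng.normal(0, 1, n),
            "z_ferritin": rng.normal(0, 1, n),
            "z_ratio": rng.normal(0, 1, n),
        }, index=df["subject_id"].values)
        return df, z

    def test_rule_by_rule_recomputation(self):
        from conftest import make_cohort

        df, z = self._fixture()
        coh = make_cohort(df.assign(bank="VBBN", diagnosis="control", sex="M",
                                    ancestry="Caucasian", ph=6.5, pmi=30,
                                    death_mode="natural"))

        class ZT:
            pass

        zt = ZT()
        zt.df = z
        cuts = {"high_iron_young": 0.4, "low_ferritin_low_iron": -0.3,
                "high_ratio": 0.2}
        flags = build_risk_flags(zt, coh, age_cutoff=35.0, iron_cutoff=0.0,
                                 marker_cutoffs=cuts)
        age = df.set_index("subject_id")["age_death"]
        for sid in df["subject_id"]:
            young = age[sid] < 35.0
            assert flags.loc[sid, "high_iron_young"] == \
                (young and z.loc[sid, "z_iron"] > 0.4)
            assert flags.loc[sid, "high_iron_young_applicable"] == young
            low = z.loc[sid, "z_iron"] < 0.0
            assert flags.loc[sid, "low_ferritin_low_iron"] == \
                (low and z.loc[sid, "z_ferritin"] < -0.3)
            assert flags.loc[sid, "high_ratio"] == (z.loc[sid, "z_ratio"] > 0.2)

    def test_old_subject_flag1_not_applicable(self):
        from conftest import make_cohort

        df, z = self._fixture()
        df.loc[0, "age_death"] = 80.0
        coh = make_cohort(df.assign(bank="VBBN", diagnosis="control", sex="M",
                                    ancestry="Caucasian", ph=6.5, pmi=30,
                                    death_mode="natural"))

        class ZT:
            pass

        zt = ZT()
        zt.df = z
        flags = build_risk_flags(zt, coh, 35.0, 0.0,
                                 {"high_iron_young": 0, "low_ferritin_low_iron": 0,
                                  "high_ratio": 0})
        sid = df.loc[0, "subject_id"]
        assert not flags.loc[sid, "high_iron_young_applicable"]
        assert not flags.loc[sid, "high_iron_young"]


class TestCombinedClassifier:
    def _flags(self, F, index):
        F = F.copy()
        F["classifiable"] = True
        F.index = index
        return F

    def test_uninformative_flags_predict_prevalence(self):
        n = 100
        idx = [f"S{i}" for i in range(n)]
        F = self._flags(pd.DataFrame({
            "high_iron_young": [False] * n,
            "low_ferritin_low_iron": [False] * n,
            "high_ratio": [False] * n}), idx)
        y = pd.Series([1] * 60 + [0] * 40, index=idx)
        with pytest.raises(Exception):
            # all-constant design is rank deficient beyond the intercept
            combined_classifier(F, y)

    def test_planted_flag_effects_beat_baseline(self):
        """Flags with OR≈4 each: combined accuracy exceeds the
        majority-class baseline in ≥95% of seeds."""
        wins, n_seeds = 0, 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 170
            y = np.array([1] * 85 + [0] * 85)
            F = pd.DataFrame({
                name: rng.random(n) < np.where(y == 1, 0.5, 0.2)
                for name in ("high_iron_young", "low_ferritin_low_iron", "high_ratio")
            })
            idx = [f"S{i}" for i in range(n)]
            flags = self._flags(F, idx)
            rep = combined_classifier(flags, pd.Series(y, index=idx))
            wins += rep.accuracy > 0.5
        assert wins / n_seeds >= 0.95

    def test_report_identities(self):
        rng = np.random.default_rng(8)
        n = 120
        y = np.array([1] * 60 + [0] * 60)
        F = pd.DataFrame({
            name: rng.random(n) < np.where(y == 1, 0.6, 0.25)
            for name in ("high_iron_young", "low_ferritin_low_iron", "high_ratio")})
        idx = [f"S{i}" for i in range(n)]
        rep = combined_classifier(self._flags(F, idx), pd.Series(y, index=idx))
        c = rep.confusion
        assert c["tp"] + c["fp"] + c["tn"] + c["fn"] == rep.n_classified
        assert rep.accuracy == pytest.approx((c["tp"] + c["tn"]) / rep.n_classified)
        assert rep.cases_perturbed_fraction == pytest.approx(rep.sensitivity)
        assert rep.controls_intact_fraction == pytest.approx(rep.specificity)
        assert rep.accuracy_ci[0] <= rep.accuracy <= rep.accuracy_ci[1]


class TestNestedModels:
    def _fit(self, X, y, names):
        return fit_logistic(X, y, names=names)

    def test_equal_models_lr_zero(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 100)
        y = (rng.random(100) < 1 / (1 + np.exp(-x))).astype(int)
        X = np.column_stack([np.ones(100), x])
        fit = self._fit(X, y, ["intercept", "x"])
        r = compare_nested_models(fit, fit)
        assert r["lr"] == pytest.approx(0.0, abs=1e-10)
        assert r["p"] == 1.0

    def test_lr_nonnegative_and_null_distribution(self):
        """Adding a pure-noise predictor: LR ~ χ²(1) under the null."""
        rng = np.random.default_rng(10)
        lrs = []
        for _ in range(300):
            n = 120
            x = rng.normal(0, 1, n)
            noise = rng.normal(0, 1, n)
            y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
            Xr = np.column_stack([np.ones(n), x])
            Xf = np.column_stack([Xr, noise])
            r = compare_nested_models(
                self._fit(Xf, y, ["intercept", "x", "noise"]),
                self._fit(Xr, y, ["intercept", "x"]))
            assert r["lr"] >= 0
            lrs.append(r["lr"])
        from scipy import stats
        # Kolmogorov–Smirnov against χ²(1)
        d, p = stats.kstest(lrs, "chi2", args=(1,))
        assert p > 0.01

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 100)
        z = rng.normal(0, 1, 100)
        y = (rng.random(100) < 0.5).astype(int)
        a = self._fit(np.column_stack([np.ones(100), x]), y, ["intercept", "x"])
        b = self._fit(np.column_stack([np.ones(100), z]), y, ["intercept", "z"])
        with pytest.raises(ValueError):
            compare_nested_models(a, b)
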