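"""Evaluation: confusion metrics, rank AUC, bootstrap CIs, the null baseline,
threshold sweeps, and the three-way overfitting report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import f1_score, roc_auc_score

from pcuste import (
    BootstrapConfig,
    CohortSchema,
    CohortTable,
    ThresholdPolicy,
    auc_rank,
    bootstrap_ci,
    confusion,
    metrics_from_confusion,
    null_model_report,
    overfit_report,
    threshold_sweep,
)
from pcuste.evaluation import ConfusionCounts, evaluate_scores


class TestConfusionMetrics:
    def test_formula_oracle(self):
        # TP=3 FN=1 TN=90 FP=10
        y = [1] * 4 + [0] * 100
        p = [1, 1, 1, 0] + [1] * 10 + [0] * 90
        c = confusion(y, p)
        assert (c.tp, c.fn, c.tn, c.fp) == (3, 1, 90, 10)
        m = metrics_from_confusion(c)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(0.90)
        mcc = (3 * 90 - 10 * 1) / np.sqrt((3 + 10) * (3 + 1) * (90 + 10) * (90 + 1))
        assert m["mcc"] == pytest.approx(mcc)

    def test_perfect_predictions(self):
        m = metrics_from_confusion(confusion([1, 1, 0, 0], [1, 1, 0, 0]))
        assert m["sensitivity"] == m["specificity"] == m["mcc"] == 1.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, derandomize=True)
    def test_recount_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        y, p = rng.integers(0, 2, n), rng.integers(0, 2, n)
        c = confusion(y, p)
        # independent per-element recount
        tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
        tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
        fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        m = metrics_from_confusion(c)
        if len(set(y)) == 2 and len(set(p)) == 2:
            assert m["weighted_f1"] == pytest.approx(f1_score(y, p, average="weighted"))

    def test_all_positive_rule_identities(self):
        # sensitivity 1, specificity 0, accuracy = prevalence, MCC 0 exactly
        for y in ([1, 0, 0, 0], [1] * 7 + [0] * 93, [0, 1]):
            m = metrics_from_confusion(confusion(y, np.ones(len(y), dtype=int)))
            assert m["sensitivity"] == 1.0
            assert m["specificity"] == 0.0
            assert m["accuracy"] == pytest.approx(np.mean(y))
            assert m["mcc"] == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestAUC:
    def test_six_point_toy_with_tie_matches_pair_enumeration(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        s = np.array([0.9, 0.5, 0.4, 0.5, 0.3, 0.1])
        wins = ties = 0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                wins += s[i] > s[j]
                ties += s[i] == s[j]
        assert auc_rank(y, s) == pytest.approx((wins + 0.5 * ties) / 9)

    def test_matches_trapezoidal_roc_integration_on_tie_free_scores(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = rng.uniform(size=200)  # continuous, ties a.s. absent
        assert auc_rank(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_random_scores_near_half_and_separation_is_one(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 500 + [0] * 500)
        assert abs(auc_rank(y, rng.uniform(size=1000)) - 0.5) < 0.05
        assert auc_rank(y, y.astype(float)) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc_rank([1, 1], [0.2, 0.8])


class TestBootstrap:
    def test_constant_metric_collapses_to_point(self):
        y = np.array([1] * 5 + [0] * 45)
        s = y.astype(float)  # perfect scores: sensitivity 1 in every replicate
        rep = bootstrap_ci(y, s, ThresholdPolicy(0.5), BootstrapConfig(n_reps=200, seed=0))
        assert rep.ci("sensitivity") == (1.0, 1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 120)
        y[:2] = [0, 1]
        s = rng.uniform(size=120)
        cfg = BootstrapConfig(n_reps=300, seed=42)
        a = bootstrap_ci(y, s, ThresholdPolicy(0.4), cfg)
        b = bootstrap_ci(y, s, ThresholdPolicy(0.4), cfg)
        assert a.metrics == b.metrics

    def test_ci_brackets_point_and_width_shrinks_like_root_n(self):
        widths = []
        sizes = (250, 1000, 4000)
        for n in sizes:
            rng = np.random.default_rng(n)
            y = (rng.uniform(size=n) < 0.3).astype(int)
            s = np.clip(0.4 * y + rng.uniform(size=n) * 0.5, 0, 1)
            rep = bootstrap_ci(y, s, ThresholdPolicy(0.45), BootstrapConfig(n_reps=400, seed=1))
            lo, hi = rep.ci("sensitivity")
            assert lo <= rep.point("sensitivity") <= hi
            widths.append(hi - lo)
        slope = np.polyfit(np.log(sizes), np.log(widths), 1)[0]
        assert -0.7 < slope < -0.3

    def test_stratified_mode_never_skips_replicates(self):
        y = np.array([1] * 3 + [0] * 97)
        rng = np.random.default_rng(0)
        s = rng.uniform(size=100)
        plain = bootstrap_ci(y, s, ThresholdPolicy(0.5), BootstrapConfig(n_reps=300, seed=2))
        strat = bootstrap_ci(
            y, s, ThresholdPolicy(0.5), BootstrapConfig(n_reps=300, seed=2, stratified=True)
        )
        assert strat.skipped_replicates == 0
        assert plain.skipped_replicates > 0


class TestNullModel:
    def test_identities(self):
        y = np.array([1] * 5 + [0] * 245)
        rep = null_model_report(y)
        assert rep.point("sensitivity") == 1.0
        assert rep.point("specificity") == 0.0
        assert rep.point("mcc") == 0.0
        assert rep.point("auc") == 0.5
        assert rep.point("ppv") == pytest.approx(0.02)
        assert "npv" in rep.flags

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            null_model_report([1, 1, 1])


class TestThresholdSweep:
    def test_monotone_sensitivity_and_specificity(self):
        rng = np.random.default_rng(4)
        y = (rng.uniform(size=800) < 0.1).astype(int)
        s = np.clip(rng.beta(1, 30, 800) + 0.03 * y, 0, 1)
        sweep = threshold_sweep(y, s, [0.01, 0.02, 0.03, 0.04, 0.05])
        assert (np.diff(sweep["sensitivity"]) <= 1e-12).all()
        assert (np.diff(sweep["specificity"]) >= -1e-12).all()

    def test_single_cutoff_equals_direct_evaluation(self):
        y = np.array([1, 0, 1, 0, 0])
        s = np.array([0.6, 0.1, 0.7, 0.4, 0.2])
        sweep = threshold_sweep(y, s, [0.5])
        direct = evaluate_scores(y, s, ThresholdPolicy(0.5))
        for k, v in direct.items():
            assert sweep.iloc[0][k] == pytest.approx(v)

    def test_random_scores_sum_of_rates_near_one(self):
        rng = np.random.default_rng(5)
        y = (rng.uniform(size=4000) < 0.5).astype(int)
        s = rng.uniform(size=4000)
        sweep = threshold_sweep(y, s, [0.2, 0.5, 0.8])
        total = sweep["sensitivity"] + sweep["specificity"]
        assert np.allclose(total, 1.0, atol=0.05)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([1, 0], [0.5, 0.5], [0.3, 0.2])


class _Memorizer:
    """1-NN memorizer: perfect on its training rows, weak elsewhere."""

    def fit(self, table):
        self._X, self._y = table.X, table.y
        return self

    def predict_proba(self, table):
        from scipy.spatial.distance import cdist

        nearest = cdist(table.X, self._X).argmin(axis=1)
        return self._y[nearest].astype(float)


class TestOverfitReport:
    def _splits(self, seed=0):
        rng = np.random.default_rng(seed)

        def cohort(n, mu):
            y = (rng.uniform(size=n) < 0.5).astype(int)
            df = pd.DataFrame(
                {"outcome": y, "x1": rng.normal(mu * y, 1.2, n), "x2": rng.normal(0, 1, n)}
            )
            return CohortTable(df, CohortSchema(predictors=("x1", "x2")))

        return cohort(150, 1.0), cohort(150, 1.0)

    def test_memorizer_shows_overfit_signature(self):
        train, test = self._splits()
        model = _Memorizer().fit(train)
        reports = overfit_report(
            model,
            {"test": test, "train_original": train, "train_resampled": train},
            ThresholdPolicy(0.5),
            BootstrapConfig(n_reps=100, seed=0),
        )
        assert reports["train_resampled"].point("sensitivity") == 1.0
        assert reports["train_resampled"].point("specificity") == 1.0
        assert reports["test"].point("mcc") < 0.9

    def test_missing_split_reported_absent(self):
        train, test = self._splits(1)
        model = _Memorizer().fit(train)
        reports = overfit_report(
            model, {"test": test}, ThresholdPolicy(0.5), BootstrapConfig(n_reps=50, seed=0)
        )
        assert reports["train_resampled"] is None
        assert reports["test"] is not None

    def test_mcc_higher_on_balanced_split_at_equal_error_rates(self):
        # same sensitivity/specificity, different prevalence: closed-form MCC
        balanced = metrics_from_confusion(ConfusionCounts(tp=80, fn=20, tn=80, fp=20))
        rare = metrics_from_confusion(ConfusionCounts(tp=16, fn=4, tn=784, fp=196))
        assert balanced["sensitivity"] == rare["sensitivity"]
        assert balanced["specificity"] == rare["specificity"]
        assert balanced["mcc"] > rare["mcc"]
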