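"""Resampling: frequency-matched undersampling and synthetic oversampling."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from pcuste import (
    CohortSchema,
    CohortTable,
    MatchingSpec,
    ResamplerParams,
    adasyn_oversample,
    fraction_to_k,
    pcuste_sample,
    smote_enn,
    smote_oversample,
)
from conftest import make_toy


class TestFractionToK:
    @pytest.mark.parametrize(
        "frac,expected", [(0.02, 2), (0.05, 5), (0.10, 10), (0.30, 32), (0.50, 54), (0.80, 87)]
    )
    def test_reference_pairs_at_109_cases(self, frac, expected):
        assert fraction_to_k(frac, 109) == expected

    def test_minimum_clamp(self):
        assert fraction_to_k(0.001, 109) == 1

    def test_upper_clamp_below_minority_count(self):
        assert fraction_to_k(1.0, 10) == 9

    def test_matches_floor_and_clamp_brute_force_on_grid(self):
        for frac in np.linspace(0.01, 1.0, 100):
            for n in range(1, 101):
                expected = max(1, math.floor(frac * n + 1e-9))
                if n > 1:
                    expected = min(expected, n - 1)
                assert fraction_to_k(float(frac), n) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fraction_to_k(0.0, 10)
        with pytest.raises(ValueError):
            fraction_to_k(0.5, 0)


class TestPCUSTe:
    def test_stratum_counts_match_case_distribution(self, toy_cohort):
        # strata on covariate 'a': 3 cases in a=1, 1 case in a=0
        out = pcuste_sample(toy_cohort, MatchingSpec(("a",), 1, seed=4))
        ctrl = out.data.controls().data
        counts = Counter(ctrl["a"])
        assert counts[1] == 3 and counts[0] == 1
        assert out.data.n == 8 and out.data.n_cases == 4
        assert out.resampled_prior == 0.5

    def test_all_cases_retained_exactly_once_and_no_invented_rows(self, toy_cohort):
        out = pcuste_sample(toy_cohort, MatchingSpec(("a",), 1, seed=4))
        case_ids = sorted(out.data.cases().ids)
        assert case_ids == sorted(toy_cohort.cases().ids)
        assert set(out.data.ids) <= set(toy_cohort.ids)
        assert len(set(out.data.ids)) == out.data.n

    def test_output_size_is_cases_times_one_plus_ratio(self, toy_cohort):
        out = pcuste_sample(toy_cohort, MatchingSpec(("a",), 2, seed=4))
        assert out.data.n == 4 * 3

    def test_seed_determinism_and_fixed_cases(self, toy_cohort):
        a = pcuste_sample(toy_cohort, MatchingSpec(("a",), 1, seed=7))
        b = pcuste_sample(toy_cohort, MatchingSpec(("a",), 1, seed=7))
        pd.testing.assert_frame_equal(a.data.data, b.data.data)
        c = pcuste_sample(toy_cohort, MatchingSpec(("a",), 1, seed=8))
        assert sorted(c.data.cases().ids) == sorted(a.data.cases().ids)

    def test_deficit_backfilled_from_cohort_with_warning(self):
        # stratum a=0 has 4 cases but only 1 control; deficit of 3 backfilled
        toy = make_toy(n_cases_a=1, n_cases_b=4, n_ctrl_a=20, n_ctrl_b=1)
        with pytest.warns(UserWarning, match="deficit"):
            out = pcuste_sample(toy, MatchingSpec(("a",), 1, seed=2))
        assert out.data.n == 10 and out.data.n_cases == 5

    def test_errors(self, toy_cohort):
        no_cases = toy_cohort.subset(toy_cohort.y == 0)
        with pytest.raises(ValueError, match="case"):
            pcuste_sample(no_cases, MatchingSpec(("a",), 1, 0))
        bad = toy_cohort.with_data(toy_cohort.data.assign(a=toy_cohort.data.a * 3))
        with pytest.raises(ValueError, match="binary"):
            pcuste_sample(bad, MatchingSpec(("a",), 1, 0))


def _line_cohort(n_cases=5, n_ctrl=40, seed=0):
    """Minority points on a 2-D segment; majority scattered."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_cases)
    df = pd.DataFrame(
        {
            "outcome": [1] * n_cases + [0] * n_ctrl,
            "a": 0,
            "b": 0,
            "x1": np.concatenate([t, rng.normal(5, 1, n_ctrl)]),
            "x2": np.concatenate([2 * t, rng.normal(5, 1, n_ctrl)]),
        }
    )
    return CohortTable(df, CohortSchema(covariates=("a", "b"), predictors=("x1", "x2")))


class TestSMOTE:
    def test_identical_minority_points_give_identical_synthetics(self):
        df = pd.DataFrame(
            {
                "outcome": [1, 1] + [0] * 10,
                "a": 0,
                "b": 0,
                "x1": [1.0, 1.0] + list(np.linspace(4, 6, 10)),
                "x2": [2.0, 2.0] + list(np.linspace(4, 6, 10)),
            }
        )
        t = CohortTable(df, CohortSchema(covariates=("a", "b"), predictors=("x1", "x2")))
        out = smote_oversample(t, ResamplerParams("SMOTE", k_fraction=0.5, seed=1))
        syn = out.data.data[out.data.data["participant_id"].astype(str).str.startswith("syn")]
        np.testing.assert_allclose(syn[["x1", "x2"]], [[1.0, 2.0]] * len(syn))

    def test_synthetics_stay_on_the_minority_segment(self):
        t = _line_cohort()
        out = smote_oversample(t, ResamplerParams("SMOTE", k_fraction=0.4, seed=3))
        syn = out.data.data[out.data.data["participant_id"].astype(str).str.startswith("syn")]
        # segment x2 = 2 x1, 0 <= x1 <= 1
        np.testing.assert_allclose(syn["x2"], 2 * syn["x1"], atol=1e-10)
        assert ((syn["x1"] >= -1e-12) & (syn["x1"] <= 1 + 1e-12)).all()

    def test_balances_to_half_and_keeps_originals(self):
        t = _line_cohort()
        out = smote_oversample(t, ResamplerParams("SMOTE", k_fraction=0.4, seed=3))
        assert abs(out.resampled_prior - 0.5) <= 1 / out.data.n
        orig_ids = set(t.ids)
        kept = [i for i in out.data.ids if not str(i).startswith("syn")]
        assert sorted(kept, key=str) == sorted(orig_ids, key=str)

    def test_determinism_and_provenance(self):
        t = _line_cohort()
        p = ResamplerParams("SMOTE", k_fraction=0.4, seed=5)
        a, b = smote_oversample(t, p), smote_oversample(t, p)
        pd.testing.assert_frame_equal(a.data.data, b.data.data)
        assert a.provenance["params"]["k"] == 2
        assert a.provenance["counts_after"]["cases"] == 40

    def test_k_at_or_above_minority_count_rejected(self):
        t = _line_cohort(n_cases=1, n_ctrl=10)
        with pytest.raises(ValueError):
            smote_oversample(t, ResamplerParams("SMOTE", k_fraction=1.0))


class TestADASYN:
    def test_generation_concentrates_on_majority_surrounded_case(self):
        # case 0 sits inside the majority cloud; case 1 is isolated with the
        # remaining minority far away -> all-minority neighborhood, weight 0
        df = pd.DataFrame(
            {
                "outcome": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                "a": 0,
                "b": 0,
                "x1": [5.0, 20.0, 20.1, 4.9, 5.1, 4.8, 5.2, 4.95, 5.05, 5.15],
                "x2": [5.0, 20.0, 20.1, 4.9, 5.1, 4.8, 5.2, 4.95, 5.05, 5.15],
            }
        )
        t = CohortTable(df, CohortSchema(covariates=("a", "b"), predictors=("x1", "x2")))
        out = adasyn_oversample(t, ResamplerParams("ADASYN", k_fraction=0.5, seed=1))
        syn = out.data.data[out.data.data["participant_id"].astype(str).str.startswith("syn")]
        # synthetics are interpolations seeded at the surrounded case (near 5)
        # never seeded at the isolated far pair exclusively
        assert (syn["x1"] < 20.2).all()
        assert (syn["x1"] < 10).any()
        assert abs(out.resampled_prior - 0.5) <= 1 / out.data.n

    def test_uniform_fallback_when_all_neighborhoods_minority(self, caplog):
        # minority tightly clustered away from majority: k-NN of each case in
        # the full set are other cases -> all weights zero
        df = pd.DataFrame(
            {
                "outcome": [1] * 5 + [0] * 12,
                "a": 0,
                "b": 0,
                "x1": list(np.linspace(0, 0.1, 5)) + list(np.linspace(50, 51, 12)),
                "x2": 0.0,
            }
        )
        df["x2"] = np.arange(len(df)) * 0.01
        t = CohortTable(df, CohortSchema(covariates=("a", "b"), predictors=("x1", "x2")))
        out = adasyn_oversample(t, ResamplerParams("ADASYN", k_fraction=0.4, seed=2))
        assert abs(out.resampled_prior - 0.5) <= 1 / out.data.n


class TestSMOTEENN:
    def test_perfectly_separated_classes_equal_plain_smote(self):
        t = _line_cohort()
        p = ResamplerParams("SMOTE_ENN", k_fraction=0.4, seed=9)
        enn = smote_enn(t, p)
        sm = smote_oversample(t, ResamplerParams("SMOTE", k_fraction=0.4, seed=9))
        assert enn.provenance["params"]["enn_removed"] == 0
        pd.testing.assert_frame_equal(
            enn.data.data.sort_values("participant_id", key=lambda s: s.astype(str)).reset_index(drop=True),
            sm.data.data.sort_values("participant_id", key=lambda s: s.astype(str)).reset_index(drop=True),
        )

    def test_lone_majority_point_inside_minority_cluster_deleted(self):
        from pcuste.resampling import enn_clean

        # control id 7 sits inside the case cluster; the far control trio
        # protects itself by majority vote
        df = pd.DataFrame(
            {
                "participant_id": range(8),
                "outcome": [1, 1, 1, 1, 0, 0, 0, 0],
                "a": 0,
                "b": 0,
                "x1": [0.0, 0.1, 0.2, 0.3, 9.0, 9.1, 9.2, 0.15],
                "x2": [0.0, 0.1, 0.2, 0.3, 9.0, 9.1, 9.2, 0.15],
            }
        )
        t = CohortTable(df, CohortSchema(covariates=("a", "b"), predictors=("x1", "x2")))
        cleaned, removed = enn_clean(t, enn_k=3)
        assert 7 not in set(cleaned.ids)
        assert {4, 5, 6} <= set(cleaned.ids)
        assert removed == 1

    def test_output_can_leave_cases_as_majority(self):
        # heavily overlapping classes: ENN prunes many boundary controls
        rng = np.random.default_rng(0)
        n1, n0 = 15, 60
        df = pd.DataFrame(
            {
                "outcome": [1] * n1 + [0] * n0,
                "a": 0,
                "b": 0,
                "x1": np.concatenate([rng.normal(0, 1, n1), rng.normal(0.3, 1, n0)]),
                "x2": np.concatenate([rng.normal(0, 1, n1), rng.normal(0.3, 1, n0)]),
            }
        )
        t = CohortTable(df, CohortSchema(covariates=("a", "b"), predictors=("x1", "x2")))
        out = smote_enn(t, ResamplerParams("SMOTE_ENN", k_fraction=0.3, seed=4))
        assert out.provenance["params"]["enn_removed"] > 0
        assert out.resampled_prior > 0.5
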