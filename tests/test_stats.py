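"""Statistical ledger: screens, transforms, mixed model, CIs, rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from myostiff import simulate as sim, stats as st


class TestPairedChanges:
    def test_identity_gives_100(self):
        pre = {"a": 900.0, "b": 1100.0, "c": 1000.0}
        out = st.paired_changes(pre, pre)
        np.testing.assert_allclose(out["rel_change"], 100.0)

    def test_reduction_arithmetic(self):
        # 1000 -> 794 Pa is a 20.6% reduction (rel_change 79.4%)
        out = st.paired_changes({"a": 1000.0, "b": 1000.0}, {"a": 794.0, "b": 794.0})
        assert out["rel_change"].iloc[0] == pytest.approx(79.4)

    def test_rel_to_pre_median(self):
        out = st.paired_changes({"a": 500.0, "b": 1000.0, "c": 2000.0},
                                {"a": 500.0, "b": 1000.0, "c": 2000.0})
        row = out.set_index("location_id")
        assert row.loc["a", "rel_to_pre_median"] == pytest.approx(50.0)

    def test_synthetic_cohort_median_matches_generator(self):
        df = sim.gen_paired_dataset(200, effect_pct=25.7, residual_sd_pct=3.0, seed=2)
        out = st.paired_changes(df.set_index("location_id")["E_pre_Pa"],
                                df.set_index("location_id")["E_post_Pa"])
        assert 100 - np.median(out["rel_change"]) == pytest.approx(25.7, abs=2.0)

    def test_unmatched_ids(self):
        with pytest.raises(ValueError, match="unmatched"):
            st.paired_changes({"a": 1.0}, {"b": 1.0})


class TestTukey:
    def test_gross_outlier_flagged(self):
        rep = st.tukey_outliers([0.0] * 8 + [100.0])
        assert rep.flagged_ids == [8]

    def test_clean_symmetric_sample_unflagged(self):
        rep = st.tukey_outliers(list(range(20)))
        assert rep.flagged_ids == []

    def test_gaussian_flag_rate_near_0_7pct(self):
        # Gaussian expectation for the 1.5 IQR rule is ~0.7%
        rng = np.random.default_rng(0)
        rates = [
            len(st.tukey_outliers(rng.normal(size=1000)).flagged_ids) / 1000
            for _ in range(200)
        ]
        assert np.mean(rates) == pytest.approx(0.007, abs=0.002)

    def test_partition(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        rep = st.tukey_outliers(x)
        assert sorted(rep.flagged_ids + rep.retained_ids) == list(range(50))


class TestRout:
    def test_null_flag_rate_at_most_Q(self):
        rng = np.random.default_rng(2)
        rates = [
            len(st.rout_outliers(rng.normal(size=50)).flagged_ids) / 50
            for _ in range(400)
        ]
        assert np.mean(rates) <= 0.015

    def test_ten_sd_outlier_always_flagged(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = np.concatenate([rng.normal(size=49), [10.0 * 1.5]])
            # robust SD of a unit Gaussian ~ 1; 15 is far outside
            rep = st.rout_outliers(x)
            assert 49 in rep.flagged_ids

    def test_single_deviant_in_constant_sample(self):
        rep = st.rout_outliers([5.0] * 19 + [9.0])
        assert rep.flagged_ids == [19]
        assert len(rep.retained_ids) == 19

    def test_fully_constant_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.rout_outliers([5.0] * 20)

    def test_order_invariance_and_idempotence(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(size=30), [8.0, -9.0]])
        rep = st.rout_outliers(x)
        perm = rng.permutation(len(x))
        rep_p = st.rout_outliers(x[perm], ids=perm.tolist())
        assert sorted(rep.flagged_ids) == sorted(rep_p.flagged_ids)
        retained = x[rep.retained_ids]
        rep2 = st.rout_outliers(retained, ids=rep.retained_ids)
        assert rep2.flagged_ids == []


class TestRelationshipScreen:
    def test_exact_line_none_flagged(self):
        pre = np.linspace(200, 2000, 12)
        rep = st.relationship_screen(list(zip(pre, 0.8 * pre)))
        assert rep.flagged_ids == []

    def test_power_law_with_one_swapped_pair(self):
        pre = np.linspace(300, 3000, 15)
        post = 2.0 * pre**0.8
        pairs = list(zip(pre, post))
        pairs[7] = (pre[7], post[7] * 12)  # unmatched location: far off both fits
        rep = st.relationship_screen(pairs)
        assert rep.flagged_ids == [7]

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 8"):
            st.relationship_screen([(1.0, 1.0)] * 7)

    def test_nonpositive_pairs_warn(self):
        pre = np.linspace(100, 1000, 10)
        pairs = list(zip(pre, 0.9 * pre))
        pairs[0] = (-5.0, 10.0)
        with pytest.warns(UserWarning, match="non-positive"):
            st.relationship_screen(pairs)


class TestBoxCox:
    def test_lognormal_lambda_near_zero(self):
        rng = np.random.default_rng(5)
        lam, transformed = st.boxcox_select(np.exp(rng.normal(size=500)))
        assert abs(lam) < 0.15
        assert transformed.shape == (500,)

    def test_matches_scipy_profile_likelihood(self):
        rng = np.random.default_rng(6)
        x = np.exp(rng.normal(0.5, 0.8, 300))
        lam, _ = st.boxcox_select(x)
        assert lam == pytest.approx(float(sps.boxcox_normmax(x, method="mle")), abs=0.02)

    def test_normal_lambda_near_one(self):
        rng = np.random.default_rng(7)
        lam, _ = st.boxcox_select(rng.normal(50, 3, 800))
        assert lam == pytest.approx(1.0, abs=0.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            st.boxcox_select([1.0, -2.0, 3.0])

    def test_constant_sample_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            st.boxcox_select([4.0] * 10)


class TestMixedModel:
    def test_effect_detected_at_25pct(self, long_table):
        df = sim.gen_paired_dataset(90, effect_pct=25.0, residual_sd_pct=5.0, seed=10)
        res = st.fit_lme(long_table(df))
        p = [f for f in res.fixed_effects if "treatment" in f["term"]][0]
        assert p["adjusted_p"] < 0.001
        assert res.N == 90

    def test_null_p_not_extreme(self, long_table):
        df = sim.gen_paired_dataset(60, effect_pct=0.0, residual_sd_pct=5.0, seed=11)
        res = st.fit_lme(long_table(df))
        p = [f for f in res.fixed_effects if "treatment" in f["term"]][0]
        assert p["p_value"] > 0.001  # no true effect: should not be decisive

    def test_type_I_control_over_replicates(self, long_table):
        rej = 0
        R = 120
        for i in range(R):
            df = sim.gen_paired_dataset(40, effect_pct=0.0, residual_sd_pct=5.0,
                                        seed=7000 + i)
            res = st.fit_lme(long_table(df))
            p = [f for f in res.fixed_effects if "treatment" in f["term"]][0]
            rej += p["p_value"] < 0.05
        assert rej / R <= 0.10  # loose Monte-Carlo bound at this replicate count

    def test_boxcox_engaged_for_lognormal_response(self, long_table):
        df = sim.gen_paired_dataset(60, effect_pct=20.0, residual_sd_pct=5.0, seed=12)
        res = st.fit_lme(long_table(df))
        assert res.transform_lambda is not None
        assert abs(res.transform_lambda) < 0.6  # near-log for a log-normal field

    def test_single_location_rejected(self, long_table):
        df = sim.gen_paired_dataset(1, effect_pct=10.0, seed=13)
        with pytest.raises(ValueError, match="2 locations"):
            st.fit_lme(long_table(df))

    def test_bonferroni_adjustment_monotone(self):
        assert st.bonferroni(0.01, 4) == pytest.approx(0.04)
        assert st.bonferroni(0.6, 4) == 1.0
        with pytest.raises(ValueError):
            st.bonferroni(1.5, 2)


class TestOneSampleVsBaseline:
    def test_all_at_baseline(self):
        t, p = st.one_sample_vs_baseline([100.0, 100.0, 100.0])
        assert t == 0.0 and p == 1.0

    def test_clear_reduction(self):
        # closed form: mean 80, sd 2, t = (80-100)/(2/sqrt(3)) = -17.32
        t, p = st.one_sample_vs_baseline([80.0, 82.0, 78.0])
        assert t == pytest.approx(-17.3205, abs=1e-3)
        assert p < 0.01

    def test_too_few(self):
        with pytest.raises(ValueError):
            st.one_sample_vs_baseline([90.0, 95.0])

    def test_degenerate_off_baseline(self):
        with pytest.raises(ValueError, match="zero variance"):
            st.one_sample_vs_baseline([80.0, 80.0, 80.0])


class TestMedianCI:
    def test_1_to_100_order_statistic_interval(self):
        # binomial order-statistic oracle: l = 40 for n = 100 at 95%
        res = st.median_ci(range(1, 101))
        assert res.median == 50.5
        assert (res.ci_low, res.ci_high) == (40.0, 61.0)
        assert res.method == "order_statistic"

    def test_constant_list_degenerate(self):
        res = st.median_ci([7.0] * 10)
        assert res.ci_low == res.ci_high == res.median == 7.0

    def test_small_sample_bootstrap(self):
        res = st.median_ci([1.0, 2.0, 3.0], seed=0)
        assert res.method == "bootstrap"
        assert res.ci_low <= res.median <= res.ci_high

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.median_ci([])

    def test_coverage_on_skewed_distribution(self):
        rng = np.random.default_rng(8)
        true_med = np.exp(0.0)
        hits = 0
        R = 600
        for _ in range(R):
            x = np.exp(rng.normal(size=25))
            res = st.median_ci(x)
            hits += res.ci_low <= true_med <= res.ci_high
        assert hits / R >= 0.94


class TestMannWhitney:
    def test_identical_groups(self):
        _, p = st.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_fully_separated_5v5_exact(self):
        # exact enumeration: 2 / C(10,5) * 2 = 0.00794
        _, p = st.mann_whitney([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert p == pytest.approx(2 / 252, rel=1e-6)

    def test_single_elements(self):
        _, p = st.mann_whitney([1.0], [2.0])
        assert p == 1.0

    def test_empty_group(self):
        with pytest.raises(ValueError):
            st.mann_whitney([], [1.0])
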