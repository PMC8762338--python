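"""Statistical primitives against closed forms and enumeration oracles."""
import numpy as np
import pandas as pd
import pytest

from immsub import (
    anova_oneway,
    bh_fdr,
    fisher_exact,
    km_estimate,
    logistic_standardized,
    logrank_test,
    mann_whitney,
    median_split,
    spearman,
    t_test,
)
from immsub.stats import SurvivalRecord
from oracles import (
    anova_ss_oracle,
    fisher_2x2_enumeration,
    km_product_limit_oracle,
    logrank_oe_oracle,
    mwu_enumeration,
)


class TestMannWhitney:
    def test_exact_p_on_separated_triples(self):
        # only 1 of C(6,3)=20 assignments puts all of x below y
        res = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.p_value == pytest.approx(0.05)
        assert "exact" in res.method

    def test_identical_samples_give_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_constant_pooled_data_gives_p_one(self):
        res = mann_whitney([5, 5], [5, 5, 5])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_enumeration_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        res = mann_whitney(x, y)
        assert res.p_value == pytest.approx(mwu_enumeration(x, y), abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=15)
        a = mann_whitney(x, y)
        b = mann_whitney(rng.permutation(x), rng.permutation(y))
        assert a.p_value == b.p_value

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            if mann_whitney(x, y).p_value < 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.06


class TestTTest:
    def test_identical_groups(self):
        res = t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_hand_value(self):
        # mean diff -1, pooled SE = sqrt(1 * 2/3)
        res = t_test([1, 2, 3], [2, 3, 4], welch=False)
        assert res.statistic == pytest.approx(-1.2247, abs=5e-5)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=8), rng.normal(1, 1, size=9)
        a, b = t_test(x, y), t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            t_test([2, 2, 2], [3, 3, 3])


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_diagonal_table_enumeration_value(self):
        # 2 of the 20 equally-extreme assignments: p = 0.1
        assert fisher_exact([[3, 0], [0, 3]]).p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("trial", range(10))
    def test_2x2_matches_enumeration_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        tab = rng.integers(1, 12, size=(2, 2))
        got = fisher_exact(tab).p_value
        assert got == pytest.approx(fisher_2x2_enumeration(tab), rel=1e-9)

    @pytest.mark.parametrize("trial", range(5))
    def test_2x3_monte_carlo_within_error_of_enumeration(self, trial):
        rng = np.random.default_rng(400 + trial)
        tab = rng.integers(1, 8, size=(2, 3))
        exact = fisher_exact(tab).p_value
        B = 20000
        mc = fisher_exact(tab, enumeration_budget=0, mc_samples=B,
                          seed=trial).p_value
        se = np.sqrt(exact * (1 - exact) / B) + 1 / B
        assert abs(mc - exact) <= 3 * se + 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [3, 3]])

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            a = rng.binomial(1, 0.5, size=30)
            b = rng.binomial(1, 0.5, size=30)
            tab = [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]]
            if min(min(r) for r in [np.array(tab).sum(0), np.array(tab).sum(1)]) == 0:
                continue
            if fisher_exact(tab).p_value < 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.06


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        rho, _ = spearman(x, x ** 3)
        assert rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(6.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        # d^2 = (1,1,1,1): rho = 1 - 6*4/(4*15) = 0.6
        rho, p = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)
        assert 0 < p <= 1

    def test_exact_permutation_p_small_n(self):
        # perfect concordance on n=4: only 1/24 pairings reaches |rho|=1
        _, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert p == pytest.approx(2 / 24)  # both perfectly +/- concordant orders

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        res = anova_oneway([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_within_variance_flagged(self):
        res = anova_oneway([[0, 0], [1, 1]])
        assert np.isinf(res.statistic)
        assert res.p_value == 0.0
        assert "zero within-group" in res.method

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(21)
        groups = [rng.normal(m, 1, size=n) for m, n in ((0, 8), (0.5, 10), (1, 6))]
        res = anova_oneway(groups)
        f, p = anova_ss_oracle(groups)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            anova_oneway([[2, 2], [2, 2]])


class TestBhFdr:
    def test_step_up_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.33])[0] == pytest.approx(0.33)

    def test_dominance_and_rank_preservation(self):
        rng = np.random.default_rng(8)
        p = rng.random(50)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestKaplanMeier:
    def test_product_limit_no_censoring(self):
        records = [SurvivalRecord(f"s{i}", t, True) for i, t in enumerate([1, 2, 3])]
        km = km_estimate(records)
        assert km.event_times == (1.0, 2.0, 3.0)
        assert km.survival == pytest.approx((2 / 3, 1 / 3, 0.0))
        assert km.at_risk == (3, 2, 1)

    def test_all_censored_stays_at_one(self):
        records = [SurvivalRecord(f"s{i}", t, False) for i, t in enumerate([1, 2, 3])]
        km = km_estimate(records)
        assert km.event_times == ()

    def test_time_scale_equivariance(self):
        df = pd.DataFrame({"time": [1, 2, 2, 4, 6], "event": [1, 1, 0, 1, 0]})
        a = km_estimate(df)
        b = km_estimate(df.assign(time=df["time"] * 3.5))
        assert b.event_times == tuple(3.5 * t for t in a.event_times)
        assert b.survival == a.survival

    def test_matches_walked_oracle_with_censoring(self):
        rng = np.random.default_rng(31)
        times = rng.exponential(10, size=40).round(1) + 0.1
        events = rng.random(40) < 0.7
        km = km_estimate(pd.DataFrame({"time": times, "event": events}))
        oracle = km_product_limit_oracle(times, events)
        assert km.event_times == tuple(t for t, _, _ in oracle)
        assert km.survival == pytest.approx([s for _, s, _ in oracle])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 0, 1]})
        res = logrank_test([df, df.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_observed_minus_expected_oracle(self):
        a = pd.DataFrame({"time": [1, 2], "event": [1, 1]})
        b = pd.DataFrame({"time": [3, 4], "event": [1, 1]})
        res = logrank_test([a, b])
        expected = logrank_oe_oracle([([1, 2], [1, 1]), ([3, 4], [1, 1])])
        assert res.statistic == pytest.approx(expected, rel=1e-9)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1, 2], "event": [0, 0]})
        with pytest.raises(ValueError, match="no events"):
            logrank_test([df, df.copy()])

    def test_three_group_oracle_agreement(self):
        rng = np.random.default_rng(12)
        frames = []
        raw = []
        for h in (0.1, 0.15, 0.3):
            t = rng.exponential(1 / h, size=25).round(2) + 0.01
            e = rng.random(25) < 0.8
            frames.append(pd.DataFrame({"time": t, "event": e}))
            raw.append((t, e))
        res = logrank_test(frames)
        assert res.statistic == pytest.approx(logrank_oe_oracle(raw), rel=1e-6)


class TestLogisticStandardized:
    def test_null_predictor_is_insignificant_most_of_the_time(self):
        rng = np.random.default_rng(11)
        insignificant = 0
        n_rep = 50
        for _ in range(n_rep):
            x = rng.normal(size=500)
            y = rng.binomial(1, 0.5, size=500)
            fit = logistic_standardized(y, pd.DataFrame({"x": x}))
            if fit.p_values[0] > 0.05 and abs(fit.standardized_betas[0]) < 0.5:
                insignificant += 1
        assert insignificant >= int(0.9 * n_rep)

    def test_row_duplication_leaves_coefficients_unchanged(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = rng.binomial(1, 1 / (1 + np.exp(-x)))
        X = pd.DataFrame({"x": x})
        fit1 = logistic_standardized(y, X)
        fit2 = logistic_standardized(np.tile(y, 2), pd.concat([X, X], ignore_index=True))
        assert fit1.coefficients[0] == pytest.approx(fit2.coefficients[0], rel=1e-5)
        assert fit2.p_values[0] < fit1.p_values[0]

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            logistic_standardized(np.ones(20), pd.DataFrame({"x": np.arange(20.0)}))

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20) * 10])
        y = np.concatenate([np.zeros(20), np.ones(20)])
        fit = logistic_standardized(y, pd.DataFrame({"x": x}))
        assert not fit.converged


class TestMedianSplit:
    def test_even_split_no_ties(self):
        labels, dropped = median_split(pd.Series([1, 2, 3, 4]))
        assert list(labels) == [0, 0, 1, 1]
        assert dropped == []

    def test_values_at_median_are_dropped(self):
        labels, dropped = median_split(pd.Series([1, 2, 2, 3]))
        assert sorted(dropped) == [1, 2]
        assert list(labels) == [0, 1]

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            median_split(pd.Series([2.0, 2.0, 2.0]))
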