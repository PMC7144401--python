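"""Statistical battery: oracles and calibration checks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sct

from somnostat import (
    FitFailure,
    cca_pillai_bootstrap,
    correlation_difference_test,
    fit_linear_interaction_model,
    fit_proportional_odds,
    kruskal_wallis,
    rank_sum_test,
    spearman_with_p,
    variable_blocks,
)
from somnostat.stats import proportional_odds_null_thresholds


def hand_kruskal_h(groups):
    """Independent rank-formula oracle (tie-free samples)."""
    values = np.concatenate(groups)
    ranks = sct.rankdata(values)
    n = values.size
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_two_group_rank_formula(self):
        groups = [[1, 2, 3], [4, 5, 6]]
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(hand_kruskal_h(groups), abs=1e-9)
        assert res.statistic == pytest.approx(3.857, abs=1e-3)

    def test_null_p_uniform_under_label_permutation(self):
        rng = np.random.default_rng(42)
        values = rng.normal(size=24)
        pvals = []
        for _ in range(500):
            labels = rng.permutation(["a"] * 8 + ["b"] * 8 + ["c"] * 8)
            pvals.append(kruskal_wallis(values, labels).p)
        assert sct.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        assert kruskal_wallis(x, labels).statistic == pytest.approx(
            kruskal_wallis(np.exp(x), labels).statistic
        )


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman_with_p([1, 2, 5, 9, 11], [2, 4, 10, 11, 30])
        assert res.statistic == 1.0

    def test_reversed(self):
        res = spearman_with_p([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert res.statistic == -1.0

    def test_exact_small_sample_p(self):
        # n=5 tie-free: p is a count over all 120 rank permutations
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        res = spearman_with_p(x, y)
        rho = res.statistic
        ry = sct.rankdata(y)
        count = sum(
            abs(np.corrcoef(p, ry)[0, 1]) >= abs(rho) - 1e-12
            for p in itertools.permutations(range(1, 6))
        )
        assert res.p == pytest.approx(count / 120)

    def test_n10_matches_permutation_oracle(self):
        rng = np.random.default_rng(3)
        cov = [[1, 0.6], [0.6, 1]]
        x, y = rng.multivariate_normal([0, 0], cov, size=10).T
        res = spearman_with_p(x, y)
        rho = res.statistic
        rx, ry = sct.rankdata(x), sct.rankdata(y)
        oracle_rng = np.random.default_rng(99)
        exceed = sum(
            abs(np.corrcoef(oracle_rng.permutation(rx), ry)[0, 1])
            >= abs(rho) - 1e-12
            for _ in range(9999)
        )
        assert res.p == pytest.approx((1 + exceed) / 10000, abs=0.01)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_with_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_rank_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 25))
        assert spearman_with_p(x, y).statistic == pytest.approx(
            spearman_with_p(np.exp(x), y**3).statistic
        )


class TestCorrelationDifference:
    def test_equal_correlations(self):
        res = correlation_difference_test(0.4, 50, 0.4, 50)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_fisher_z(self):
        res = correlation_difference_test(0.5, 50, 0.0, 50)
        z = math.atanh(0.5) / math.sqrt(2 / 47)
        assert res.statistic == pytest.approx(z, abs=1e-12)
        assert res.statistic == pytest.approx(2.6629, abs=1e-4)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            correlation_difference_test(1.0, 50, 0.0, 50)


class TestCca:
    def test_identical_blocks(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 4))
        res = cca_pillai_bootstrap(x, x.copy(), replications=199, seed=1)
        assert np.allclose(res.extra["canonical_correlations"], 1.0, atol=1e-9)
        assert res.p == pytest.approx(1 / 200)

    def test_orthogonalized_block_has_zero_trace(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(80, 3))
        raw = rng.normal(size=(80, 2))
        xc = np.column_stack([np.ones(80), x])
        y = raw - xc @ np.linalg.lstsq(xc, raw, rcond=None)[0]
        res = cca_pillai_bootstrap(x, y, replications=99, seed=2)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_shared_latent_factor_detected(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=150)
        x = 0.8 * f[:, None] + 0.6 * rng.normal(size=(150, 5))
        y = 0.8 * f[:, None] + 0.6 * rng.normal(size=(150, 3))
        res = cca_pillai_bootstrap(x, y, replications=499, seed=3)
        assert res.p <= 0.05

    def test_constant_column_names_block(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 3))
        y = rng.normal(size=(50, 2))
        y[:, 1] = 7.0
        with pytest.raises(ValueError, match="objective"):
            cca_pillai_bootstrap(x, y, replications=9)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(50, 3))
        y = rng.normal(size=(50, 2))
        a = cca_pillai_bootstrap(x, y, replications=299, seed=7)
        b = cca_pillai_bootstrap(x, y, replications=299, seed=7)
        assert a.p == b.p and a.statistic == b.statistic


def _interaction_frame(rng, n, dv_from=None, latent_slope=0.0):
    df = pd.DataFrame(
        {
            "age": rng.normal(40, 12, n),
            "gender": rng.choice(["female", "male"], n),
            "ssq": rng.normal(3.2, 0.7, n),
            "depressed": rng.integers(0, 2, n),
            "obese": rng.integers(0, 2, n),
            "mvv": rng.normal(3.6, 1.0, n),
        }
    )
    if dv_from == "linear":
        df["dv"] = 2.0 * df["mvv"] + rng.normal(0, 1, n)
    elif dv_from == "ordinal":
        eta = latent_slope * df["mvv"]
        latent = eta + rng.logistic(size=n)
        cuts = np.quantile(latent, [0.2, 0.45, 0.7, 0.9])
        df["dv"] = 1 + np.searchsorted(cuts, latent)
    return df


class TestLinearInteractionModel:
    def test_strong_objective_main_effect(self):
        rng = np.random.default_rng(5)
        df = _interaction_frame(rng, 200, dv_from="linear")
        res = fit_linear_interaction_model(df, "dv", "mvv")
        assert res.anova.loc["mvv", "PR(>F)"] < 0.001
        assert res.anova.loc["mvv", "F"] > 100

    def test_coefficients_recovered_within_2_se(self):
        rng = np.random.default_rng(6)
        df = _interaction_frame(rng, 300, dv_from="linear")
        res = fit_linear_interaction_model(df, "dv", "mvv")
        est, se = res.params["mvv"], res.bse["mvv"]
        assert abs(est - 2.0) < 2 * se

    def test_collinear_design_names_aliased_terms(self):
        rng = np.random.default_rng(7)
        df = _interaction_frame(rng, 100, dv_from="linear")
        df["obese"] = df["depressed"]  # aliases the group factors
        with pytest.raises(FitFailure, match="aliased"):
            fit_linear_interaction_model(df, "dv", "mvv")


class TestProportionalOdds:
    def test_null_model_thresholds_closed_form(self):
        values = np.array([1] * 30 + [2] * 50 + [3] * 20)
        thresholds = proportional_odds_null_thresholds(values)
        expected = [math.log(0.3 / 0.7), math.log(0.8 / 0.2)]
        assert thresholds == pytest.approx(expected, abs=1e-12)

    def test_slope_recovered_on_fixed_seed(self):
        rng = np.random.default_rng(8)
        df = _interaction_frame(rng, 500, dv_from="ordinal", latent_slope=1.0)
        fit = fit_proportional_odds(df, "dv", "mvv", interactions=())
        assert fit.params["objective"] == pytest.approx(1.0, abs=0.2)

    def test_too_few_levels_rejected(self):
        rng = np.random.default_rng(9)
        df = _interaction_frame(rng, 100)
        df["dv"] = rng.integers(0, 2, 100)
        with pytest.raises(ValueError, match="3 observed levels"):
            fit_proportional_odds(df, "dv", "mvv")


class TestRankSum:
    def test_identical_single_values(self):
        assert rank_sum_test([3.0], [3.0]).p == 1.0

    def test_exact_small_sample_enumeration(self):
        # {1,2} vs {3,4}: of the C(4,2)=6 equally likely assignments the
        # observed rank split is the most extreme on either side -> 2/6
        res = rank_sum_test([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p == pytest.approx(1 / 3)

    def test_power_under_unit_shift(self):
        rng = np.random.default_rng(10)
        rejections = 0
        for _ in range(300):
            a = rng.normal(0, 1, 30)
            b = rng.normal(1, 1, 30)
            rejections += rank_sum_test(a, b).p < 0.05
        assert rejections / 300 >= 0.9


class TestVariableBlocks:
    def test_complete_cases_aligned(self):
        df = pd.DataFrame(
            {
                **{v: np.arange(5.0) for v in
                   ("sss_pre", "kss_pre", "vas_pre", "sss_post", "kss_post",
                    "vas_post", "d_sss", "d_kss", "d_vas", "asleep")},
                **{v: np.arange(5.0) for v in
                   ("prop_0", "prop_a", "prop_b", "prop_c", "mvv", "ass")},
            }
        )
        df.loc[2, "mvv"] = np.nan
        x, y = variable_blocks(df)
        assert x.shape == (4, 10) and y.shape == (4, 6)
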