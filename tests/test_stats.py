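"""Statistical engine: oracle equivalence, invariances, branching, power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enrvar.stats import (
    StatsInputError,
    brown_forsythe,
    compare_all_traits,
    compare_trait,
    f_variance_test,
    log_transform,
    multiplicity_policy,
    shapiro_wilk,
    variance_power,
    welch_t,
    wilcoxon_rank_sum,
)

from conftest import R_ORACLE, R_ORACLE_SKEW, R_ORACLE_X, R_ORACLE_Y

sample = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=5, max_size=30
).filter(lambda v: np.ptp(v) > 1e-6)


class TestReferenceOracles:
    """Frozen R reference values (R 4.3.3; see conftest for provenance)."""

    def test_shapiro_wilk(self):
        w, p = shapiro_wilk(R_ORACLE_X)
        assert w == pytest.approx(R_ORACLE["shapiro_x"][0], abs=1e-6)
        assert p == pytest.approx(R_ORACLE["shapiro_x"][1], abs=1e-6)
        w, p = shapiro_wilk(R_ORACLE_SKEW)
        assert p == pytest.approx(R_ORACLE["shapiro_skew"][1], abs=1e-6)

    def test_welch_t(self):
        t, df, p = welch_t(R_ORACLE_X, R_ORACLE_Y)
        rt, rdf, rp = R_ORACLE["welch"]
        assert t == pytest.approx(rt, abs=1e-9)
        assert df == pytest.approx(rdf, abs=1e-6)
        assert p == pytest.approx(rp, abs=1e-9)

    def test_f_variance(self):
        f, _, _, p = f_variance_test(R_ORACLE_X, R_ORACLE_Y)
        assert f == pytest.approx(R_ORACLE["var_test"][0], abs=1e-9)
        assert p == pytest.approx(R_ORACLE["var_test"][1], abs=1e-9)

    def test_wilcoxon_with_ties(self):
        u, p = wilcoxon_rank_sum([1, 2, 2, 3, 4, 4, 5], [2, 3, 3, 5, 6, 6, 7, 8])
        assert u == pytest.approx(R_ORACLE["wilcox_ties"][0])
        assert p == pytest.approx(R_ORACLE["wilcox_ties"][1], abs=1e-8)

    def test_brown_forsythe(self):
        f, p = brown_forsythe(R_ORACLE_X, R_ORACLE_Y)
        assert f == pytest.approx(R_ORACLE["brown_forsythe"][0], abs=1e-8)
        assert p == pytest.approx(R_ORACLE["brown_forsythe"][1], abs=1e-8)


class TestWelch:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0, 4.0]
        t, df, p = welch_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_formula(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(1, 3, 20)
        t, df, p = welch_t(x, y)
        vx, vy = x.var(ddof=1) / 15, y.var(ddof=1) / 20
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / 14 + vy**2 / 19)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == pytest.approx(df_hand, rel=1e-12)

    @given(x=sample, y=sample)
    @settings(max_examples=50, deadline=None)
    def test_group_swap_antisymmetry(self, x, y):
        t1, _, p1 = welch_t(x, y)
        t2, _, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2, rel=1e-9, abs=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestWilcoxon:
    def test_exact_separated_3v3(self):
        """x entirely below y: the most extreme of the C(6,3)=20 rank splits."""
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_exact_matches_enumeration(self, rng):
        """Exact p equals brute-force enumeration of all C(9,4) group splits."""
        x = rng.normal(0, 1, 4)
        y = rng.normal(0.5, 1, 5)
        _, p = wilcoxon_rank_sum(x, y)
        u_obs = float(sum(xi > yj for xi in x for yj in y))
        pooled = np.concatenate([x, y])
        us = []
        for combo in itertools.combinations(range(9), 4):
            xs = pooled[list(combo)]
            ys = pooled[[i for i in range(9) if i not in combo]]
            us.append(float(sum(a > b for a in xs for b in ys)))
        us = np.array(us)
        p_le = np.mean(us <= u_obs)
        p_ge = np.mean(us >= u_obs)
        expected = min(1.0, 2.0 * min(p_le, p_ge))
        assert p == pytest.approx(expected, abs=1e-12)

    @given(x=sample, y=sample)
    @settings(max_examples=50, deadline=None)
    def test_group_swap_invariance(self, x, y):
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(y, x)
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestFVarianceTest:
    def test_equal_patterns_give_unit_f(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [11.0, 12.0, 13.0, 14.0]
        f, _, _, p = f_variance_test(x, y)
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    @given(x=sample, y=sample)
    @settings(max_examples=50, deadline=None)
    def test_swap_invariance_of_p(self, x, y):
        _, _, _, p1 = f_variance_test(x, y)
        _, _, _, p2 = f_variance_test(y, x)
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestBrownForsythe:
    def test_location_invariance(self, rng):
        x = rng.normal(0, 2, 25)
        f1, p1 = brown_forsythe(x, x + 100.0)
        assert f1 == pytest.approx(0.0, abs=1e-20)

    def test_matches_hand_anova_oracle(self):
        """ANOVA on |value - group median| for a 4+4 toy sample."""
        x = np.array([1.0, 3.0, 5.0, 9.0])
        y = np.array([2.0, 2.5, 3.0, 3.5])
        zx = np.abs(x - np.median(x))
        zy = np.abs(y - np.median(y))
        grand = np.concatenate([zx, zy]).mean()
        ss_between = 4 * (zx.mean() - grand) ** 2 + 4 * (zy.mean() - grand) ** 2
        ss_within = ((zx - zx.mean()) ** 2).sum() + ((zy - zy.mean()) ** 2).sum()
        f_hand = (ss_between / 1) / (ss_within / 6)
        f, p = brown_forsythe(x, y)
        assert f == pytest.approx(f_hand, rel=1e-12)

    def test_scaling_one_group_shrinks_p(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        _, p_null = brown_forsythe(x, y)
        _, p_scaled = brown_forsythe(x, y * 10.0)
        assert p_scaled < p_null


class TestShapiro:
    def test_permutation_invariance(self, rng):
        v = rng.normal(0, 1, 40)
        assert shapiro_wilk(v) == pytest.approx(shapiro_wilk(np.sort(v)))

    def test_constant_sample_rejected(self):
        with pytest.raises(StatsInputError, match="constant"):
            shapiro_wilk([2.0] * 10)

    def test_detects_lognormal_skew(self, rng):
        """n=40 lognormal samples should usually fail the normality gate."""
        rejected = sum(
            shapiro_wilk(np.exp(rng.normal(0, 1, 40)))[1] < 0.05 for _ in range(100)
        )
        assert rejected > 80


class TestLogTransform:
    def test_known_values(self):
        np.testing.assert_allclose(log_transform([np.e, 1.0]), [1.0, 0.0], atol=1e-15)

    def test_round_trip(self, rng):
        v = rng.uniform(0.1, 100, 50)
        np.testing.assert_allclose(np.exp(log_transform(v)), v, rtol=1e-12)

    def test_nan_passes_through(self):
        out = log_transform([1.0, np.nan, np.e])
        assert np.isnan(out[1])

    def test_nonpositive_identified(self):
        with pytest.raises(StatsInputError, match=r"rows \[1\]"):
            log_transform([1.0, -2.0, 3.0], trait="cort")


class TestCompareTrait:
    def test_branch_consistency(self, two_group_table):
        res = compare_trait(two_group_table, "normal_trait")
        parametric = res.shapiro_p_ctrl > 0.05 and res.shapiro_p_enr > 0.05
        assert res.branch == ("parametric" if parametric else "nonparametric")
        if res.branch == "parametric":
            assert res.mean_test == "Welch t" and res.variance_test == "F"
        else:
            assert res.mean_test == "Wilcoxon rank-sum" and res.variance_test == "Brown-Forsythe"
        assert res.significant_mean == (res.mean_p < res.alpha)
        assert res.significant_variance == (res.variance_p < res.alpha)

    def test_lognormal_without_policy_goes_nonparametric(self, two_group_table):
        res = compare_trait(two_group_table, "skewed_trait")
        assert res.branch == "nonparametric"

    def test_log_policy_restores_parametric_branch(self, two_group_table):
        res = compare_trait(two_group_table, "skewed_trait", log_traits={"skewed_trait"})
        assert res.transform == "log"
        assert res.branch == "parametric"

    def test_missing_dropped_and_n_reported(self, two_group_table):
        res = compare_trait(two_group_table, "gappy_trait")
        assert res.n_ctrl == 18 and res.n_enr == 19

    def test_insufficient_n_flagged(self, two_group_table):
        table = two_group_table.copy()
        table.loc[table["group"] == "ENR", "gappy_trait"] = np.nan
        with pytest.raises(StatsInputError, match="non-missing"):
            compare_trait(table, "gappy_trait")
        res = compare_all_traits(table, ["gappy_trait"])
        assert len(res) == 1 and res["note"].notna().all()


class TestMultiplicityPolicy:
    def test_flags_never_altered(self, two_group_table):
        res = compare_all_traits(two_group_table)
        adj = multiplicity_policy(res)
        pd.testing.assert_series_equal(res["significant_variance"], adj["significant_variance"])
        pd.testing.assert_series_equal(res["significant_mean"], adj["significant_mean"])
        assert "mean_p_bh" in adj.columns and "variance_p_bh" in adj.columns

    def test_bh_matches_step_up_oracle(self):
        p = np.array([0.001, 0.04, 0.03, 0.2, 0.9])
        df = pd.DataFrame({"mean_p": p, "variance_p": p,
                           "significant_mean": p < 0.05, "significant_variance": p < 0.05})
        adj = multiplicity_policy(df)["mean_p_bh"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            running = min(running, p[i] * m / (rank_from_top + 1))
            expected[i] = running
        np.testing.assert_allclose(adj, expected, rtol=1e-12)


class TestVariancePower:
    def test_size_under_null(self):
        for n, alpha in [(10, 0.05), (40, 0.05), (25, 0.10)]:
            assert variance_power(n, n, 1.0, alpha) == pytest.approx(alpha, abs=1e-10)

    def test_monotone_in_ratio_and_n(self):
        powers = [variance_power(40, 40, r) for r in (1.0, 1.5, 2.5, 5.0, 50.0)]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999
        by_n = [variance_power(n, n, 2.5) for n in (5, 10, 20, 40, 80)]
        assert all(a < b for a, b in zip(by_n, by_n[1:]))

    def test_reciprocal_ratio_symmetry(self):
        """Swapping the groups inverts the ratio but cannot change the power."""
        assert variance_power(30, 20, 2.0) == pytest.approx(
            variance_power(20, 30, 0.5), abs=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(StatsInputError):
            variance_power(1, 40, 2.5)
        with pytest.raises(StatsInputError):
            variance_power(40, 40, -1.0)
        with pytest.raises(StatsInputError):
            variance_power(40, 40, 2.5, alpha=1.5)
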