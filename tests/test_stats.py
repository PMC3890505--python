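import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sedi.stats import (
    adjusted_odds_ratio,
    chi_square,
    cronbach_alpha,
    oneway_anova,
)


def brute_force_alpha(matrix):
    """Direct evaluation of k/(k-1) * (1 - sum var_i / var_total)."""
    arr = np.asarray(matrix, dtype=float)
    k = arr.shape[1]
    item_vars = [np.var(arr[:, j], ddof=1) for j in range(k)]
    total_var = np.var(arr.sum(axis=1), ddof=1)
    return k / (k - 1) * (1 - sum(item_vars) / total_var)


class TestCronbachAlpha:
    def test_parallel_items_alpha_one(self):
        r = cronbach_alpha([[1, 1], [2, 2], [3, 3]])
        assert r.alpha == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(3)
        r = cronbach_alpha(rng.standard_normal((5000, 10)))
        assert r.alpha == pytest.approx(0.0, abs=0.05)

    def test_matches_direct_formula(self):
        m = [[2, 4, 3, 7], [4, 5, 5, 8], [1, 2, 2, 5], [5, 6, 6, 10]]
        r = cronbach_alpha(m)
        assert r.alpha == pytest.approx(brute_force_alpha(m), abs=1e-12)

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        latent = rng.standard_normal(300)
        df = pd.DataFrame({f"i{j}": latent + rng.standard_normal(300)
                           for j in range(6)})
        expected = pingouin.cronbach_alpha(df)[0]
        assert cronbach_alpha(df).alpha == pytest.approx(expected, abs=1e-10)

    def test_corrected_item_total_excludes_self(self):
        """A pure-noise item added to a coherent scale is flagged below 0.2."""
        rng = np.random.default_rng(4)
        latent = rng.standard_normal(800)
        df = pd.DataFrame({f"i{j}": latent + 0.5 * rng.standard_normal(800)
                           for j in range(5)})
        df["junk"] = rng.standard_normal(800)
        r = cronbach_alpha(df)
        assert r.low_items == ["junk"]
        assert r.item_total["junk"] < 0.2 < min(
            v for k, v in r.item_total.items() if k != "junk")

    def test_invariance_under_shift_and_common_scale(self):
        rng = np.random.default_rng(6)
        m = rng.standard_normal((50, 4)) + rng.standard_normal((50, 1))
        base = cronbach_alpha(m).alpha
        shifted = m.copy()
        shifted[:, 2] += 17.0
        assert cronbach_alpha(shifted).alpha == pytest.approx(base, abs=1e-12)
        assert cronbach_alpha(3.5 * m).alpha == pytest.approx(base, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="2 items"):
            cronbach_alpha([[1], [2]])
        with pytest.raises(ValueError, match="variance"):
            cronbach_alpha([[1, 1], [1, 1], [1, 1]])


class TestOnewayAnova:
    def test_textbook_sums_of_squares(self):
        """Three groups with means 2, 3, 7: SSB = 42, SSW = 6, F = 21."""
        y = [1, 2, 3, 2, 3, 4, 6, 7, 8]
        g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        r = oneway_anova(y, g)
        assert r.F == pytest.approx(21.0, abs=1e-10)
        assert (r.df_between, r.df_within) == (2, 6)

    def test_matches_scipy(self):
        import scipy.stats
        rng = np.random.default_rng(8)
        y = rng.normal(size=120)
        g = rng.choice(list("abcd"), size=120)
        r = oneway_anova(y, g)
        ref = scipy.stats.f_oneway(*[y[g == lv] for lv in "abcd"])
        assert r.F == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_equal_group_means_give_zero_f(self):
        r = oneway_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert r.F == 0.0

    def test_pairwise_deletion_df_contract(self):
        """Missing values shrink df_within to usable_n - groups, mirroring
        per-domain denominators like (4, 1081) vs (4, 1079)."""
        rng = np.random.default_rng(10)
        n = 1091
        y = rng.normal(size=n)
        y[[3, 44, 800, 801, 900]] = np.nan
        g = rng.choice([1, 2, 3, 4, 5], size=n)
        r = oneway_anova(y, g)
        assert r.df_between == 4
        assert r.df_within == (n - 5) - 5

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([1, 2, 3], ["a", "a", "a"])


class TestAdjustedOddsRatio:
    def test_crude_or_equals_cross_product(self):
        """2x2 with counts (193, 370, 104, 420): OR = 193*420 / (104*370)."""
        outcome = [1] * 193 + [0] * 370 + [1] * 104 + [0] * 420
        exposure = ["boy"] * 563 + ["girl"] * 524
        res = adjusted_odds_ratio(outcome, exposure, reference="girl")
        assert len(res) == 1
        expected = (193 * 420) / (104 * 370)
        assert res[0].odds_ratio == pytest.approx(expected, abs=1e-6)
        assert res[0].ci_low < expected < res[0].ci_high

    def test_independent_outcome_or_one(self):
        outcome = ([1] * 30 + [0] * 70) * 2
        exposure = ["e"] * 100 + ["u"] * 100
        res = adjusted_odds_ratio(outcome, exposure, reference="u")
        assert res[0].odds_ratio == pytest.approx(1.0, abs=1e-8)

    @given(st.tuples(*[st.integers(min_value=5, max_value=400)] * 4))
    @settings(max_examples=30, deadline=None)
    def test_logistic_fit_equals_closed_form(self, counts):
        a, b, c, d = counts
        outcome = [1] * a + [0] * b + [1] * c + [0] * d
        exposure = ["e"] * (a + b) + ["u"] * (c + d)
        res = adjusted_odds_ratio(outcome, exposure, reference="u")
        assert res[0].odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_parameter_recovery_from_logistic_truth(self):
        """Data generated with gender log-OR log(2.5) and an age effect is
        recovered by the adjusted fit."""
        rng = np.random.default_rng(123)
        n = 20_000
        male = rng.random(n) < 0.5
        age = rng.uniform(4.5, 6.5, n)
        logit = -1.8 + np.log(2.5) * male + 0.3 * (age - 5.5)
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        res = adjusted_odds_ratio(
            y.astype(int), np.where(male, "male", "female"), "female",
            covariates=pd.DataFrame({"age": age}))
        assert 2.3 <= res[0].odds_ratio <= 2.7

    def test_multilevel_exposure_one_model(self):
        rng = np.random.default_rng(14)
        q = rng.choice([1, 2, 3, 4, 5], size=4000)
        y = rng.random(4000) < 0.1 + 0.04 * (5 - q)
        res = adjusted_odds_ratio(y.astype(int), q.astype(str), "5")
        assert [r.contrast for r in res] == [
            "1 vs 5", "2 vs 5", "3 vs 5", "4 vs 5"]
        assert all(r.odds_ratio > 1 for r in res[:2])

    def test_perfect_separation_flagged(self):
        outcome = [1] * 20 + [0] * 20
        exposure = ["e"] * 20 + ["u"] * 20
        res = adjusted_odds_ratio(outcome, exposure, reference="u")
        assert not res[0].estimable


class TestChiSquare:
    def test_hand_computed_2x2(self):
        """[[10,20],[20,10]]: all expected cells are 15, statistic 20/3."""
        r = chi_square([[10, 20], [20, 10]])
        assert r.statistic == pytest.approx(20 / 3, abs=1e-10)
        assert r.df == 1

    def test_margin_product_table_is_independent(self):
        table = np.outer([1, 2, 3], [4, 5]) * 2
        assert chi_square(table).statistic == pytest.approx(0.0, abs=1e-12)

    def test_2x3_brute_force(self):
        table = np.array([[12, 7, 31], [8, 11, 9]], dtype=float)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat = ((table - exp) ** 2 / exp).sum()
        r = chi_square(table)
        assert r.statistic == pytest.approx(stat, abs=1e-10)
        assert r.df == 2

    @given(st.lists(st.lists(st.integers(1, 50), min_size=2, max_size=4),
                    min_size=2, max_size=4).filter(
                        lambda t: len({len(r) for r in t}) == 1))
    @settings(max_examples=30, deadline=None)
    def test_transpose_symmetry(self, table):
        t = np.array(table, dtype=float)
        assert chi_square(t).statistic == pytest.approx(
            chi_square(t.T).statistic, rel=1e-12)

    def test_zero_margin_named(self):
        with pytest.raises(ValueError, match="column 1"):
            chi_square([[5, 0], [3, 0]])
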