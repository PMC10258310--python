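"""Rank tests vs enumeration oracles, frequency tables, BH and survival."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from repsig import (
    UndefinedTestError,
    adjust_bh,
    categorical_test,
    frequency_table,
    km_logrank,
    mann_whitney,
    paired_wilcoxon,
    spearman,
)
from repsig.cohort import km_curve, median_split


# ---------------------------------------------------------------- oracles
def wilcoxon_exact_oracle(d):
    """Two-sided exact signed-rank p by brute-force sign enumeration."""
    d = np.asarray([x for x in d if x != 0], dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2 * min(lo, hi))


def mwu_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by brute-force rank-split enumeration."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na = len(a)
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(ranks)), na):
        us.append(sum(ranks[list(idx)]) - na * (na + 1) / 2)
    us = np.asarray(us)
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------- wilcoxon
class TestPairedWilcoxon:
    def test_all_positive_differences_n5(self):
        res = paired_wilcoxon([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(2 / 32)

    def test_antisymmetric_input_same_p(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        assert paired_wilcoxon(x, y).p_value == pytest.approx(
            paired_wilcoxon(y, x).p_value, abs=1e-12
        )

    def test_mostly_tied_pairs_match_enumeration(self):
        """Zero differences drop; the rest follow the sign-flip distribution."""
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [1.0, 2.0, 3.0, 2.5, 6.0, 3.5]
        res = paired_wilcoxon(x, y)
        _, p = wilcoxon_exact_oracle([1.5, -1.0, 2.5])
        assert res.n == 3
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_all_zero_differences_undefined(self):
        with pytest.raises(UndefinedTestError):
            paired_wilcoxon([1.0, 2.0], [1.0, 2.0])

    def test_matches_enumeration_oracle_on_random_inputs(self, rng):
        """Exact branch equals brute-force enumeration, with and without ties."""
        for _ in range(60):
            n = int(rng.integers(3, 11))
            d = rng.integers(-4, 5, size=n).astype(float)
            if np.sum(d != 0) < 3:
                continue
            w, p = wilcoxon_exact_oracle(d)
            res = paired_wilcoxon(d)
            assert res.statistic == pytest.approx(w)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        """Independent cross-check against scipy's exact distribution."""
        for _ in range(20):
            d = rng.permutation(np.arange(1, 11) * rng.choice([-1.0, 1.0], size=10))
            ours = paired_wilcoxon(d)
            ref = sps.wilcoxon(d, method="exact", alternative="two-sided")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        d = rng.normal(0.3, 1.0, size=40)
        res = paired_wilcoxon(d)
        assert res.method == "wilcoxon_signed_rank_normal"
        ref = sps.wilcoxon(d, method="approx", correction=True, alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------- mann-whitney
class TestMannWhitney:
    def test_identical_groups_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        res = mann_whitney([1, 2], [10, 11])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6)

    def test_label_swap_symmetric(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=6)
        assert mann_whitney(a, b).p_value == pytest.approx(
            mann_whitney(b, a).p_value, abs=1e-12
        )

    def test_empty_group_rejected(self):
        with pytest.raises(UndefinedTestError):
            mann_whitney([1.0], [2.0, 3.0])

    def test_matches_enumeration_oracle_on_random_inputs(self, rng):
        for _ in range(60):
            na = int(rng.integers(2, 6))
            nb = int(rng.integers(2, 11 - na))
            a = rng.integers(0, 6, size=na).astype(float)
            b = rng.integers(0, 6, size=nb).astype(float)
            u, p = mwu_exact_oracle(a, b)
            res = mann_whitney(a, b)
            assert res.statistic == pytest.approx(u)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_type_one_error_under_null(self, rng):
        """Empirical size at alpha=0.05 across 2000 null replicates."""
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            if mann_whitney(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


# ---------------------------------------------------------------- spearman
class TestSpearman:
    def test_perfect_monotone(self, rng):
        x = np.sort(rng.normal(size=10))
        assert spearman(x, x * 3 + 1).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert spearman(x, y).statistic == pytest.approx(rho, abs=1e-12)

    def test_constant_vector_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(res.statistic)

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, np.nan, 7.0])
        assert spearman(x, y).n == 4


# ---------------------------------------------------------------- categorical
class TestCategorical:
    @pytest.mark.parametrize("a,b,c,d", [(10, 0, 0, 10), (8, 1, 2, 7), (3, 5, 6, 2)])
    def test_fisher_matches_hypergeometric_enumeration(self, a, b, c, d):
        res = categorical_test([[a, b], [c, d]], method="fisher")
        # enumerate hypergeometric point probabilities over all feasible tables
        n = a + b + c + d
        r1, c1 = a + b, a + c
        ks = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        probs = {k: sps.hypergeom.pmf(k, n, r1, c1) for k in ks}
        expected = sum(p for p in probs.values() if p <= probs[a] * (1 + 1e-7))
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_auto_dispatch_small_expected_uses_fisher(self):
        assert categorical_test([[8, 1], [1, 8]]).method == "fisher_exact"
        assert categorical_test([[50, 50], [50, 50]]).method == "chi_square"

    def test_homogeneous_table_p_one(self):
        assert categorical_test([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_large_balanced_table_chi2_zero(self):
        res = categorical_test([[50, 50], [50, 50]])
        assert res.method == "chi_square"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_undefined(self):
        with pytest.raises(UndefinedTestError):
            categorical_test([[0, 0], [3, 4]])


# ---------------------------------------------------------------- frequency
class TestFrequencyTable:
    def test_single_record_is_100_percent(self):
        df = pd.DataFrame({"sex": ["male"]})
        out = frequency_table(df)
        assert out.loc[0, "percent"] == 100.0

    def test_percentages_sum_to_100_within_rounding(self, rng):
        df = pd.DataFrame({"grade": rng.choice(list("ABC"), size=63)})
        out = frequency_table(df)
        assert out["percent"].sum() == pytest.approx(100.0, abs=0.2)

    def test_counts_and_rounding(self):
        df = pd.DataFrame({"sex": ["male"] * 55 + ["female"] * 9})
        out = frequency_table(df).set_index("category")
        assert out.loc["male", "count"] == 55
        assert out.loc["male", "percent"] == 85.9
        assert out.loc["female", "percent"] == 14.1


# ---------------------------------------------------------------- BH
class TestBH:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.04])[0] == pytest.approx(0.04)

    def test_step_up_hand_computation(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_stay_equal(self):
        q = adjust_bh([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_monotone_after_sorting(self, rng):
        p = rng.uniform(0.001, 1.0, size=25)
        q = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)


# ---------------------------------------------------------------- survival
def _cohort(times, events, feature):
    return pd.DataFrame(
        {
            "os_months": times,
            "os_event": events,
            "feat": feature,
            "patient_id": [f"P{i}" for i in range(len(times))],
        }
    )


class TestSurvival:
    def test_product_limit_hand_example(self):
        curve = km_curve([5.0, 10.0], [1, 1])
        # S(5) = 1 - 1/2; S(10) = (1 - 1/2)(1 - 1/1) = 0
        s = dict(zip(curve.times, curve.survival))
        assert s[5.0] == pytest.approx(0.5)
        assert s[10.0] == pytest.approx(0.0)

    def test_all_censored_survival_stays_one(self):
        curve = km_curve([3.0, 7.0, 9.0], [0, 0, 0])
        assert np.allclose(curve.survival, 1.0)

    def test_km_without_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=50)
        curve = km_curve(t, np.ones(50, dtype=int))
        for time, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(t > time), abs=1e-10)

    def test_identical_groups_logrank_p_one(self):
        times = [2.0, 4.0, 6.0, 8.0] * 2
        events = [1, 1, 0, 1] * 2
        feature = [0.0] * 4 + [1.0] * 4  # median split separates the copies
        _, _, res = km_logrank(_cohort(times, events, feature), "feat", "OS")
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_logrank_invariant_under_label_swap(self, rng):
        n = 30
        df = _cohort(
            rng.exponential(10, size=n), rng.integers(0, 2, size=n), rng.normal(size=n)
        )
        _, _, res1 = km_logrank(df, "feat", "OS")
        df2 = df.assign(feat=-df["feat"])  # swaps high/low membership
        _, _, res2 = km_logrank(df2, "feat", "OS")
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-9)

    def test_all_censored_returns_curves_with_nan_p(self):
        df = _cohort([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0], [1.0, 2.0, 3.0, 4.0])
        low, high, res = km_logrank(df, "feat", "OS")
        assert math.isnan(res.p_value)
        assert np.allclose(low.survival, 1.0) and np.allclose(high.survival, 1.0)

    def test_median_split_ties_to_low(self):
        high = median_split([1.0, 2.0, 2.0, 3.0])
        assert list(high) == [False, False, False, True]
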