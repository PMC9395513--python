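"""Nonparametric statistics against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ctmt.stats import (
    PowerSpec,
    effect_size,
    kuiper_two_sample,
    monte_carlo_power,
    signed_rank_null_distribution,
    spearman,
    wilcoxon_signed_rank,
)


def wilcoxon_exact_oracle(diffs):
    """Two-sided exact p by explicit enumeration of all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=n)]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_n6_extreme(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.p == pytest.approx(2 / 64)
        assert res.statistic == 21.0
        assert res.method == "wilcoxon-exact"

    def test_antisymmetric_z_zero(self):
        res = wilcoxon_signed_rank([3, -3, 5, -5, 7, -7, 2, -2])
        assert res.z == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    @given(st.lists(st.integers(-20, 20).filter(lambda v: v != 0),
                    min_size=3, max_size=10))
    @settings(max_examples=80, deadline=None)
    def test_exact_p_matches_enumeration(self, diffs):
        res = wilcoxon_signed_rank(diffs)
        assert res.p == pytest.approx(wilcoxon_exact_oracle(diffs), abs=1e-12)

    @given(st.lists(st.floats(-10, 10, allow_nan=False).filter(
        lambda v: abs(v) > 1e-3), min_size=5, max_size=12, unique=True))
    @settings(max_examples=40, deadline=None)
    def test_matches_scipy_exact_when_tie_free(self, diffs):
        # tie-free means tie-free in |d|: the ranking happens on magnitudes
        if len({abs(v) for v in diffs}) < len(diffs):
            return
        res = wilcoxon_signed_rank(diffs)
        ref = sps.wilcoxon(diffs, method="exact")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_approx_close_to_exact(self, rng):
        for n in (11, 13, 15):
            for _ in range(20):
                d = rng.normal(0.3, 1.0, n)
                exact = wilcoxon_signed_rank(d).p
                approx_res = wilcoxon_signed_rank(d, exact_max_n=0)
                assert approx_res.method == "wilcoxon-normal"
                assert abs(approx_res.p - exact) < 0.02

    def test_null_distribution_counts(self):
        counts = signed_rank_null_distribution(2 * np.arange(1, 5))
        assert counts.sum() == 16  # 2^4 sign patterns


class TestEffectSize:
    @pytest.mark.parametrize("z, n, expected", [
        (6.0, 49, 0.86), (-6.0, 49, 0.86), (4.7, 49, 0.67), (0.0, 7, 0.0),
    ])
    def test_values(self, z, n, expected):
        assert effect_size(z, n) == pytest.approx(expected, abs=0.005)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            effect_size(1.0, 0)


class TestKuiper:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = kuiper_two_sample(x, x)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_fully_separated(self):
        res = kuiper_two_sample([1, 2, 3], [10, 11, 12])
        assert res.statistic == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            kuiper_two_sample([], [1.0])

    @given(st.lists(st.integers(0, 30), min_size=2, max_size=15),
           st.lists(st.integers(0, 30), min_size=2, max_size=15))
    @settings(max_examples=100, deadline=None)
    def test_v_matches_brute_force(self, xs, ys):
        res = kuiper_two_sample(xs, ys)
        # brute-force sup over a dense grid of evaluation points
        grid = np.linspace(-1, 31, 2000)
        f1 = np.searchsorted(np.sort(xs), grid, side="right") / len(xs)
        f2 = np.searchsorted(np.sort(ys), grid, side="right") / len(ys)
        v_bf = np.max(f1 - f2) + np.max(f2 - f1)
        assert res.statistic == pytest.approx(v_bf, abs=1e-12)
        assert 0.0 <= res.statistic <= 2.0

    def test_p_in_unit_interval(self, rng):
        for _ in range(10):
            res = kuiper_two_sample(rng.normal(size=40), rng.normal(1.0, 1, 40))
            assert 0.0 <= res.p <= 1.0


class TestSpearman:
    def test_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [9, 7, 5, 1]).statistic == pytest.approx(-1.0)

    def test_ties_average_rank_formula(self):
        x = [1, 2, 2, 4, 5]
        y = [2, 1, 3, 3, 5]
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rho_hand = np.corrcoef(rx, ry)[0, 1]  # Pearson on average ranks
        assert spearman(x, y).statistic == pytest.approx(rho_hand)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestMonteCarloPower:
    def test_null_calibration(self):
        """Under the null, rejection rate matches the attained exact size."""
        spec = PowerSpec(effect_mean=0.0, effect_sd=1.0, n=12,
                         iterations=10_000, seed=7)
        power = monte_carlo_power(spec)
        # attained size of the discrete exact test, computed independently
        counts = signed_rank_null_distribution(2 * np.arange(1, 13))
        total = counts.sum()
        cum = np.cumsum(counts)
        rev = np.cumsum(counts[::-1])[::-1]
        w2 = 2 * np.arange(12 * 13 // 2 + 1)
        pvals = np.minimum(1.0, 2.0 * np.minimum(cum[w2], rev[w2]) / total)
        # attained size = P(p < alpha) under the null
        size = float(np.sum((pvals < 0.05) * counts[w2]) / total)
        mc_se = math.sqrt(size * (1 - size) / spec.iterations)
        assert abs(power - size) < 4 * mc_se + 1e-9

    def test_saturated_effect(self):
        spec = PowerSpec(effect_mean=100.0, effect_sd=1.0, n=12,
                         iterations=2000, seed=1)
        assert monte_carlo_power(spec) == pytest.approx(1.0)

    def test_seed_determinism(self):
        spec = PowerSpec(iterations=2000, seed=5)
        assert monte_carlo_power(spec) == monte_carlo_power(spec)

    def test_monotone_in_effect_and_n(self):
        powers = [monte_carlo_power(PowerSpec(effect_mean=m, effect_sd=10.0,
                                              n=12, iterations=4000, seed=3))
                  for m in (-2.0, -6.0, -10.0)]
        assert powers[0] <= powers[1] <= powers[2]
        powers_n = [monte_carlo_power(PowerSpec(effect_mean=-8.0, effect_sd=10.0,
                                                n=n, iterations=4000, seed=3))
                    for n in (8, 12, 20)]
        assert powers_n[0] <= powers_n[1] <= powers_n[2]
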