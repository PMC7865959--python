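"""Summaries, frequency curves, rank correlation and group tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from spinestereo.errors import ConfigError, EstimationError
from spinestereo.stats import (
    AREA_BINS,
    LENGTH_BINS,
    VOLUME_BINS,
    HistogramSpec,
    compare_groups,
    frequency_curve,
    spearman,
    summarize,
)
from spinestereo.synthetic import generate_population


def rank_formula_rho(x, y):
    """Brute-force oracle (no ties): 1 - 6*sum(d^2)/(n(n^2-1))."""
    n = len(x)
    rx = [sorted(x).index(v) + 1 for v in x]
    ry = [sorted(y).index(v) + 1 for v in y]
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def midrank(values):
    """Brute-force mid-ranks: (#less) + (#equal + 1)/2."""
    return [
        sum(v < u for v in values) + (sum(v == u for v in values) + 1) / 2.0 for u in values
    ]


class TestSummarize:
    def test_hand_computed(self):
        t = summarize([1.0, 2.0, 3.0], "x", "um")
        assert t.mean == pytest.approx(2.0)
        assert t.sem == pytest.approx(1.0 / math.sqrt(3), abs=5e-4)  # sd = 1
        assert (t.min, t.max, t.n) == (1.0, 3.0, 3)

    def test_constant_vector_sem_zero(self):
        assert summarize([2.2] * 10).sem == 0.0

    def test_min_le_mean_le_max(self):
        rng = np.random.default_rng(0)
        t = summarize(rng.lognormal(size=100))
        assert t.min <= t.mean <= t.max

    def test_too_small(self):
        with pytest.raises(EstimationError):
            summarize([1.0])

    def test_generated_sal_like_sample_mean(self):
        """SAL lengths implied by the calibrated generator: the SAS-equivalent
        diameter has a mean in the observed SAL neighbourhood."""
        sp = generate_population(340, seed=1)
        sal_equiv = [2 * math.sqrt(s.sas_area / math.pi) for s in sp]
        assert 0.26 <= summarize(sal_equiv).mean <= 0.32


class TestFrequencyCurve:
    def test_two_bin_example(self):
        f = frequency_curve([0.05, 0.05, 0.15], HistogramSpec(0.0, 0.1, 2))
        assert np.allclose(f, [2 / 3, 1 / 3])

    def test_single_bin_mass(self):
        f = frequency_curve([0.01, 0.02, 0.03], HistogramSpec(0.0, 1.0, 5))
        assert f[0] == 1.0 and f[1:].sum() == 0.0

    def test_overflow_clipped_into_last_bin(self):
        f = frequency_curve([0.05, 99.0], HistogramSpec(0.0, 0.1, 3))
        assert f[0] == 0.5 and f[-1] == 0.5

    def test_uniform_sample_near_flat(self):
        rng = np.random.default_rng(7)
        f = frequency_curve(rng.uniform(0, 1, 50_000), HistogramSpec(0.0, 0.1, 10))
        chi2 = 50_000 * 10 * np.sum((f - 0.1) ** 2) / 1.0  # vs Uniform, 9 dof
        assert chi2 < sps.chi2.ppf(0.999, df=9)

    @pytest.mark.parametrize("spec", [LENGTH_BINS, AREA_BINS, VOLUME_BINS])
    def test_frequencies_sum_to_one(self, spec):
        rng = np.random.default_rng(3)
        f = frequency_curve(rng.lognormal(-2, 0.8, 500), spec)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(f) == spec.n_bins

    def test_empty_input(self):
        with pytest.raises(EstimationError):
            frequency_curve([], LENGTH_BINS)

    def test_bad_spec(self):
        with pytest.raises(ConfigError):
            HistogramSpec(0.0, -0.1, 5)


class TestSpearman:
    def test_monotone_pairs(self):
        x = [0.1, 0.5, 2.0, 7.0]
        assert spearman(x, [1, 2, 3, 4]) == pytest.approx(1.0)
        assert spearman(x, [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert spearman(x, y) == pytest.approx(spearman(y, x), abs=1e-15)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(perm=st.permutations(list(range(8))))
    def test_matches_rank_formula_oracle_no_ties(self, perm):
        x = list(range(8))
        assert spearman(x, perm) == pytest.approx(rank_formula_rho(x, perm), abs=1e-12)

    def test_matches_midrank_pearson_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.integers(0, 5, 30).astype(float)  # heavy ties
            y = rng.integers(0, 5, 30).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            oracle = np.corrcoef(midrank(list(x)), midrank(list(y)))[0, 1]
            assert spearman(x, y) == pytest.approx(float(oracle), abs=1e-12)

    def test_constant_vector_signalled(self):
        with pytest.raises(EstimationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_length_mismatch(self):
        with pytest.raises(ConfigError):
            spearman([1, 2], [1, 2, 3])


def exact_mw_p(a, b):
    """Full-enumeration oracle for the two-sided Mann-Whitney p-value."""
    pooled = list(a) + list(b)
    n1 = len(a)
    obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    stats_all = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
            1 for x in ga for y in gb if x == y
        )
        stats_all.append(u)
    mean_u = n1 * (len(pooled) - n1) / 2.0
    dev = abs(obs - mean_u)
    return sum(1 for u in stats_all if abs(u - mean_u) >= dev - 1e-12) / len(stats_all)


class TestCompareGroups:
    def test_identical_groups_high_p(self):
        g = list(range(1, 21))
        rep = compare_groups(g, g)
        assert rep.p_value > 0.9

    def test_well_separated_groups(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(8.0, 1.0, 50)
        rep = compare_groups(a, b)
        assert rep.test == "mann_whitney_asymptotic"
        assert rep.p_value < 0.001

    def test_exact_small_sample_matches_enumeration_oracle(self):
        a = [1.2, 3.4, 2.2, 5.1, 0.3]
        b = [2.9, 6.4, 7.7, 4.8, 5.9]
        rep = compare_groups(a, b)
        assert rep.test == "mann_whitney_exact"
        assert rep.p_value == pytest.approx(exact_mw_p(a, b), abs=1e-12)

    def test_three_equal_mean_groups_f_near_one(self):
        rng = np.random.default_rng(9)
        fs = []
        for _ in range(300):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            fs.append(compare_groups(*groups).statistic)
        # E[F(2, 27)] = 27/25 = 1.08
        assert np.mean(fs) == pytest.approx(27 / 25, abs=0.15)

    def test_anova_selected_for_three_groups(self):
        rng = np.random.default_rng(4)
        rep = compare_groups(*(rng.normal(0, 1, 15) for _ in range(3)))
        assert rep.test == "anova_oneway"
        assert rep.group_sizes == (15, 15, 15)

    def test_config_errors(self):
        with pytest.raises(ConfigError):
            compare_groups([1.0, 2.0])
        with pytest.raises(ConfigError):
            compare_groups([1.0], [2.0, 3.0])
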