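import math

import numpy as np
import pytest
from scipy import stats

from acceptorkit.feature_stats import (bh_adjust, binomial_two_tail,
                                       chi_square_contingency,
                                       compare_feature, composition_at,
                                       fisher_z_interval,
                                       hypergeometric_enrichment,
                                       pearson_correlation,
                                       positional_nucleotide_frequencies,
                                       wilcoxon_rank_sum)
from conftest import make_region


class TestPositionalFrequencies:
    def test_identical_regions_give_indicators(self):
        regs = [make_region("UUCAG", "GAAAA") for _ in range(10)]
        table = positional_nucleotide_frequencies(regs)
        assert table.prob(-1, "G") == 1.0
        assert table.prob(-1, "A") == 0.0
        assert table.counts[-1] == 10

    def test_uniform_random_within_binomial_bound(self, rng):
        regs = [make_region("".join(rng.choice(list("ACGU"), size=20)),
                            "".join(rng.choice(list("ACGU"), size=5)))
                for _ in range(500)]
        table = positional_nucleotide_frequencies(regs)
        for off in table.offsets:
            assert np.abs(table.probabilities[off] - 0.25).max() < 0.07

    def test_planted_a_depletion_shows_negative_log_ratio(self, small_cohort):
        up = positional_nucleotide_frequencies(
            small_cohort.regions_by_group("up"))
        ctrl = positional_nucleotide_frequencies(
            small_cohort.regions_by_group("control"))
        ratios = up.log2_ratio(ctrl, "A")
        zone = [ratios[o] for o in range(-38, -17)]
        assert np.mean(zone) < 0
        assert np.mean(zone) < np.mean([ratios[o] for o in range(-12, -3)])

    def test_n_excluded_from_denominator(self):
        regs = [make_region("NNCAG"), make_region("UUCAG")]
        table = positional_nucleotide_frequencies(regs)
        assert table.counts[-5] == 1
        assert table.prob(-5, "U") == 1.0


class TestCompositionAt:
    def test_all_c_at_minus3(self):
        regs = [make_region("UUCAG") for _ in range(7)]
        assert composition_at(regs, -3).tolist() == [0, 7, 0, 0]

    def test_hand_counted_mixed_set(self):
        regs = [make_region(u) for u in ("AACAG", "ACCAG", "GUCAG", "UUCAG")]
        assert composition_at(regs, -5).tolist() == [2, 0, 1, 1]
        assert composition_at(regs, -4).tolist() == [1, 1, 0, 2]

    def test_planted_composition_shift_detected(self, rng):
        a = [make_region("UU" + "C" + "AG") for _ in range(100)] + \
            [make_region("UU" + "U" + "AG") for _ in range(100)]
        b = [make_region("UU" + ("C" if rng.random() < 0.2 else "A") + "AG")
             for _ in range(200)]
        table = np.vstack([composition_at(a, -3), composition_at(b, -3)])
        table = table[:, table.sum(axis=0) > 0]
        res = chi_square_contingency(table)
        assert res.p < 0.01


class TestCompareFeature:
    def test_identical_groups(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        t = compare_feature(vals, vals, "t")
        w = compare_feature(vals, vals, "wilcoxon")
        assert t.statistic == pytest.approx(0.0)
        assert w.p == pytest.approx(1.0)

    def test_planted_agez_separation_power(self, rng):
        a = rng.normal(70, 15, size=100)
        b = rng.normal(40, 12, size=100)
        assert compare_feature(a, b, "t").p < 1e-6
        assert compare_feature(a, b, "wilcoxon").p < 1e-6

    def test_location_shift_invariance(self, rng):
        a = rng.normal(0, 1, size=30)
        b = rng.normal(0.5, 1, size=30)
        p0 = compare_feature(a, b, "t").p
        p1 = compare_feature(a + 100, b + 100, "t").p
        assert p0 == pytest.approx(p1, rel=1e-9)

    def test_zero_variance_equal_means_p_one(self):
        res = compare_feature([2.0, 2.0, 2.0], [2.0, 2.0], "t")
        assert res.p == 1.0

    def test_statistic_sign_follows_mean_difference(self, rng):
        a = rng.normal(5, 1, size=20)
        b = rng.normal(0, 1, size=20)
        assert compare_feature(a, b, "t").statistic > 0
        assert compare_feature(b, a, "t").statistic < 0


class TestWilcoxon:
    def test_exact_small_samples_match_scipy_exact(self, rng):
        a = list(rng.normal(0, 1, size=8))
        b = list(rng.normal(1, 1, size=9))
        res = wilcoxon_rank_sum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact")
        assert res.p == pytest.approx(float(ref.pvalue))

    def test_ties_fall_back_to_normal_approximation(self):
        a = [1.0, 1.0, 2.0, 3.0]
        b = [1.0, 2.0, 2.0, 4.0]
        res = wilcoxon_rank_sum(a, b)
        assert 0.0 < res.p <= 1.0


class TestBinomialTwoTail:
    def test_site_pair_counts_give_p_003(self):
        assert round(binomial_two_tail(51, 138, 0.5), 3) == 0.003

    def test_balanced_is_one(self):
        assert binomial_two_tail(5, 10, 0.5) == pytest.approx(1.0)

    def test_direct_pmf_summation_oracle(self):
        k, n = 10, 30
        pk = stats.binom.pmf(k, n, 0.5)
        expected = sum(stats.binom.pmf(i, n, 0.5)
                       for i in range(n + 1)
                       if stats.binom.pmf(i, n, 0.5) <= pk * (1 + 1e-12))
        assert binomial_two_tail(k, n, 0.5) == pytest.approx(expected)

    def test_symmetry_at_half(self):
        for k, n in [(0, 8), (3, 10), (17, 40), (51, 138)]:
            assert binomial_two_tail(k, n, 0.5) == \
                binomial_two_tail(n - k, n, 0.5)


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        res = chi_square_contingency([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_diagonal_2x2_closed_form(self):
        res = chi_square_contingency([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.p == pytest.approx(float(stats.chi2.sf(20.0, 1)))

    def test_textbook_formula_oracle(self, rng):
        table = rng.integers(1, 40, size=(3, 2)).astype(float)
        res = chi_square_contingency(table)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        exp = row * col / table.sum()
        stat = float(((table - exp) ** 2 / exp).sum())
        assert res.statistic == pytest.approx(stat)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_contingency([[0, 0], [1, 2]])


class TestHypergeometric:
    def test_degenerate_all_ones(self):
        assert hypergeometric_enrichment(1, 1, 1, 1) == pytest.approx(1.0)

    def test_closed_form_small_case(self):
        # P(X >= 2) drawing 2 of 4 with 2 marked = C(2,2)/C(4,2) = 1/6
        assert hypergeometric_enrichment(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_direct_summation_oracle(self):
        k, m, K, N = 14, 51, 300, 5000
        expected = sum(
            math.comb(K, i) * math.comb(N - K, m - i) / math.comb(N, m)
            for i in range(k, min(m, K) + 1))
        assert hypergeometric_enrichment(k, m, K, N) == \
            pytest.approx(expected, rel=1e-9)


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, [2 * v for v in x]).statistic == \
            pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]).statistic == \
            pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        r0 = pearson_correlation(x, y).statistic
        r1 = pearson_correlation(3 * x + 7, 0.5 * y - 2).statistic
        assert r0 == pytest.approx(r1)

    def test_planted_correlation_within_fisher_interval(self, rng):
        n, r = 100, 0.4
        x = rng.normal(size=n)
        y = r * x + math.sqrt(1 - r * r) * rng.normal(size=n)
        est = pearson_correlation(x, y).statistic
        lo, hi = fisher_z_interval(r, n)
        assert lo <= est <= hi

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBHAdjust:
    def test_small_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == \
            pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_uniform_ps_stay_calibrated(self, rng):
        p = rng.uniform(size=100)
        q = np.array(bh_adjust(p))
        assert q.min() >= p.min() - 1e-12
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
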