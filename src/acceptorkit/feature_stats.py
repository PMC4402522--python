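"""Group-level statistics for splice-site feature comparisons.

Thin, contract-stable wrappers around scipy.stats / statsmodels plus the
positional composition profiles.  Every test returns a `GroupComparison`
so results can be collected into a single tab-separated statistics ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sequence_io import ThreePrimeRegion
from .splice_architecture import BASES, _BASE_INDEX

LOG_RATIO_CLAMP = 5.0


@dataclass
class GroupComparison:
    test: str                    # t, wilcoxon, binomial, chi2,
                                 # hypergeometric, pearson
    statistic: float
    p: float
    n_a: int = 0
    n_b: int = 0
    effect: float = float("nan")   # difference of means, or r
    q: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")


@dataclass
class PositionalFrequencyTable:
    group: str
    offsets: list[int]
    probabilities: dict[int, np.ndarray]   # offset -> (4,) probs over ACGU
    counts: dict[int, int]                 # non-N observations per offset

    def prob(self, offset: int, base: str) -> float:
        return float(self.probabilities[offset][_BASE_INDEX[base]])

    def log2_ratio(self, other: "PositionalFrequencyTable", base: str,
                   ) -> dict[int, float]:
        """Per-offset log2 enrichment of one base, self over other.

        Ratios involving a zero cell are clamped at +/-5.
        """
        out: dict[int, float] = {}
        for off in self.offsets:
            if off not in other.probabilities:
                continue
            a = self.prob(off, base)
            b = other.prob(off, base)
            if a == 0.0 and b == 0.0:
                out[off] = 0.0
            elif a == 0.0:
                out[off] = -LOG_RATIO_CLAMP
            elif b == 0.0:
                out[off] = LOG_RATIO_CLAMP
            else:
                out[off] = max(-LOG_RATIO_CLAMP,
                               min(LOG_RATIO_CLAMP, math.log2(a / b)))
        return out


def positional_nucleotide_frequencies(regions: Sequence[ThreePrimeRegion],
                                      offsets: Sequence[int] | None = None,
                                      group: str = "",
                                      ) -> PositionalFrequencyTable:
    """Per-offset base probabilities over a group of anchored windows.

    N never enters a denominator: probabilities at an offset are computed
    over the regions with a determinate base there.
    """
    if not regions:
        raise ValueError("need at least one region")
    if offsets is None:
        lo = min(-r.up_len for r in regions)
        hi = max(r.down_len for r in regions)
        offsets = range(lo, hi)
    probs: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    kept: list[int] = []
    for off in offsets:
        vec = np.zeros(4)
        for r in regions:
            if -r.up_len <= off < r.down_len:
                base = r.base_at(off)
                if base != "N":
                    vec[_BASE_INDEX[base]] += 1
        total = int(vec.sum())
        if total == 0:
            continue
        kept.append(off)
        probs[off] = vec / total
        counts[off] = total
    return PositionalFrequencyTable(
        group=group or (regions[0].group if regions else ""),
        offsets=kept, probabilities=probs, counts=counts)


def composition_at(regions: Sequence[ThreePrimeRegion], offset: int,
                   ) -> np.ndarray:
    """Base counts (A, C, G, U) at one offset across regions; N skipped."""
    vec = np.zeros(4, dtype=int)
    for r in regions:
        if -r.up_len <= offset < r.down_len:
            base = r.base_at(offset)
            if base != "N":
                vec[_BASE_INDEX[base]] += 1
    return vec


def compare_feature(values_a: Sequence[float], values_b: Sequence[float],
                    test: str = "t") -> GroupComparison:
    """Two-sided comparison of a per-exon feature between two groups.

    ``t`` is Welch's unequal-variance t-test; ``wilcoxon`` the
    Wilcoxon-Mann-Whitney rank-sum test.  The statistic's sign follows
    mean(a) - mean(b).  Two zero-variance groups with equal means give
    p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    effect = float(a.mean() - b.mean())
    if a.std() == 0.0 and b.std() == 0.0:
        if effect == 0.0:
            return GroupComparison(test, 0.0, 1.0, len(a), len(b), 0.0)
        if test == "t":
            sign = math.copysign(math.inf, effect)
            return GroupComparison(test, sign, 0.0, len(a), len(b), effect)
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison("t", float(res.statistic), float(res.pvalue),
                               len(a), len(b), effect)
    if test == "wilcoxon":
        res = wilcoxon_rank_sum(a, b)
        res.effect = effect
        return res
    raise ValueError(f"unknown test {test!r}")


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float],
                      exact_max_n: int = 12) -> GroupComparison:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact null distribution when both groups have n <= ``exact_max_n`` and
    the pooled data are tie-free; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return GroupComparison("wilcoxon", float(len(a) * len(b)) / 2.0, 1.0,
                               len(a), len(b), 0.0)
    method = ("exact" if len(a) <= exact_max_n and len(b) <= exact_max_n
              and not has_ties else "asymptotic")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return GroupComparison("wilcoxon", float(res.statistic),
                           float(min(res.pvalue, 1.0)),
                           len(a), len(b), float(a.mean() - b.mean()))


def binomial_two_tail(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial test by the point-probability method.

    The p-value sums the probabilities of all outcomes whose point
    probability does not exceed that of the observed count, capped at 1.
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("need 0 < p0 < 1")
    if n == 0:
        return 1.0
    return float(min(1.0, stats.binomtest(k, n, p0).pvalue))


def chi_square_contingency(table: Sequence[Sequence[float]],
                           ) -> GroupComparison:
    """Pearson chi-square test of independence (no continuity correction)."""
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(arr, correction=False)
    return GroupComparison("chi2", float(res.statistic), float(res.pvalue),
                           int(arr.sum()), 0, float(res.dof))


def hypergeometric_enrichment(hits_in_set: int, set_size: int,
                              hits_total: int, universe: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k) drawing ``set_size`` from
    ``universe`` with ``hits_total`` marked."""
    k, m, K, N = hits_in_set, set_size, hits_total, universe
    if not (0 <= k <= min(m, K) and K <= N and m <= N):
        raise ValueError("inconsistent hypergeometric counts")
    return float(stats.hypergeom.sf(k - 1, N, K, m))


def pearson_correlation(x: Sequence[float], y: Sequence[float],
                        ) -> GroupComparison:
    """Pearson r with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined for a zero-variance variable")
    res = stats.pearsonr(x, y)
    return GroupComparison("pearson", float(res.statistic),
                           float(res.pvalue), len(x), len(y),
                           effect=float(res.statistic))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def fisher_z_interval(r: float, n: int, level: float = 0.95,
                      ) -> tuple[float, float]:
    """Confidence interval for a correlation via the Fisher z-transform."""
    if not (-1.0 < r < 1.0) or n < 4:
        raise ValueError("need -1 < r < 1 and n >= 4")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    return math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)
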