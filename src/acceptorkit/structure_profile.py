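"""Equilibrium single-strandedness (PU) profiles across 3' splice sites.

The energy model is deliberately simple and fully specified: a
pair-additive model in which every admissible base pair (Watson-Crick plus
G·U) contributes a fixed stabilizing energy, structures are pseudoknot-free
with a minimum hairpin loop of 3 unpaired nucleotides, and the Boltzmann
weight of a structure is ``exp(-E/kT)`` with E the sum of its pair
energies.  The empty structure has weight 1, so the partition function Z is
always >= 1.  McCaskill-style inside-outside recursions give exact base
pair probabilities p(i,j) in cubic time; the probability of a position
being unpaired is ``PU_i = 1 - sum_j p(i,j)``.

An exhaustive enumeration oracle (`enumerate_structures`) verifies the
dynamic program on short sequences.  An adapter slot (`fold_fn`) on the
profile functions allows swapping in an external folding engine without
changing any downstream contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import ThreePrimeRegion, extract_three_prime_region

DEFAULT_PAIR_ENERGIES = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


@dataclass(frozen=True)
class EnergyModel:
    """Pair-additive RNA secondary-structure energy model.

    Energies in kcal/mol (negative = favorable); ``kT`` defaults to
    0.616 kcal/mol (37 C); ``min_hairpin`` is the minimum number of
    unpaired nucleotides enclosed by a hairpin-closing pair.
    """

    pair_energy: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_ENERGIES))
    min_hairpin: int = 3
    kT: float = 0.616

    def __post_init__(self) -> None:
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    def weight(self, a: str, b: str) -> float:
        """Boltzmann weight of pairing bases a and b (0 if not allowed)."""
        e = self.pair_energy.get((a, b))
        if e is None or "N" in (a, b):
            return 0.0
        return math.exp(-e / self.kT)

    def shifted(self, delta: float) -> "EnergyModel":
        """Model with every pair energy made less favorable by +delta."""
        return EnergyModel(
            pair_energy={k: v + delta for k, v in self.pair_energy.items()},
            min_hairpin=self.min_hairpin, kT=self.kT)


@dataclass
class PairProbabilityMatrix:
    n: int
    p: np.ndarray          # (n, n) symmetric pairing probabilities
    Z: float               # partition function (scale-corrected; may be inf
                           # for very long, very stable sequences)
    log_Z: float           # always finite

    def unpaired_probabilities(self) -> np.ndarray:
        return 1.0 - self.p.sum(axis=1)


def _pair_weights(seq: str, model: EnergyModel) -> np.ndarray:
    n = len(seq)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + model.min_hairpin + 1, n):
            w[i, j] = model.weight(seq[i], seq[j])
    return w


def _validate_sequence(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"invalid letters for folding: {sorted(bad)}")
    return seq


def partition_function(seq: str, model: EnergyModel | None = None,
                       ) -> PairProbabilityMatrix:
    """Exact base-pair probabilities under the pair-additive model.

    Inside recursion (``Zb`` restricted to i,j paired)::

        Zb[i,j] = w(i,j) * Z[i+1,j-1]
        Z[i,j]  = Z[i,j-1] + sum_k Z[i,k-1] * Zb[k,j]

    followed by an outside pass accumulating, for each pair, the weight of
    its exterior (including enclosing pairs).  Arrays are rescaled by a
    per-nucleotide factor when the raw partition function would overflow.
    """
    if model is None:
        model = EnergyModel()
    seq = _validate_sequence(seq)
    if len(seq) > 5000:
        raise ValueError("sequence longer than the 5000 nt folding cap")
    w = _pair_weights(seq, model)
    with np.errstate(over="ignore", invalid="ignore"):
        result = _mccaskill(len(seq), w, scale=1.0)
    if result is None:     # overflow: rescale per nucleotide and redo
        wmax = float(w.max())
        result = _mccaskill(len(seq), w, scale=math.sqrt(max(wmax, math.e)))
        if result is None:
            raise OverflowError("partition function overflow despite rescaling")
    return result


def _mccaskill(n: int, w: np.ndarray, scale: float,
               ) -> PairProbabilityMatrix | None:
    if n == 0:
        return PairProbabilityMatrix(0, np.zeros((0, 0)), 1.0, 0.0)
    inv = 1.0 / scale
    what = w * inv * inv
    Z = np.zeros((n, n))       # Z[i,j] for i<=j, scaled by scale^(j-i+1)
    Zb = np.zeros((n, n))

    def zrow(i: int, j: int) -> float:
        # scaled partition of subsequence i..j; 1.0 for the empty interval
        return 1.0 if j < i else Z[i, j]

    for j in range(n):
        col = np.empty(j + 1)
        # Zb column
        inner = np.ones(j + 1)
        if j >= 2:
            inner[: j - 1] = Z[1: j, j - 1]
        Zb[: j + 1, j] = what[: j + 1, j] * inner
        # Z column: start from the "j unpaired" term
        if j == 0:
            col[0] = inv
        else:
            col[: j] = Z[: j, j - 1] * inv
            col[j] = inv
        for k in range(j + 1):
            zb = Zb[k, j]
            if zb == 0.0:
                continue
            col[k] += zb                      # i = k: empty left interval
            if k > 0:
                col[:k] += zb * Z[:k, k - 1]  # i < k: Z[i, k-1] left factor
        Z[: j + 1, j] = col

    Ztot = Z[0, n - 1]
    if not np.isfinite(Ztot) or Ztot == 0.0:
        return None

    # outside pass: p[i,j] via the innermost-enclosing-pair decomposition,
    # with accumulator T[i2, l] = sum over already-processed pairs (k, l)
    # with k < i2 of p[k,l] * Z[k+1, i2-1] / Z[k+1, l-1]
    p = np.zeros((n, n))
    T = np.zeros((n, n))
    for span in range(n, 0, -1):
        updates = []
        for i in range(0, n - span + 1):
            j = i + span - 1
            zb = Zb[i, j]
            if zb == 0.0:
                continue
            left = zrow(0, i - 1)
            right = zrow(j + 1, n - 1)
            s = left * right / Ztot
            if j + 1 < n:
                m = n - 1 - j            # l runs over j+1 .. n-1
                zr = np.empty(m)
                zr[0] = 1.0
                if m > 1:
                    zr[1:] = Z[j + 1, j + 1: n - 1]
                s += float(np.dot(T[i, j + 1: n], zr))
            pij = zb * s
            if pij > 0.0:
                p[i, j] = pij
                updates.append((i, j, pij))
        for i, j, pij in updates:
            if j - i < 2:
                continue
            c = pij / zrow(i + 1, j - 1)
            m = j - i - 1                # i2 runs over i+1 .. j-1
            vec = np.empty(m)
            vec[0] = 1.0
            if m > 1:
                vec[1:] = Z[i + 1, i + 1: j - 1]
            T[i + 1: j, j] += c * vec

    if not np.all(np.isfinite(p)):
        return None
    p = p + p.T
    log_Z = math.log(Ztot) + n * math.log(scale)
    Zraw = math.exp(log_Z) if log_Z < 700 else math.inf
    return PairProbabilityMatrix(n=n, p=p, Z=Zraw, log_Z=log_Z)


# --- exhaustive oracle ------------------------------------------------------

def _all_structures(seq: str, model: EnergyModel, i: int, j: int,
                    memo: dict) -> list[tuple[tuple[int, int], ...]]:
    """All pseudoknot-free pair sets on seq[i..j], as tuples of (i, j)."""
    if i > j:
        return [()]
    key = (i, j)
    if key in memo:
        return memo[key]
    out = list(_all_structures(seq, model, i + 1, j, memo))
    for k in range(i + model.min_hairpin + 1, j + 1):
        if model.weight(seq[i], seq[k]) == 0.0:
            continue
        for left in _all_structures(seq, model, i + 1, k - 1, memo):
            for right in _all_structures(seq, model, k + 1, j, memo):
                out.append(((i, k),) + left + right)
    memo[key] = out
    return out


def enumerate_structures(seq: str, model: EnergyModel | None = None,
                         max_length: int = 22,
                         ) -> tuple[float, np.ndarray]:
    """Brute-force oracle: (Z, exact pair probabilities) by enumeration.

    Refuses sequences longer than ``max_length``; intended only to verify
    `partition_function` on small inputs.
    """
    if model is None:
        model = EnergyModel()
    seq = _validate_sequence(seq)
    n = len(seq)
    if n > max_length:
        raise ValueError(f"enumeration capped at {max_length} nt, got {n}")
    structures = _all_structures(seq, model, 0, n - 1, {})
    Z = 0.0
    p = np.zeros((n, n))
    for pairs in structures:
        e = sum(model.pair_energy[(seq[i], seq[j])] for i, j in pairs)
        wgt = math.exp(-e / model.kT)
        Z += wgt
        for i, j in pairs:
            p[i, j] += wgt
    p /= Z
    return Z, p + p.T


# --- PU profiles ------------------------------------------------------------

FoldFunction = Callable[[str], np.ndarray]
"""Adapter type: maps an RNA sequence to its per-position PU vector."""


@dataclass
class PUProfile:
    group: str
    offsets: list[int]
    mean_pu: dict[int, float]
    n: dict[int, int]


@dataclass
class DeltaPUResult:
    offsets: list[int]
    delta: dict[int, float]            # mean PU(up) - mean PU(down)
    p: dict[int, float]                # raw two-sided Wilcoxon-Mann-Whitney
    q: dict[int, float]                # Benjamini-Hochberg across offsets
    star: dict[int, bool]              # raw p < 0.05, mirroring per-position
                                       # significance marking
    n_up: dict[int, int]
    n_down: dict[int, int]


def _default_fold(model: EnergyModel) -> FoldFunction:
    def fold(seq: str) -> np.ndarray:
        return partition_function(seq, model).unpaired_probabilities()
    return fold


def pu_profile_region(region: ThreePrimeRegion,
                      model: EnergyModel | None = None,
                      flank: int = 30,
                      genome: Mapping[str, str] | None = None,
                      exon=None,
                      fold_fn: FoldFunction | None = None,
                      ) -> dict[int, float]:
    """Per-offset unpaired probabilities for one 3'ss window.

    When ``genome`` and ``exon`` are given, the window is re-extracted with
    ``flank`` extra nucleotides on each side, folded once, and PU reported
    only for the original offsets.  Without genome context the bare region
    is folded (equivalent to flank = 0).
    """
    if model is None:
        model = EnergyModel()
    if fold_fn is None:
        fold_fn = _default_fold(model)
    if genome is not None and exon is not None and flank > 0:
        ext = extract_three_prime_region(
            genome, exon, up_len=region.up_len + flank,
            down_len=region.down_len + flank)
        pu = fold_fn(ext.sequence)
        return {off: float(pu[ext.index_of(off)]) for off in region.offsets}
    pu = fold_fn(region.sequence)
    return {off: float(pu[region.index_of(off)]) for off in region.offsets}


def group_pu_profile(regions: Sequence[ThreePrimeRegion],
                     model: EnergyModel | None = None,
                     flank: int = 30,
                     genome: Mapping[str, str] | None = None,
                     exons: Mapping[str, object] | None = None,
                     group: str = "",
                     fold_fn: FoldFunction | None = None,
                     ) -> PUProfile:
    """Arithmetic mean PU per offset over a group of regions."""
    if not regions:
        raise ValueError("group_pu_profile needs at least one region")
    per_region = _per_region_pu(regions, model, flank, genome, exons, fold_fn)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for pus in per_region:
        for off, val in pus.items():
            sums[off] = sums.get(off, 0.0) + val
            counts[off] = counts.get(off, 0) + 1
    offsets = sorted(sums)
    return PUProfile(
        group=group or regions[0].group,
        offsets=offsets,
        mean_pu={o: sums[o] / counts[o] for o in offsets},
        n=dict(counts),
    )


def _per_region_pu(regions, model, flank, genome, exons, fold_fn,
                   ) -> list[dict[int, float]]:
    out = []
    for region in regions:
        exon = exons.get(region.exon_id) if exons else None
        out.append(pu_profile_region(region, model=model, flank=flank,
                                     genome=genome, exon=exon,
                                     fold_fn=fold_fn))
    return out


def delta_pu(up_regions: Sequence[ThreePrimeRegion],
             down_regions: Sequence[ThreePrimeRegion],
             model: EnergyModel | None = None,
             flank: int = 30,
             genome: Mapping[str, str] | None = None,
             exons: Mapping[str, object] | None = None,
             fold_fn: FoldFunction | None = None,
             alpha: float = 0.05,
             ) -> DeltaPUResult:
    """Positional delta-PU (mean up minus mean down) with Wilcoxon tests.

    At each offset covered by both groups the per-region PU values are
    compared by a two-sided Wilcoxon-Mann-Whitney test (exact when both
    groups have n <= 12 and no ties; tie-corrected normal approximation
    with continuity correction otherwise).  Offsets with fewer than two
    regions in either group get no p-value.  BH-adjusted q-values are
    reported alongside; the significance star uses the raw p.
    """
    from .feature_stats import bh_adjust, wilcoxon_rank_sum

    if not up_regions or not down_regions:
        raise ValueError("both groups must be non-empty")
    pu_up = _per_region_pu(up_regions, model, flank, genome, exons, fold_fn)
    pu_down = _per_region_pu(down_regions, model, flank, genome, exons, fold_fn)

    by_off_up: dict[int, list[float]] = {}
    by_off_down: dict[int, list[float]] = {}
    for pus in pu_up:
        for off, v in pus.items():
            by_off_up.setdefault(off, []).append(v)
    for pus in pu_down:
        for off, v in pus.items():
            by_off_down.setdefault(off, []).append(v)

    offsets = sorted(set(by_off_up) & set(by_off_down))
    delta: dict[int, float] = {}
    pvals: dict[int, float] = {}
    n_up: dict[int, int] = {}
    n_down: dict[int, int] = {}
    for off in offsets:
        a = by_off_up[off]
        b = by_off_down[off]
        n_up[off] = len(a)
        n_down[off] = len(b)
        delta[off] = float(np.mean(a) - np.mean(b))
        if len(a) >= 2 and len(b) >= 2:
            pvals[off] = wilcoxon_rank_sum(a, b).p
    tested = [o for o in offsets if o in pvals]
    qvals = dict(zip(tested, bh_adjust([pvals[o] for o in tested])))
    star = {o: (o in pvals and pvals[o] < alpha) for o in offsets}
    return DeltaPUResult(offsets=offsets, delta=delta, p=pvals, q=qvals,
                         star=star, n_up=n_up, n_down=n_down)


def pu_substring(seq: str, start: int, length: int,
                 model: EnergyModel | None = None) -> float:
    """Probability that an entire substring is unpaired (constrained-Z ratio).

    Positions ``start .. start+length-1`` are forbidden from pairing and the
    constrained partition function is divided by the unconstrained one.
    Substring length 1 reduces to the positional PU used by the pipeline.
    """
    if model is None:
        model = EnergyModel()
    seq = _validate_sequence(seq)
    n = len(seq)
    if not (0 <= start and start + length <= n and length >= 1):
        raise ValueError("substring outside sequence")
    w = _pair_weights(seq, model)
    full = _mccaskill(n, w, 1.0)
    wc = w.copy()
    wc[start: start + length, :] = 0.0
    wc[:, start: start + length] = 0.0
    constrained = _mccaskill(n, wc, 1.0)
    if full is None or constrained is None:
        raise OverflowError("partition function overflow in pu_substring")
    return math.exp(constrained.log_Z - full.log_Z)
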