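"""3' splice-site architecture: AGEZ, branch points, PPT and site strength.

The AG exclusion zone (AGEZ) is the stretch upstream of the 3'ss AG devoid
of other AG dinucleotides; the branch point (BP) is scored with a log-odds
weight matrix over a 7-mer window with the branch adenosine fixed at
position 6 (yUnAy-style consensus) — a deliberate, documented
approximation of SVM-based BP predictors; the polypyrimidine tract (PPT)
is the best-scoring contiguous pyrimidine-rich window between the best BP
and offset -3.  Intrinsic splice-site strength is a frequency-matrix
(position weight matrix) log-odds score in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import ThreePrimeRegion

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PYRIMIDINES = frozenset("CU")
PURINES = frozenset("AG")

#: Default branch-point training alignment: 7-mers with the branch A at
#: position 6 (1-based), following the yUnAy-style consensus around the
#: canonical UACUAAC.  Packaged so the scorer works out of the box; users
#: can train on their own aligned sites.
DEFAULT_BP_SITES = (
    "UACUAAC", "CACUAAC", "UGCUAAC", "UACUGAC", "CUCUAAC",
    "UUCUAAC", "CACUGAC", "UACUCAC", "CUGUAAC", "UUCUGAC",
    "CGCUAAC", "UACUAAU", "CACUAAU", "UCCUAAC", "UUCUAAU",
    "CUCUGAC",
)

#: Position of the branch adenosine inside the BP scoring window (0-based).
BP_BRANCH_INDEX = 5

#: Default BP search range (offsets of the branch A), 3'ss-proximal first.
BP_SEARCH_RANGE = (-9, -100)

# PPT scoring constants (declared, overridable): pyrimidine +1, purine -2,
# minimum window length 5, minimum pyrimidine fraction 0.6.
PPT_PYRIMIDINE_SCORE = 1
PPT_PURINE_SCORE = -2
PPT_MIN_LENGTH = 5
PPT_MIN_FRACTION = 0.6


@dataclass(frozen=True)
class AGEZResult:
    exon_id: str
    agez_length: int
    upstream_ag_offset: int | None   # offset of the G of the nearest upstream AG
    censored: bool
    canonical: bool = True


@dataclass(frozen=True)
class BranchPointCandidate:
    bp_offset: int          # signed offset of the branch adenosine
    score: float            # bits
    window: str


@dataclass(frozen=True)
class PPTResult:
    exon_id: str
    bp_offset: int
    ppt_start_offset: int | None
    ppt_end_offset: int | None
    ppt_length: int
    pyrimidine_fraction: float


@dataclass(frozen=True)
class SiteModel:
    """A per-position frequency matrix with log-odds scoring."""

    site_type: str                      # one of {"3ss", "5ss", "bp"}
    columns: np.ndarray                 # (length, 4) probabilities over ACGU
    background: np.ndarray              # (4,) probabilities
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "background", bg)
        if cols.ndim != 2 or cols.shape[1] != 4:
            raise ValueError("columns must be (length, 4)")
        if not np.allclose(cols.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every column must sum to 1")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.columns.shape[0]


def find_agez(region: ThreePrimeRegion) -> AGEZResult:
    """Locate the nearest upstream AG and measure the AG exclusion zone.

    Scans 3'ss-proximal to distal for the first AG dinucleotide whose G
    sits at offset <= -3.  The AGEZ length counts the nucleotides strictly
    between that G and the A of the 3'ss AG, i.e. ``|g_offset| - 3``.  If
    no AG exists in the window the result is censored with
    ``agez_length = up_len - 2``.
    """
    up = region.upstream()
    up_len = region.up_len
    if up_len < 4:
        raise ValueError("find_agez needs up_len >= 4")
    for g_off in range(-3, -up_len, -1):
        g_idx = up_len + g_off
        if up[g_idx] == "G" and up[g_idx - 1] == "A":
            return AGEZResult(
                exon_id=region.exon_id,
                agez_length=-g_off - 3,
                upstream_ag_offset=g_off,
                censored=False,
                canonical=region.canonical,
            )
    return AGEZResult(
        exon_id=region.exon_id,
        agez_length=up_len - 2,
        upstream_ag_offset=None,
        censored=True,
        canonical=region.canonical,
    )


def count_purine_dinucleotides(region: ThreePrimeRegion, dinucleotide: str,
                               ) -> dict[int, int]:
    """Mark upstream offsets where a purine dinucleotide starts.

    Returns ``{offset: 0/1}`` over offsets ``-up_len .. -3`` where 1 means
    the dinucleotide begins at that offset (the 3'ss AG itself, at -2/-1,
    is constant in canonical sites and is excluded).  Summed across a
    group these become per-offset occurrence frequencies, used to show
    that an AG dip is AG-specific and not shared by AA/GA/GG.
    """
    dinucleotide = dinucleotide.upper()
    if len(dinucleotide) != 2 or not set(dinucleotide) <= PURINES:
        raise ValueError("dinucleotide must be a 2-mer over {A, G}")
    up = region.upstream()
    out: dict[int, int] = {}
    for off in range(-region.up_len, -2):
        i = region.up_len + off
        out[off] = int(up[i: i + 2] == dinucleotide)
    return out


def train_site_model(aligned_sites: Sequence[str], site_type: str = "3ss",
                     pseudocount: float = 0.5,
                     background: Sequence[float] | str = "uniform",
                     ) -> SiteModel:
    """Build a frequency-matrix model from equal-length aligned sites.

    Column probabilities are ``(count + pseudocount) / (n + 4*pseudocount)``.
    ``background`` is ``"uniform"``, ``"empirical"`` (pooled base
    frequencies of the input) or an explicit 4-vector over ACGU.
    """
    if not aligned_sites:
        raise ValueError("need at least one site")
    length = len(aligned_sites[0])
    if any(len(s) != length for s in aligned_sites):
        raise ValueError("aligned sites must all have the same length")
    counts = np.zeros((length, 4))
    for s in aligned_sites:
        s = s.upper().replace("T", "U")
        for pos, base in enumerate(s):
            if base not in _BASE_INDEX:
                raise ValueError(f"invalid base {base!r} in site {s!r}")
            counts[pos, _BASE_INDEX[base]] += 1
    n = len(aligned_sites)
    cols = (counts + pseudocount) / (n + 4 * pseudocount)
    if isinstance(background, str):
        if background == "uniform":
            bg = np.full(4, 0.25)
        elif background == "empirical":
            total = counts.sum()
            bg = (counts.sum(axis=0) + pseudocount) / (total + 4 * pseudocount)
        else:
            raise ValueError(f"unknown background {background!r}")
    else:
        bg = np.asarray(background, dtype=float)
    return SiteModel(site_type=site_type, columns=cols, background=bg,
                     pseudocount=pseudocount)


def score_site(seq: str, model: SiteModel) -> float:
    """Log-odds score of a k-mer under a site model, in bits.

    ``sum_i log2(column_i[base_i] / background[base_i])``.  Sequences
    containing N are not scorable and raise a ValueError (callers flag
    them).
    """
    seq = seq.upper().replace("T", "U")
    if len(seq) != len(model):
        raise ValueError(f"sequence length {len(seq)} != model length {len(model)}")
    if "N" in seq:
        raise ValueError("cannot score a sequence containing N")
    total = 0.0
    for pos, base in enumerate(seq):
        b = _BASE_INDEX[base]
        p = model.columns[pos, b]
        q = model.background[b]
        if p == 0.0:
            return -math.inf
        total += math.log2(p / q)
    return total


def default_bp_model(pseudocount: float = 0.5) -> SiteModel:
    return train_site_model(DEFAULT_BP_SITES, site_type="bp",
                            pseudocount=pseudocount)


def score_branch_points(region: ThreePrimeRegion,
                        bp_model: SiteModel | None = None,
                        search_range: tuple[int, int] = BP_SEARCH_RANGE,
                        ) -> list[BranchPointCandidate]:
    """Score every candidate branch adenosine in the search range.

    One candidate per A whose 7-mer scoring window (branch A at window
    position 6) lies fully inside the region.  Sorted by score descending;
    ties broken toward the 3'ss-proximal offset.
    """
    if bp_model is None:
        bp_model = default_bp_model()
    near, far = search_range
    if near < far:
        near, far = far, near
    wlen = len(bp_model)
    candidates: list[BranchPointCandidate] = []
    lo = max(far, -region.up_len + BP_BRANCH_INDEX)
    hi = min(near, -1 - (wlen - 1 - BP_BRANCH_INDEX))
    for off in range(hi, lo - 1, -1):
        if region.base_at(off) != "A":
            continue
        start = region.index_of(off) - BP_BRANCH_INDEX
        window = region.sequence[start: start + wlen]
        if "N" in window:
            continue
        candidates.append(BranchPointCandidate(
            bp_offset=off, score=score_site(window, bp_model), window=window))
    # stable sort: candidates are already 3'ss-proximal first, so ties keep
    # the proximal one on top
    candidates.sort(key=lambda c: -c.score)
    return candidates


def best_branch_point(region: ThreePrimeRegion,
                      bp_model: SiteModel | None = None,
                      search_range: tuple[int, int] = BP_SEARCH_RANGE,
                      ) -> BranchPointCandidate | None:
    cands = score_branch_points(region, bp_model, search_range)
    return cands[0] if cands else None


def ppt_for_branch_point(region: ThreePrimeRegion, bp: BranchPointCandidate,
                         min_length: int = PPT_MIN_LENGTH,
                         min_fraction: float = PPT_MIN_FRACTION,
                         ) -> PPTResult:
    """Best polypyrimidine tract between the branch point and offset -3.

    Exhaustively scores every contiguous window in ``(bp_offset, -3]`` with
    pyrimidine +1 / purine -2 (N scores 0), requiring length >= 5 and
    pyrimidine fraction >= 0.6.  The maximal-scoring window wins; ties go
    to the longer window, then the 3'ss-proximal one.
    """
    if bp.bp_offset >= -3:
        raise ValueError("branch point must lie upstream of offset -3")
    offsets = list(range(bp.bp_offset + 1, -2))      # candidates bp+1 .. -3
    best: tuple[float, int, int] | None = None       # (score, length, end)
    best_window: tuple[int, int, float] | None = None
    for si, start in enumerate(offsets):
        n_pyr = 0
        n_pur = 0
        for end in offsets[si:]:
            base = region.base_at(end)
            if base in PYRIMIDINES:
                n_pyr += 1
            elif base in PURINES:
                n_pur += 1
            length = end - start + 1
            if length < min_length:
                continue
            frac = n_pyr / length
            if frac < min_fraction:
                continue
            score = n_pyr * PPT_PYRIMIDINE_SCORE + n_pur * PPT_PURINE_SCORE
            key = (score, length, end)
            if best is None or key > best:
                best = key
                best_window = (start, end, frac)
    if best_window is None:
        return PPTResult(region.exon_id, bp.bp_offset, None, None, 0, 0.0)
    start, end, frac = best_window
    return PPTResult(
        exon_id=region.exon_id,
        bp_offset=bp.bp_offset,
        ppt_start_offset=start,
        ppt_end_offset=end,
        ppt_length=end - start + 1,
        pyrimidine_fraction=frac,
    )


def site_pair_preference(score_pairs: Sequence[tuple[float, float]],
                         ) -> tuple[int, int, int, float]:
    """Is the promoted 3'ss of a pair intrinsically stronger than its rival?

    Returns ``(n_stronger, n_ties, n_total, two_tail_p)`` where the p-value
    is an exact two-tailed binomial test of ``n_stronger`` out of the
    non-tied pairs against 0.5.  Ties count as not-stronger and are
    reported separately.
    """
    from .feature_stats import binomial_two_tail

    if not score_pairs:
        raise ValueError("need at least one score pair")
    n_stronger = sum(1 for a, b in score_pairs if a > b)
    n_ties = sum(1 for a, b in score_pairs if a == b)
    n_total = len(score_pairs)
    p = binomial_two_tail(n_stronger, n_total - n_ties, 0.5)
    return n_stronger, n_ties, n_total, p


# --- model serialization (plain-text matrices) ------------------------------

def save_site_model(model: SiteModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# site_type\t{model.site_type}\n")
        fh.write(f"# pseudocount\t{model.pseudocount}\n")
        fh.write("# background\t" + "\t".join(f"{x:.10g}" for x in model.background) + "\n")
        fh.write("pos\t" + "\t".join(BASES) + "\n")
        for i, row in enumerate(model.columns):
            fh.write(str(i) + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def load_site_model(path: str | Path) -> SiteModel:
    site_type = "3ss"
    pseudocount = 0.0
    background = np.full(4, 0.25)
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# site_type"):
                site_type = line.split("\t")[1]
            elif line.startswith("# pseudocount"):
                pseudocount = float(line.split("\t")[1])
            elif line.startswith("# background"):
                background = np.array([float(x) for x in line.split("\t")[1:]])
            elif line.startswith("pos\t") or not line:
                continue
            else:
                rows.append([float(x) for x in line.split("\t")[1:]])
    return SiteModel(site_type=site_type, columns=np.array(rows),
                     background=background, pseudocount=pseudocount)
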