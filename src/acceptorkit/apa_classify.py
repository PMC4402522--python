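"""Exon position classes and alternative polyadenylation (APA) categories.

Differentially used exons are classed as start / internal / terminal
within their transcript.  APA events are categorized by an explicit rule
cascade — tandem 3'UTR (two poly(A) sites in one terminal exon), intronic
APA (proximal site inside an annotated intron), and alternative-3'ss APA
(competing terminal exons sharing their 5' boundary region but using
distinct 3'ss) — with a proximal/distal shift call from which exon group
(up or down) sits nearest each site.  Events the rules underdetermine are
emitted with an ambiguity flag and excluded from tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .sequence_io import ExonRecord, GenomicInterval

APA_CATEGORIES = ("alt3ss_apa", "intronic_apa", "tandem_3utr")
SHIFTS = ("proximal", "distal")


@dataclass
class TranscriptModel:
    """Ordered exons of one transcript (5'->3' in transcript orientation)."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        strands = {e.strand for e in self.exons}
        contigs = {e.contig for e in self.exons}
        if len(strands) != 1 or len(contigs) != 1:
            raise ValueError("exons must share one contig and strand")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}")
        # store 5'->3' in transcript orientation
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def terminal_exon(self) -> GenomicInterval:
        return self.exons[-1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic (start, end) of each intron, half-open."""
        genomic = sorted(self.exons, key=lambda e: e.start)
        return [(a.end, b.start) for a, b in zip(genomic, genomic[1:])]

    def three_prime_ss(self, exon: GenomicInterval) -> int:
        """Genomic coordinate of the exon's 3' splice site (acceptor)."""
        return exon.start if exon.strand == "+" else exon.end


@dataclass
class APAEvent:
    gene_id: str
    category: str | None
    shift: str | None
    proximal_site: int
    distal_site: int
    supporting_exons: list[str] = field(default_factory=list)
    ambiguous: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.category is not None and self.category not in APA_CATEGORIES:
            raise ValueError(f"unknown APA category {self.category!r}")
        if self.shift is not None and self.shift not in SHIFTS:
            raise ValueError(f"unknown shift {self.shift!r}")


def classify_exon_position(exon: ExonRecord,
                           transcript: TranscriptModel) -> str:
    """start / internal / terminal position of an exon within a transcript.

    Matching is exact interval equality.  A single-exon transcript's only
    exon is classed terminal (declared rule).
    """
    iv = exon.interval
    matches = [i for i, e in enumerate(transcript.exons)
               if (e.start, e.end) == (iv.start, iv.end)
               and e.contig == iv.contig]
    if not matches:
        raise ValueError(
            f"exon {exon.exon_id} not found in transcript "
            f"{transcript.transcript_id}")
    idx = matches[0]
    n = len(transcript.exons)
    if n == 1 or idx == n - 1:
        return "terminal"
    if idx == 0:
        return "start"
    return "internal"


def _tx_position(transcript: TranscriptModel, genomic_pos: int) -> float:
    """Order a genomic point 5'->3' along the transcript's direction."""
    return genomic_pos if transcript.strand == "+" else -genomic_pos


def _inside(iv: GenomicInterval, pos: int) -> bool:
    return iv.start <= pos < iv.end


def classify_apa_event(gene_id: str,
                       transcripts: Sequence[TranscriptModel],
                       apa_sites: Sequence[int],
                       up_exons: Sequence[ExonRecord] = (),
                       down_exons: Sequence[ExonRecord] = (),
                       ) -> APAEvent:
    """Categorize one gene's pair of APA sites and call the usage shift.

    Rules, applied in order:

    1. both sites inside one annotated terminal exon -> ``tandem_3utr``;
    2. proximal site inside an annotated intron of some isoform, distal
       site in or downstream of a terminal exon -> ``intronic_apa``;
    3. two terminal exons of different isoforms share their 5' boundary
       region but use distinct 3'ss, one holding each site
       -> ``alt3ss_apa``;

    The shift is ``proximal`` when the differential exons nearest the
    proximal site are upregulated, ``distal`` when those nearest the
    distal site are; conflicting or absent evidence flags the event
    ambiguous.
    """
    if len(apa_sites) != 2:
        raise ValueError("an APA event needs exactly two sites")
    txs = [t for t in transcripts if t.gene_id == gene_id]
    if not txs:
        raise ValueError(f"no transcripts for gene {gene_id}")
    strand = txs[0].strand
    s1, s2 = apa_sites
    proximal, distal = sorted(apa_sites, key=lambda p: _tx_position(txs[0], p))

    category = None
    note = ""
    # rule 1: tandem 3'UTR.  Blocked when terminal exons with distinct
    # acceptors split the two sites (that geometry is alternative-3'ss APA
    # even if the longer terminal exon happens to span both sites).
    terminals = [(t, t.terminal_exon) for t in txs]
    acc_p = {t.three_prime_ss(e) for t, e in terminals if _inside(e, proximal)}
    acc_d = {t.three_prime_ss(e) for t, e in terminals if _inside(e, distal)}
    split_acceptors = bool((acc_p | acc_d) and acc_p != acc_d)
    if not split_acceptors:
        for tx in txs:
            term = tx.terminal_exon
            if _inside(term, proximal) and _inside(term, distal):
                category = "tandem_3utr"
                break
    # rule 2: intronic APA
    if category is None:
        for tx in txs:
            in_intron = any(a <= proximal < b for a, b in tx.introns())
            if not in_intron:
                continue
            term = tx.terminal_exon
            distal_ok = (_inside(term, distal) or
                         _tx_position(tx, distal) >=
                         _tx_position(tx, term.start if strand == "+"
                                      else term.end - 1))
            if distal_ok:
                category = "intronic_apa"
                break
    # rule 3: alternative-3'ss APA
    if category is None:
        terminals = [t.terminal_exon for t in txs]
        holders_p = [t for t in txs if _inside(t.terminal_exon, proximal)]
        holders_d = [t for t in txs if _inside(t.terminal_exon, distal)]
        for tp in holders_p:
            for td in holders_d:
                ep, ed = tp.terminal_exon, td.terminal_exon
                if (ep.start, ep.end) == (ed.start, ed.end):
                    continue
                acc_p = tp.three_prime_ss(ep)
                acc_d = td.three_prime_ss(ed)
                # share 5' boundary region: the exons overlap
                overlap = min(ep.end, ed.end) - max(ep.start, ed.start)
                if overlap > 0 and acc_p != acc_d:
                    category = "alt3ss_apa"
                    break
            if category:
                break
    if category is None:
        return APAEvent(gene_id, None, None, proximal, distal,
                        ambiguous=True, note="no category rule matched")

    shift, s_note, support = _call_shift(txs[0], proximal, distal,
                                         up_exons, down_exons)
    return APAEvent(gene_id, category, shift, proximal, distal,
                    supporting_exons=support,
                    ambiguous=shift is None, note=s_note)


def _call_shift(tx: TranscriptModel, proximal: int, distal: int,
                up_exons: Sequence[ExonRecord],
                down_exons: Sequence[ExonRecord],
                ) -> tuple[str | None, str, list[str]]:
    def nearest_site(exon: ExonRecord) -> str:
        mid = (exon.interval.start + exon.interval.end) / 2.0
        return ("proximal" if abs(mid - proximal) <= abs(mid - distal)
                else "distal")

    votes: dict[str, set[str]] = {"proximal": set(), "distal": set()}
    support: list[str] = []
    for exon in up_exons:
        votes[nearest_site(exon)].add("up")
        support.append(exon.exon_id)
    for exon in down_exons:
        votes[nearest_site(exon)].add("down")
        support.append(exon.exon_id)
    prox_up = "up" in votes["proximal"]
    dist_up = "up" in votes["distal"]
    prox_down = "down" in votes["proximal"]
    dist_down = "down" in votes["distal"]
    if prox_up and dist_up:
        return None, "up exons flank both sites", support
    if prox_up or dist_down:
        if dist_up or prox_down:
            return None, "conflicting shift evidence", support
        return "proximal", "", support
    if dist_up or prox_down:
        return "distal", "", support
    return None, "no differential exon near either site", support


def tally_shifts(events: Iterable[APAEvent],
                 ) -> dict[str, tuple[int, int]]:
    """Per-category (n_proximal, n_distal), excluding ambiguous events."""
    out = {cat: [0, 0] for cat in APA_CATEGORIES}
    for ev in events:
        if ev.ambiguous or ev.category is None or ev.shift is None:
            continue
        out[ev.category][0 if ev.shift == "proximal" else 1] += 1
    return {cat: (v[0], v[1]) for cat, v in out.items()}


def exon_class_table(exons: Sequence[ExonRecord],
                     transcripts: Mapping[str, TranscriptModel],
                     ) -> dict[str, dict[str, int]]:
    """3x2 counts of exon class (start/internal/terminal) by group (up/down)."""
    table = {cls: {"up": 0, "down": 0}
             for cls in ("start", "internal", "terminal")}
    for exon in exons:
        if exon.group not in ("up", "down"):
            continue
        tx = transcripts.get(exon.transcript_id)
        if tx is None:
            raise ValueError(f"unknown transcript {exon.transcript_id!r} "
                             f"for exon {exon.exon_id}")
        table[classify_exon_position(exon, tx)][exon.group] += 1
    return table


# --- annotation I/O ---------------------------------------------------------

def read_transcripts_gtf(path: str | Path) -> dict[str, TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    Parses the 9-column GTF dialect this package writes (and standard
    Ensembl-style attributes): only ``exon`` features are used, grouped by
    ``transcript_id`` with ``gene_id`` carried along.
    """
    by_tx: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            contig, _src, _feat, start, end, _score, strand, _frame, attrs = \
                fields[:9]
            attr = _parse_gtf_attrs(attrs)
            tx_id = attr.get("transcript_id", "")
            if not tx_id:
                raise ValueError(f"GTF exon without transcript_id: {line!r}")
            by_tx.setdefault(tx_id, []).append(
                GenomicInterval(contig, int(start) - 1, int(end), strand))
            genes[tx_id] = attr.get("gene_id", tx_id)
    return {tx_id: TranscriptModel(tx_id, genes[tx_id], exons)
            for tx_id, exons in by_tx.items()}


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def write_transcripts_gtf(transcripts: Iterable[TranscriptModel],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            for iv in sorted(tx.exons, key=lambda e: e.start):
                fh.write("\t".join([
                    iv.contig, "acceptorkit", "exon",
                    str(iv.start + 1), str(iv.end), ".", iv.strand, ".",
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";',
                ]) + "\n")


def read_apa_sites_bed(path: str | Path) -> dict[str, list[int]]:
    """Read APA point sites from BED-6; the name column carries the gene id."""
    sites: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError("APA BED must have 6 columns")
            _contig, start, _end, gene, _score, _strand = fields[:6]
            sites.setdefault(gene, []).append(int(start))
    return sites
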