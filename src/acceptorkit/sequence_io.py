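"""Reading standard formats and extracting 3'ss-anchored sequence windows.

Coordinate conventions used throughout the package:

* genomic intervals are 0-based, half-open (BED convention);
* within an extracted window, offsets are signed integers anchored at the
  3' splice site: ``-1`` and ``-2`` are the G and A of the 3'ss AG
  dinucleotide (the last two intron nucleotides) and ``+0`` is the first
  exon nucleotide.  There is no offset zero on the intron side.  Note that
  position labels of the form "+1 = first exon nucleotide" common in the
  splicing literature correspond to this package's ``+0``.

The internal analysis alphabet is RNA ``{A, C, G, U, N}``; extraction
transliterates T to U.  ``N`` is excluded from composition denominators and
never pairs in the structure module.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


class SequenceIOError(ValueError):
    """Raised for malformed or inconsistent sequence/annotation inputs."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExonRecord:
    """An exon with its group label and expression change.

    ``expression_change`` is a signed log2-fold usage change; positive means
    higher usage in the depleted condition (the "up" group direction).
    """

    exon_id: str
    interval: GenomicInterval
    transcript_id: str = ""
    group: str = "control"
    expression_change: float = 0.0

    GROUPS = ("up", "down", "control")

    def __post_init__(self) -> None:
        if self.group not in self.GROUPS:
            raise ValueError(f"group must be one of {self.GROUPS}, got {self.group!r}")
        if not math.isfinite(self.expression_change):
            raise ValueError("expression_change must be finite")


@dataclass(frozen=True)
class ThreePrimeRegion:
    """A sequence window anchored at one 3' splice site.

    ``sequence`` reads 5'->3' on the transcribed strand and has length
    ``up_len + down_len``; index ``up_len + offset`` holds the base at a
    given signed offset (valid for offsets ``-up_len .. down_len - 1``).
    """

    exon_id: str
    sequence: str
    up_len: int
    down_len: int
    canonical: bool = True
    truncated: bool = False
    group: str = "control"

    def __post_init__(self) -> None:
        if len(self.sequence) != self.up_len + self.down_len:
            raise ValueError("sequence length must equal up_len + down_len")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"sequence contains letters outside ACGUN: {sorted(bad)}")

    @property
    def offsets(self) -> range:
        return range(-self.up_len, self.down_len)

    def index_of(self, offset: int) -> int:
        if not (-self.up_len <= offset < self.down_len):
            raise IndexError(f"offset {offset} outside window "
                             f"[-{self.up_len}, {self.down_len})")
        return self.up_len + offset

    def base_at(self, offset: int) -> str:
        return self.sequence[self.index_of(offset)]

    def upstream(self) -> str:
        """Intron-side part of the window (offsets -up_len .. -1)."""
        return self.sequence[: self.up_len]


def _check_canonical(sequence: str, up_len: int) -> bool:
    if up_len < 2:
        return False
    return sequence[up_len - 2: up_len] == "AG"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: upper-case sequence}``.

    Ids are the first whitespace-delimited token of the header.  Sequences
    are upper-cased but otherwise kept as written (DNA stays DNA here).
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise SequenceIOError(f"duplicate FASTA id: {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise SequenceIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    """Write ``{id: sequence}`` to FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_regions_fasta(regions: Iterable[ThreePrimeRegion],
                        path: str | Path) -> None:
    write_fasta({r.exon_id: r.sequence for r in regions}, path)


def read_exon_table(bed_path: str | Path, group_path: str | Path,
                    ) -> tuple[list[ExonRecord], list[str]]:
    """Join a BED-6 exon file with a group table.

    The group table is tab-separated with a header and columns
    ``exon_id``, ``group`` (up/down/control, case-insensitive) and
    ``expression_change``.

    Returns ``(records, rejects)`` where rejects lists BED exon ids with no
    group row.  A group row whose exon_id is absent from the BED file is an
    error (the annotation is incomplete).
    """
    groups: dict[str, tuple[str, float]] = {}
    with open(group_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"exon_id", "group", "expression_change"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SequenceIOError(
                f"group table must have columns {sorted(required)}")
        for row in reader:
            label = row["group"].strip().lower()
            if label not in ExonRecord.GROUPS:
                raise SequenceIOError(
                    f"unknown group label {row['group']!r} for {row['exon_id']}")
            groups[row["exon_id"]] = (label, float(row["expression_change"]))

    records: list[ExonRecord] = []
    rejects: list[str] = []
    seen: set[str] = set()
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise SequenceIOError(f"{bed_path}:{ln}: need BED-6, "
                                      f"got {len(fields)} columns")
            contig, start, end, name, _score, strand = fields[:6]
            seen.add(name)
            if name not in groups:
                rejects.append(name)
                continue
            label, change = groups[name]
            records.append(ExonRecord(
                exon_id=name,
                interval=GenomicInterval(contig, int(start), int(end), strand),
                group=label,
                expression_change=change,
            ))
    missing = sorted(set(groups) - seen)
    if missing:
        raise SequenceIOError(
            "group table ids absent from BED file: " + ", ".join(missing))
    return records, rejects


def reverse_complement(seq: str) -> str:
    """DNA/RNA reverse complement (output in DNA letters; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def extract_three_prime_region(genome: Mapping[str, str], exon: ExonRecord,
                               up_len: int = 100, down_len: int = 50,
                               ) -> ThreePrimeRegion:
    """Extract the strand-corrected window around an exon's 3' splice site.

    For a plus-strand exon the 3'ss is the exon start; for minus strand it
    is the exon end and the window is reverse-complemented so that offsets
    read 5'->3' on the transcribed strand.  Windows running off a contig
    edge are truncated and flagged.  Output is RNA (T -> U).
    """
    iv = exon.interval
    if iv.contig not in genome:
        raise SequenceIOError(f"contig {iv.contig!r} not found in genome")
    contig_seq = genome[iv.contig]
    n = len(contig_seq)

    if iv.strand == "+":
        anchor = iv.start                     # first exon base
        up_start = anchor - up_len
        down_end = anchor + down_len
        truncated = up_start < 0 or down_end > n
        up_start = max(up_start, 0)
        down_end = min(down_end, n)
        window = contig_seq[up_start:down_end]
        real_up = anchor - up_start
        real_down = down_end - anchor
    else:
        anchor = iv.end                       # first exon base is end-1 (genomic)
        up_end = anchor + up_len              # intron lies at higher coordinates
        down_start = anchor - down_len
        truncated = down_start < 0 or up_end > n
        up_end = min(up_end, n)
        down_start = max(down_start, 0)
        window = reverse_complement(contig_seq[down_start:up_end])
        real_up = up_end - anchor
        real_down = anchor - down_start

    rna = window.upper().replace("T", "U")
    return ThreePrimeRegion(
        exon_id=exon.exon_id,
        sequence=rna,
        up_len=real_up,
        down_len=real_down,
        canonical=_check_canonical(rna, real_up),
        truncated=truncated,
        group=exon.group,
    )
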