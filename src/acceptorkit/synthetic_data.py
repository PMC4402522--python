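"""Synthetic cohorts of 3'ss-anchored regions with planted effects.

Regions are constructed outward from the 3' splice site, so every planted
quantity (AGEZ length, branch-point position, PPT composition, positional
base-frequency modifiers, upstream hairpins, AGEZ-correlated expression
changes) is guaranteed by construction rather than by filtering.  This
makes planted-equals-measured tests possible and keeps the generator the
single source of ground truth for the whole pipeline.

The default configuration encodes the study conditions the pipeline is
meant to detect: upregulated exons with long AG exclusion zones (mean 70
nt vs 40 nt for downregulated, 45 nt for controls), adenine depletion over
offsets -17..-38 in the up group, a planted Pearson correlation of 0.4
between AGEZ length and expression change in the up group only, and an
optional hairpin spanning offsets -25..-50 for structure cohorts.

One integer seed drives a root `numpy.random.Generator`; per-region
substreams are spawned by counter so output is byte-identical for a fixed
seed regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .apa_classify import TranscriptModel, write_transcripts_gtf
from .sequence_io import (ExonRecord, GenomicInterval, ThreePrimeRegion,
                          write_fasta)

GROUPS = ("up", "down", "control")


@dataclass(frozen=True)
class GroupSettings:
    """Planted parameters for one exon group."""

    agez_mean: float = 45.0
    agez_sd: float = 12.0
    ppt_pyrimidine_fraction: float = 0.85
    ppt_length_mean: float = 18.0
    ppt_length_sd: float = 4.0
    bp_offset_mean: float = -24.0
    bp_offset_sd: float = 4.0
    #: per-offset-zone base probability overrides, e.g.
    #: {(-38, -17): {"A": 0.08, "C": 0.32, "G": 0.20, "U": 0.40}}
    zone_composition: Mapping[tuple[int, int], Mapping[str, float]] = \
        field(default_factory=dict)
    structure_mode: str = "unstructured"     # or "hairpin_upstream"
    expression_corr: float = 0.0             # planted r(AGEZ, change)
    expression_mean: float = 0.0
    expression_sd: float = 1.0
    plant_bp: bool = True                    # plant the BP 7-mer motif
    exon_composition: Mapping[str, float] | None = None  # None: default


#: Background base probabilities for intronic filler outside planted
#: elements: mildly pyrimidine-skewed, intron-like, with enough purines
#: that AG dinucleotides occur freely outside the exclusion zone.
INTRON_BACKGROUND_COMPOSITION = {"A": 0.24, "C": 0.26, "G": 0.20, "U": 0.30}

#: Default exon-side composition (slightly GC-skewed).
EXON_COMPOSITION = {"A": 0.24, "C": 0.28, "G": 0.26, "U": 0.22}

BP_MOTIF = "UACUAAC"            # planted branch-point 7-mer, branch A at
                                # position 6 (1-based)
BP_BRANCH_INDEX = 5

HAIRPIN_SPAN = (-50, -25)       # offsets the planted stem-loop occupies
HAIRPIN_STEM = 10
HAIRPIN_LOOP = 6


def default_cohort_config(seed: int = 0, n_per_group: int = 100,
                          up_len: int = 100, down_len: int = 50,
                          ) -> "CohortConfig":
    """The study conditions: long-AGEZ up group, A-depletion -17..-38,
    planted r = 0.4 for the up group only."""
    a_depleted = {(-38, -17): {"A": 0.04, "C": 0.38, "G": 0.05, "U": 0.53}}
    return CohortConfig(
        seed=seed,
        n_per_group={g: n_per_group for g in GROUPS},
        up_len=up_len,
        down_len=down_len,
        groups={
            "up": GroupSettings(agez_mean=70.0, agez_sd=15.0,
                                ppt_length_mean=22.0, bp_offset_mean=-28.0,
                                zone_composition=a_depleted,
                                expression_corr=0.4,
                                expression_mean=1.5, expression_sd=0.6),
            "down": GroupSettings(agez_mean=40.0, agez_sd=12.0,
                                  ppt_length_mean=14.0,
                                  expression_mean=-1.5, expression_sd=0.6),
            "control": GroupSettings(agez_mean=45.0, agez_sd=12.0,
                                     ppt_length_mean=16.0,
                                     expression_mean=0.0, expression_sd=0.3),
        },
    )


def structure_cohort_config(seed: int = 0, n_per_group: int = 60,
                            ) -> "CohortConfig":
    """Structure-contrast conditions: hairpin-planted down group versus an
    unstructured up group, windows reaching offset -50."""
    # pairing-poor conditions: outside the two AG dinucleotides the windows
    # carry no purines at all, so the only pairing partners are those four
    # planted bases; BP motif planting is off (it would seed A-U pairs)
    pyr_only = {(-1000, 1000): {"A": 0.0, "C": 0.45, "G": 0.0, "U": 0.55}}
    common = dict(agez_mean=50.0, agez_sd=0.0, bp_offset_mean=-17.0,
                  bp_offset_sd=2.0, ppt_length_mean=10.0, ppt_length_sd=2.0,
                  ppt_pyrimidine_fraction=1.0, plant_bp=False,
                  zone_composition=pyr_only,
                  exon_composition={"A": 0.0, "C": 0.5, "G": 0.0, "U": 0.5})
    return CohortConfig(
        seed=seed,
        n_per_group={g: n_per_group for g in GROUPS},
        up_len=55,
        down_len=25,
        groups={
            "up": GroupSettings(structure_mode="unstructured",
                                expression_mean=1.5, expression_sd=0.6,
                                **common),
            "down": GroupSettings(structure_mode="hairpin_upstream",
                                  expression_mean=-1.5, expression_sd=0.6,
                                  **common),
            "control": GroupSettings(expression_mean=0.0,
                                     expression_sd=0.3, **common),
        },
    )


@dataclass(frozen=True)
class CohortConfig:
    seed: int = 0
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {g: 100 for g in GROUPS})
    up_len: int = 100
    down_len: int = 50
    groups: Mapping[str, GroupSettings] = field(
        default_factory=lambda: {g: GroupSettings() for g in GROUPS})
    pad: int = 20              # genomic padding around each planted window

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("n per group must be >= 1")
        for name, gs in self.groups.items():
            if gs.structure_mode not in ("unstructured", "hairpin_upstream"):
                raise ValueError(f"unknown structure mode for {name}")
            if gs.agez_mean > self.up_len - 2:
                raise ValueError(
                    f"planted AGEZ mean for {name} exceeds up_len - 2")


def _draw_base(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    bases = ("A", "C", "G", "U")
    p = np.array([probs.get(b, 0.0) for b in bases])
    p = p / p.sum()
    return bases[rng.choice(4, p=p)]


def _composition_for(settings: GroupSettings, offset: int,
                     ) -> Mapping[str, float]:
    for (lo, hi), probs in settings.zone_composition.items():
        if lo <= offset <= hi:
            return probs
    return INTRON_BACKGROUND_COMPOSITION


_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def generate_region(config: CohortConfig, group: str, index: int,
                    ) -> tuple[ThreePrimeRegion, float, dict]:
    """Build one region; returns (region, expression_change, truth).

    ``truth`` records the planted AGEZ length, BP offset and PPT bounds so
    tests can compare measured against planted values.
    """
    settings = config.groups[group]
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, GROUPS.index(group), index]))
    up_len, down_len = config.up_len, config.down_len

    agez_z = float(rng.standard_normal())
    agez = int(round(settings.agez_mean + settings.agez_sd * agez_z))
    agez = max(10, min(up_len - 2, agez))

    # upstream window indexed by offset -up_len .. -1; 'planted' offsets are
    # protected from the AG-repair pass
    up: dict[int, str] = {-1: "G", -2: "A"}
    planted: set[int] = {-1, -2}

    # closing AG bounding the exclusion zone: G at -(agez+3).  If the A
    # would fall outside the window, the region is censored (no upstream AG)
    g_off = -(agez + 3)
    censored = g_off - 1 < -up_len
    if not censored:
        up[g_off] = "G"
        up[g_off - 1] = "A"
        planted.update((g_off, g_off - 1))

    # branch-point 7-mer inside the AG-free zone, branch A at bp_off
    bp_lo = -(agez + 2) + BP_BRANCH_INDEX       # keep the 7-mer inside zone
    bp_hi = -9
    bp_off = int(round(rng.normal(settings.bp_offset_mean,
                                  settings.bp_offset_sd)))
    bp_off = max(min(bp_off, bp_hi), min(bp_hi, bp_lo))
    if settings.plant_bp:
        for k, base in enumerate(BP_MOTIF):
            off = bp_off - BP_BRANCH_INDEX + k
            if max(-up_len, g_off + 1) <= off <= -3:
                up[off] = base
                planted.add(off)

    # PPT between the BP and -3 (pyrimidines C/U; purines are A only, so
    # the PPT can never seed an AG)
    ppt_len = int(round(rng.normal(settings.ppt_length_mean,
                                   settings.ppt_length_sd)))
    ppt_len = max(5, min(ppt_len, -bp_off - 4))
    ppt_start = -2 - ppt_len
    for off in range(ppt_start, -2):
        if off in up:
            continue
        if rng.random() < settings.ppt_pyrimidine_fraction:
            up[off] = "C" if rng.random() < 0.4 else "U"
        else:
            up[off] = "A"

    # fill the rest: zone-aware composition, AG-avoiding inside the zone
    for off in range(-3, -up_len - 1, -1):
        if off in up:
            continue
        probs = dict(_composition_for(settings, off))
        if off >= g_off and up.get(off + 1) == "G":
            probs["A"] = 0.0    # never create AG inside the exclusion zone
        up[off] = _draw_base(rng, probs)

    # hairpin planting overwrites its span (structure cohorts): stem arms
    # over {G,U} / {A,C} and a {C,U} loop cannot form AG internally
    if settings.structure_mode == "hairpin_upstream":
        lo, hi = HAIRPIN_SPAN
        if lo >= -up_len:
            left = [("G" if rng.random() < 0.6 else "U")
                    for _ in range(HAIRPIN_STEM)]
            loop = [("C" if rng.random() < 0.5 else "U")
                    for _ in range(HAIRPIN_LOOP)]
            right = [_RC[b] for b in reversed(left)]
            for k, base in enumerate(left + loop + right):
                up[lo + k] = base
                planted.add(lo + k)

    # repair stray AGs inside the exclusion zone that planting boundaries
    # may have formed; always edit the non-planted member of the pair
    for off in range(max(g_off + 1, -up_len), -3):
        if up[off] == "A" and up[off + 1] == "G":
            target = off + 1 if off + 1 not in planted else off
            if target in planted:
                continue        # both planted: cannot occur by construction
            up[target] = "C" if rng.random() < 0.5 else "U"

    # exon side
    exon_comp = settings.exon_composition or EXON_COMPOSITION
    down = [_draw_base(rng, exon_comp) for _ in range(down_len)]
    seq = "".join(up[o] for o in range(-up_len, 0)) + "".join(down)

    noise = float(rng.standard_normal())
    r = settings.expression_corr
    change = settings.expression_mean + settings.expression_sd * (
        r * agez_z + math.sqrt(max(0.0, 1.0 - r * r)) * noise)

    region = ThreePrimeRegion(
        exon_id=f"{group}_{index:04d}", sequence=seq,
        up_len=up_len, down_len=down_len, group=group)
    truth = {"agez": agez if not censored else up_len - 2,
             "censored": censored, "bp_offset": bp_off,
             "ppt_start": ppt_start, "ppt_len": ppt_len}
    return region, change, truth


@dataclass
class Cohort:
    config: CohortConfig
    regions: list[ThreePrimeRegion]
    exons: list[ExonRecord]
    genome: dict[str, str]
    truth: dict[str, dict]

    def regions_by_group(self, group: str) -> list[ThreePrimeRegion]:
        return [r for r in self.regions if r.group == group]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate all groups and embed each window in its own small contig.

    Half of the regions are placed on the minus strand so strand handling
    is exercised end to end; re-extracting each exon's window from the
    written genome reproduces the region sequence exactly.
    """
    regions: list[ThreePrimeRegion] = []
    exons: list[ExonRecord] = []
    genome: dict[str, str] = {}
    truth: dict[str, dict] = {}
    pad = config.pad
    for group in GROUPS:
        for i in range(config.n_per_group.get(group, 0)):
            region, change, info = generate_region(config, group, i)
            rng = np.random.default_rng(np.random.SeedSequence(
                [config.seed, GROUPS.index(group), i, 7]))
            dna = region.sequence.replace("U", "T")
            padding = "".join(
                "ACGT"[k] for k in rng.integers(0, 4, size=2 * pad))
            left_pad, right_pad = padding[:pad], padding[pad:]
            minus = bool(rng.integers(0, 2))
            contig = f"chr_{region.exon_id}"
            if not minus:
                contig_seq = left_pad + dna + right_pad
                start = pad + region.up_len              # first exon base
                iv = GenomicInterval(contig, start,
                                     start + region.down_len, "+")
            else:
                from .sequence_io import reverse_complement
                contig_seq = left_pad + reverse_complement(dna) + right_pad
                end = pad + region.down_len              # 3'ss on minus strand
                iv = GenomicInterval(contig, pad, end, "-")
            genome[contig] = contig_seq
            exon = ExonRecord(exon_id=region.exon_id, interval=iv,
                              transcript_id=f"tx_{region.exon_id}",
                              group=group, expression_change=change)
            regions.append(region)
            exons.append(exon)
            truth[region.exon_id] = info
    return Cohort(config=config, regions=regions, exons=exons,
                  genome=genome, truth=truth)


def write_cohort(cohort: Cohort, outdir: str | Path,
                 ) -> dict[str, Path]:
    """Write genome FASTA, BED-6 exons and the group table.

    The dialects match exactly what `sequence_io` reads back.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "bed": outdir / "exons.bed",
        "groups": outdir / "groups.tsv",
    }
    write_fasta(cohort.genome, paths["genome"])
    with open(paths["bed"], "w") as fh:
        for exon in cohort.exons:
            iv = exon.interval
            fh.write("\t".join([iv.contig, str(iv.start), str(iv.end),
                                exon.exon_id, "0", iv.strand]) + "\n")
    with open(paths["groups"], "w") as fh:
        fh.write("exon_id\tgroup\texpression_change\n")
        for exon in cohort.exons:
            fh.write(f"{exon.exon_id}\t{exon.group}\t"
                     f"{exon.expression_change:.6f}\n")
    return paths


# --- toy annotation for APA classification ---------------------------------

def generate_toy_annotation() -> tuple[list[TranscriptModel],
                                       dict[str, list[int]],
                                       dict[str, dict],
                                       list[ExonRecord]]:
    """A fixed 14-gene annotation with known APA categories.

    Twelve unambiguous genes cover all three categories, both strands and
    both shift directions; two genes are deliberately ambiguous (one with
    conflicting group evidence, one whose sites match no category rule).
    Returns (transcripts, apa_sites, expected, differential_exons) where
    ``expected`` maps gene -> {"category": ..., "shift": ...} (None values
    for the ambiguous pair).
    """
    transcripts: list[TranscriptModel] = []
    apa_sites: dict[str, list[int]] = {}
    expected: dict[str, dict] = {}
    diff_exons: list[ExonRecord] = []

    def add_exon(gene, tx, iv, group, change):
        diff_exons.append(ExonRecord(
            exon_id=f"{gene}_{len(diff_exons)}", interval=iv,
            transcript_id=tx, group=group, expression_change=change))

    def tandem(gene, strand, shift, base):
        # one transcript; terminal exon [base+300, base+900) holds both sites
        if strand == "+":
            exons = [GenomicInterval("c" + gene, base, base + 100, "+"),
                     GenomicInterval("c" + gene, base + 300, base + 900, "+")]
            prox, dist = base + 400, base + 800
            seg_prox = GenomicInterval("c" + gene, base + 300, base + 450, "+")
            seg_dist = GenomicInterval("c" + gene, base + 700, base + 880, "+")
        else:
            exons = [GenomicInterval("c" + gene, base + 800, base + 900, "-"),
                     GenomicInterval("c" + gene, base, base + 600, "-")]
            prox, dist = base + 500, base + 100     # 5'->3' runs rightward->left
            seg_prox = GenomicInterval("c" + gene, base + 450, base + 600, "-")
            seg_dist = GenomicInterval("c" + gene, base, base + 150, "-")
        transcripts.append(TranscriptModel(f"{gene}_t1", gene, exons))
        apa_sites[gene] = [prox, dist]
        if shift == "proximal":
            add_exon(gene, f"{gene}_seg", seg_prox, "up", 1.0)
            add_exon(gene, f"{gene}_seg", seg_dist, "down", -1.0)
        else:
            add_exon(gene, f"{gene}_seg", seg_prox, "down", -1.0)
            add_exon(gene, f"{gene}_seg", seg_dist, "up", 1.0)
        expected[gene] = {"category": "tandem_3utr", "shift": shift}

    def intronic(gene, strand, shift, base):
        # isoform 1: 3 exons; isoform 2 ends inside intron 2 (proximal site)
        if strand == "+":
            e1 = GenomicInterval("c" + gene, base, base + 100, "+")
            e2 = GenomicInterval("c" + gene, base + 200, base + 300, "+")
            e3 = GenomicInterval("c" + gene, base + 600, base + 800, "+")
            ei = GenomicInterval("c" + gene, base + 350, base + 500, "+")
            prox, dist = base + 450, base + 750
        else:
            e1 = GenomicInterval("c" + gene, base + 700, base + 800, "-")
            e2 = GenomicInterval("c" + gene, base + 500, base + 600, "-")
            e3 = GenomicInterval("c" + gene, base, base + 200, "-")
            ei = GenomicInterval("c" + gene, base + 300, base + 450, "-")
            prox, dist = base + 350, base + 50
        transcripts.append(TranscriptModel(f"{gene}_t1", gene, [e1, e2, e3]))
        transcripts.append(TranscriptModel(f"{gene}_t2", gene, [e1, e2, ei]))
        apa_sites[gene] = [prox, dist]
        if shift == "proximal":
            add_exon(gene, f"{gene}_t2", ei, "up", 1.0)
            add_exon(gene, f"{gene}_t1", e3, "down", -1.0)
        else:
            add_exon(gene, f"{gene}_t2", ei, "down", -1.0)
            add_exon(gene, f"{gene}_t1", e3, "up", 1.0)
        expected[gene] = {"category": "intronic_apa", "shift": shift}

    def alt3ss(gene, strand, shift, base):
        # two isoforms whose terminal exons overlap but use distinct 3'ss;
        # the proximal site sits in the shared region, the distal one in
        # the longer exon's private 3' extension
        if strand == "+":
            e1 = GenomicInterval("c" + gene, base, base + 100, "+")
            ta = GenomicInterval("c" + gene, base + 300, base + 500, "+")
            tb = GenomicInterval("c" + gene, base + 360, base + 700, "+")
            prox, dist = base + 430, base + 650
            seg_prox, seg_dist = ta, \
                GenomicInterval("c" + gene, base + 550, base + 700, "+")
        else:
            e1 = GenomicInterval("c" + gene, base + 700, base + 800, "-")
            ta = GenomicInterval("c" + gene, base + 200, base + 500, "-")
            tb = GenomicInterval("c" + gene, base, base + 440, "-")
            prox, dist = base + 300, base + 100
            seg_prox, seg_dist = ta, \
                GenomicInterval("c" + gene, base, base + 160, "-")
        transcripts.append(TranscriptModel(f"{gene}_t1", gene, [e1, ta]))
        transcripts.append(TranscriptModel(f"{gene}_t2", gene, [e1, tb]))
        apa_sites[gene] = [prox, dist]
        if shift == "proximal":
            add_exon(gene, f"{gene}_seg", seg_prox, "up", 1.0)
        else:
            add_exon(gene, f"{gene}_seg", seg_dist, "up", 1.0)
        expected[gene] = {"category": "alt3ss_apa", "shift": shift}

    base = 1000
    i = 0
    for maker in (tandem, intronic, alt3ss):
        for strand in ("+", "-"):
            for shift in ("proximal", "distal"):
                gene = f"g{i:02d}"
                maker(gene, strand, shift, base)
                base += 2000
                i += 1

    # ambiguous 1: tandem layout but up exons flank BOTH sites
    gene = "amb_conflict"
    exons = [GenomicInterval("c" + gene, 100, 200, "+"),
             GenomicInterval("c" + gene, 400, 1000, "+")]
    transcripts.append(TranscriptModel(f"{gene}_t1", gene, exons))
    apa_sites[gene] = [500, 900]
    add_exon(gene, f"{gene}_seg", GenomicInterval("c" + gene, 400, 550, "+"),
             "up", 1.0)
    add_exon(gene, f"{gene}_seg", GenomicInterval("c" + gene, 800, 980, "+"),
             "up", 0.8)
    expected[gene] = {"category": "tandem_3utr", "shift": None}

    # ambiguous 2: sites in the first exon / first intron, matching no rule
    gene = "amb_norule"
    exons = [GenomicInterval("c" + gene, 100, 300, "+"),
             GenomicInterval("c" + gene, 500, 700, "+"),
             GenomicInterval("c" + gene, 900, 1200, "+")]
    transcripts.append(TranscriptModel(f"{gene}_t1", gene, exons))
    apa_sites[gene] = [150, 550]
    expected[gene] = {"category": None, "shift": None}

    return transcripts, apa_sites, expected, diff_exons


def generate_class_cohort(n_up: int = 60, n_down: int = 60, seed: int = 0,
                          up_probs: tuple[float, float, float] = (0.1, 0.3, 0.6),
                          down_probs: tuple[float, float, float] = (0.4, 0.4, 0.2),
                          ) -> tuple[dict[str, TranscriptModel],
                                     list[ExonRecord]]:
    """Transcripts plus differential exons with a planted class imbalance.

    Each record gets its own three-exon transcript and its exon is drawn
    from (start, internal, terminal) with group-specific probabilities
    (defaults bias upregulated exons toward terminal positions), feeding
    the 3x2 exon-class contingency test.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    transcripts: dict[str, TranscriptModel] = {}
    exons: list[ExonRecord] = []
    classes = ("start", "internal", "terminal")
    for group, n, probs in (("up", n_up, up_probs),
                            ("down", n_down, down_probs)):
        for i in range(n):
            tx_id = f"cls_{group}_{i:03d}"
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            base = 1000 + 10 * i
            ivs = [GenomicInterval("chr_cls", base, base + 100, strand),
                   GenomicInterval("chr_cls", base + 200, base + 300, strand),
                   GenomicInterval("chr_cls", base + 400, base + 500, strand)]
            tx = TranscriptModel(tx_id, tx_id, ivs)
            transcripts[tx_id] = tx
            cls = classes[rng.choice(3, p=np.asarray(probs))]
            idx = {"start": 0, "internal": 1, "terminal": 2}[cls]
            exon_iv = tx.exons[idx]       # transcript orientation
            exons.append(ExonRecord(
                exon_id=f"{tx_id}_e", interval=exon_iv, transcript_id=tx_id,
                group=group,
                expression_change=1.0 if group == "up" else -1.0))
    return transcripts, exons
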