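"""End-to-end runs: extraction -> features -> statistics -> report tables.

Each ``run_*`` function takes a `RunConfig`, executes one analysis stage
and writes tab-separated tables with stable column order plus a manifest
echoing every configuration constant, so two runs with the same manifest
are byte-identical.
"""

from __future__ import annotations

import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .apa_classify import (TranscriptModel, classify_apa_event,
                           exon_class_table, read_apa_sites_bed,
                           read_transcripts_gtf, tally_shifts,
                           write_transcripts_gtf)
from .feature_stats import (GroupComparison, bh_adjust,
                            chi_square_contingency, compare_feature,
                            pearson_correlation)
from .sequence_io import (ExonRecord, ThreePrimeRegion,
                          extract_three_prime_region, read_exon_table,
                          read_fasta)
from .splice_architecture import (PPT_MIN_FRACTION, PPT_MIN_LENGTH,
                                  best_branch_point, default_bp_model,
                                  find_agez, ppt_for_branch_point,
                                  score_site, train_site_model)
from .structure_profile import EnergyModel, delta_pu, group_pu_profile
from .synthetic_data import (Cohort, CohortConfig, default_cohort_config,
                             generate_class_cohort, generate_cohort,
                             generate_toy_annotation,
                             structure_cohort_config, write_cohort)

THREE_SS_WINDOW = (-20, 2)     # 23-mer scored as intrinsic 3'ss strength


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage it occurred in."""


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    synthetic: str | None = "default"   # "default", "structure" or None
    n_per_group: int = 100
    genome_path: Path | None = None
    bed_path: Path | None = None
    groups_path: Path | None = None
    gtf_path: Path | None = None
    apa_bed_path: Path | None = None
    up_len: int = 100
    down_len: int = 50
    flank: int = 30
    p_star: float = 0.05
    energy: EnergyModel = field(default_factory=EnergyModel)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        real = self.genome_path is not None
        if real == (self.synthetic is not None):
            raise ValueError("exactly one of real inputs or a synthetic "
                             "cohort must be configured")


def load_run_config(path: str | Path, outdir: str | Path,
                    **overrides) -> RunConfig:
    """Read a flat key-value (YAML) config file into a RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    energy_kwargs = {}
    for key in ("kT", "min_hairpin"):
        if key in raw:
            energy_kwargs[key] = raw.pop(key)
    pair_energy = dict(EnergyModel().pair_energy)
    for key, pairs in (("e_gc", (("G", "C"), ("C", "G"))),
                       ("e_au", (("A", "U"), ("U", "A"))),
                       ("e_gu", (("G", "U"), ("U", "G")))):
        if key in raw:
            val = float(raw.pop(key))
            for pair in pairs:
                pair_energy[pair] = val
    for key in ("genome_path", "bed_path", "groups_path", "gtf_path",
                "apa_bed_path"):
        if key in raw and raw[key] is not None:
            raw[key] = Path(raw[key])
    raw.update(overrides)
    return RunConfig(outdir=Path(outdir),
                     energy=EnergyModel(pair_energy=pair_energy,
                                        **energy_kwargs),
                     **raw)


def _materialize(config: RunConfig) -> Cohort:
    """Build the cohort: generate synthetically or load real inputs."""
    if config.synthetic is not None:
        maker = {"default": default_cohort_config,
                 "structure": structure_cohort_config}.get(config.synthetic)
        if maker is None:
            raise StageError(f"unknown synthetic cohort {config.synthetic!r}")
        if config.synthetic == "default":
            cc = maker(seed=config.seed, n_per_group=config.n_per_group,
                       up_len=config.up_len, down_len=config.down_len)
        else:
            cc = maker(seed=config.seed, n_per_group=config.n_per_group)
        return generate_cohort(cc)
    genome = read_fasta(config.genome_path)
    exon_records, rejects = read_exon_table(config.bed_path,
                                            config.groups_path)
    regions = []
    for exon in exon_records:
        region = extract_three_prime_region(
            genome, exon, up_len=config.up_len, down_len=config.down_len)
        regions.append(region)
    return Cohort(config=None, regions=regions, exons=exon_records,
                  genome=genome, truth={})


def _write_table(path: Path, header: Sequence[str],
                 rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    if v is None:
        return "NA"
    return str(v)


def write_manifest(config: RunConfig, stage: str) -> None:
    config.outdir.mkdir(parents=True, exist_ok=True)
    lines = {
        "acceptorkit_version": __version__,
        "stage": stage,
        "seed": config.seed,
        "synthetic": config.synthetic,
        "up_len": config.up_len,
        "down_len": config.down_len,
        "flank": config.flank,
        "p_star": config.p_star,
        "ppt_min_length": PPT_MIN_LENGTH,
        "ppt_min_fraction": PPT_MIN_FRACTION,
        "energy_kT": config.energy.kT,
        "energy_min_hairpin": config.energy.min_hairpin,
        "energy_pairs": {"".join(k): v
                         for k, v in sorted(config.energy.pair_energy.items())},
    }
    with open(config.outdir / "manifest.txt", "w") as fh:
        yaml.safe_dump(lines, fh, sort_keys=True)


def run_architecture(config: RunConfig) -> dict:
    """AGEZ / BP / PPT / 3'ss strength per exon, plus group statistics."""
    try:
        cohort = _materialize(config)
    except Exception as exc:
        raise StageError(f"input stage failed: {exc}") from exc
    config.outdir.mkdir(parents=True, exist_ok=True)

    bp_model = default_bp_model()
    # intrinsic 3'ss strength: frequency-matrix model trained on the
    # control group's own windows (empirical background)
    lo, hi = THREE_SS_WINDOW
    controls = [r for r in cohort.regions if r.group == "control"]
    pool = controls or cohort.regions
    kmers = [r.sequence[r.index_of(lo): r.index_of(hi) + 1]
             for r in pool
             if -r.up_len <= lo and hi < r.down_len
             and "N" not in r.sequence[r.index_of(lo): r.index_of(hi) + 1]]
    ss3_model = train_site_model(kmers, "3ss", pseudocount=0.5,
                                 background="empirical") if kmers else None

    changes = {e.exon_id: e.expression_change for e in cohort.exons}
    rows = []
    features: dict[str, dict] = {}
    for region in cohort.regions:
        try:
            agez = find_agez(region)
            bp = best_branch_point(region, bp_model)
            ppt = ppt_for_branch_point(region, bp) if bp else None
            score3 = None
            if ss3_model is not None and -region.up_len <= lo \
                    and hi < region.down_len:
                kmer = region.sequence[region.index_of(lo):
                                       region.index_of(hi) + 1]
                if "N" not in kmer:
                    score3 = score_site(kmer, ss3_model)
        except Exception as exc:
            raise StageError(
                f"architecture stage failed on {region.exon_id}: {exc}"
            ) from exc
        feats = {
            "group": region.group,
            "expression_change": changes.get(region.exon_id, 0.0),
            "agez_length": agez.agez_length,
            "censored": int(agez.censored),
            "bp_offset": bp.bp_offset if bp else None,
            "bp_score": bp.score if bp else None,
            "ppt_length": ppt.ppt_length if ppt else 0,
            "pyrimidine_fraction": ppt.pyrimidine_fraction if ppt else 0.0,
            "site_score_3ss": score3,
        }
        features[region.exon_id] = feats
        rows.append([region.exon_id] + list(feats.values()))
    _write_table(config.outdir / "features.tsv",
                 ["exon_id", "group", "expression_change", "agez_length",
                  "censored", "bp_offset", "bp_score", "ppt_length",
                  "pyrimidine_fraction", "site_score_3ss"],
                 rows)

    comparisons: list[tuple[str, GroupComparison]] = []
    by_group = {g: [f for f in features.values() if f["group"] == g]
                for g in ("up", "down", "control")}
    for feat in ("agez_length", "ppt_length"):
        for ga, gb in (("up", "down"), ("up", "control"),
                       ("down", "control")):
            a = [f[feat] for f in by_group[ga]]
            b = [f[feat] for f in by_group[gb]]
            if len(a) >= 2 and len(b) >= 2:
                comparisons.append(
                    (f"{feat}:{ga}_vs_{gb}", compare_feature(a, b, "t")))
        for g in ("up", "down"):
            vals = [(f[feat], f["expression_change"]) for f in by_group[g]]
            if len(vals) >= 3 and len({v[0] for v in vals}) > 1:
                x, y = zip(*vals)
                comparisons.append(
                    (f"{feat}_vs_change:{g}", pearson_correlation(x, y)))
    _write_comparisons(config.outdir / "comparisons.tsv", comparisons)
    write_manifest(config, "architecture")
    return {"features": features,
            "comparisons": {cid: c for cid, c in comparisons}}


def _write_comparisons(path: Path,
                       comparisons: Sequence[tuple[str, GroupComparison]],
                       ) -> None:
    qvals = bh_adjust([c.p for _, c in comparisons]) if comparisons else []
    rows = [[cid, c.test, c.statistic, c.p, q, c.n_a, c.n_b, c.effect]
            for (cid, c), q in zip(comparisons, qvals)]
    _write_table(path, ["contrast", "test", "statistic", "p", "q",
                        "n_a", "n_b", "effect"], rows)


def run_structure(config: RunConfig) -> dict:
    """Group PU profiles and the positional delta-PU table."""
    try:
        cohort = _materialize(config)
    except Exception as exc:
        raise StageError(f"input stage failed: {exc}") from exc
    config.outdir.mkdir(parents=True, exist_ok=True)
    exons = {e.exon_id: e for e in cohort.exons}
    up = cohort.regions_by_group("up")
    down = cohort.regions_by_group("down")
    if not up or not down:
        raise StageError("structure stage needs up and down regions")
    try:
        prof_up = group_pu_profile(up, model=config.energy,
                                   flank=config.flank, genome=cohort.genome,
                                   exons=exons, group="up")
        prof_down = group_pu_profile(down, model=config.energy,
                                     flank=config.flank,
                                     genome=cohort.genome, exons=exons,
                                     group="down")
        result = delta_pu(up, down, model=config.energy, flank=config.flank,
                          genome=cohort.genome, exons=exons,
                          alpha=config.p_star)
    except Exception as exc:
        raise StageError(f"structure stage failed: {exc}") from exc

    rows = []
    for off in sorted(set(prof_up.offsets) | set(prof_down.offsets)):
        rows.append([off,
                     prof_up.mean_pu.get(off), prof_up.n.get(off, 0),
                     prof_down.mean_pu.get(off), prof_down.n.get(off, 0)])
    _write_table(config.outdir / "pu_profile.tsv",
                 ["offset", "mean_up", "n_up", "mean_down", "n_down"], rows)

    rows = []
    for off in result.offsets:
        rows.append([off, result.delta[off],
                     result.p.get(off), result.q.get(off),
                     "*" if result.star.get(off) else "",
                     result.n_up[off], result.n_down[off]])
    _write_table(config.outdir / "delta_pu.tsv",
                 ["offset", "delta", "p", "q", "star", "n_up", "n_down"],
                 rows)
    write_manifest(config, "structure")
    return {"profile_up": prof_up, "profile_down": prof_down,
            "delta": result}


def run_apa(config: RunConfig) -> dict:
    """APA event classification, shift tallies and the exon-class test."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    try:
        if config.synthetic is not None:
            transcripts, apa_sites, _expected, diff_exons = \
                generate_toy_annotation()
        else:
            tx_map = read_transcripts_gtf(config.gtf_path)
            transcripts = list(tx_map.values())
            apa_sites = (read_apa_sites_bed(config.apa_bed_path)
                         if config.apa_bed_path else {})
            diff_exons, _rej = read_exon_table(config.bed_path,
                                               config.groups_path)
    except Exception as exc:
        raise StageError(f"apa input stage failed: {exc}") from exc

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    events = []
    rejects = []
    for gene, sites in sorted(apa_sites.items()):
        if gene not in by_gene:
            rejects.append(gene)
            continue
        ups = [e for e in diff_exons if e.group == "up"
               and e.interval.contig == by_gene[gene][0].contig]
        downs = [e for e in diff_exons if e.group == "down"
                 and e.interval.contig == by_gene[gene][0].contig]
        try:
            events.append(classify_apa_event(gene, by_gene[gene], sites,
                                             ups, downs))
        except Exception as exc:
            raise StageError(f"apa stage failed on {gene}: {exc}") from exc
    tallies = tally_shifts(events)

    rows = [[ev.gene_id, ev.category, ev.shift, ev.proximal_site,
             ev.distal_site, int(ev.ambiguous), ev.note]
            for ev in events]
    _write_table(config.outdir / "apa_events.tsv",
                 ["gene", "category", "shift", "proximal", "distal",
                  "ambiguous", "note"], rows)
    rows = [[cat, n_prox, n_dist] for cat, (n_prox, n_dist)
            in sorted(tallies.items())]
    _write_table(config.outdir / "apa_tallies.tsv",
                 ["category", "n_proximal", "n_distal"], rows)

    comparisons = []
    if config.synthetic is not None:
        tx_by_id, class_exons = generate_class_cohort(seed=config.seed)
        classable = class_exons
    else:
        tx_by_id = {tx.transcript_id: tx for tx in transcripts}
        classable = [
            e for e in diff_exons if e.transcript_id in tx_by_id
            and any((x.start, x.end) == (e.interval.start, e.interval.end)
                    for x in tx_by_id[e.transcript_id].exons)]
    if classable:
        table = exon_class_table(classable, tx_by_id)
        counts = [[table[cls]["up"], table[cls]["down"]]
                  for cls in ("start", "internal", "terminal")]
        if all(sum(row) > 0 for row in counts) and \
                all(sum(col) > 0 for col in zip(*counts)):
            comparisons.append(("exon_class_3x2",
                                chi_square_contingency(counts)))
        _write_table(config.outdir / "exon_classes.tsv",
                     ["class", "n_up", "n_down"],
                     [[cls, table[cls]["up"], table[cls]["down"]]
                      for cls in ("start", "internal", "terminal")])
    _write_comparisons(config.outdir / "apa_comparisons.tsv", comparisons)
    write_manifest(config, "apa")
    return {"events": events, "tallies": tallies, "rejects": rejects,
            "comparisons": dict(comparisons)}


def run_generate(config: RunConfig) -> dict:
    """Write the synthetic cohort (FASTA / BED / group table / toy GTF)."""
    if config.synthetic is None:
        raise StageError("generate requires a synthetic configuration")
    cohort = _materialize(config)
    paths = write_cohort(cohort, config.outdir)
    transcripts, apa_sites, _expected, _diff = generate_toy_annotation()
    gtf = config.outdir / "toy_annotation.gtf"
    write_transcripts_gtf(transcripts, gtf)
    apa_bed = config.outdir / "toy_apa_sites.bed"
    with open(apa_bed, "w") as fh:
        for gene, sites in sorted(apa_sites.items()):
            for pos in sites:
                strand = transcripts[0].strand
                fh.write("\t".join(["c" + gene, str(pos), str(pos + 1),
                                    gene, "0", strand]) + "\n")
    paths["gtf"] = gtf
    paths["apa_bed"] = apa_bed
    write_manifest(config, "generate")
    return {"paths": paths, "cohort": cohort}


def run_all(config: RunConfig) -> dict:
    out = {}
    out["architecture"] = run_architecture(config)
    out["structure"] = run_structure(config)
    out["apa"] = run_apa(config)
    return out
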