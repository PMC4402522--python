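# acceptorkit

Tools for characterizing the architecture of 3′ splice sites (acceptor
sites) whose usage changes between two cellular conditions — the setting
that arises downstream of differential exon-usage analysis, for example
after depleting a splicing factor such as U2AF35 and calling exons
upregulated or downregulated in the depleted cells.

Given a genome FASTA, BED exon intervals and a table assigning exons to
{up, down, control} groups with an expression-change value, the package
extracts strand-corrected sequence windows anchored at each 3′ss and
measures, per exon:

- **AGEZ** — the AG exclusion zone, the stretch upstream of the 3′ss AG
  devoid of other AG dinucleotides.  With the nearest upstream AG's G at
  offset *g* (offsets: −1/−2 are the G/A of the 3′ss AG, +0 the first
  exon base), `AGEZ = |g| − 3`.
- **Branch point** — the best-scoring adenosine in a configurable search
  range, scored with a log-odds weight matrix over a 7-mer window
  (branch A at position 6, yUnAy-style consensus): a documented
  weight-matrix approximation of SVM-based branch-point predictors.
- **PPT** — the polypyrimidine tract for that branch point: the
  maximal-scoring window between BP and −3 under pyrimidine +1 / purine
  −2, minimum length 5, pyrimidine fraction ≥ 0.6.
- **Intrinsic site strength** — frequency-matrix log-odds score in bits,
  `Σᵢ log₂(pᵢ(bᵢ)/q(bᵢ))`.
- **PU** — the equilibrium probability that each position is unpaired,
  `PUᵢ = 1 − Σⱼ p(i,j)`, with base-pair probabilities p(i,j) from
  McCaskill-style inside–outside recursions over a pair-additive energy
  model (exact for that model; verified against exhaustive enumeration).

Group-level statistics (Welch t, Wilcoxon–Mann–Whitney, exact two-tailed
binomial, χ², upper-tail hypergeometric, Pearson r, Benjamini–Hochberg)
compare the groups, including the positional **delta-PU** statistic
`Δᵢ = mean PUᵢ(up) − mean PUᵢ(down)` with per-position Wilcoxon tests.
An APA module classifies alternative-polyadenylation events into tandem
3′UTR, intronic, and alternative-3′ss categories with proximal/distal
shift calls, and a synthetic-cohort generator plants all of these effects
with known ground truth so the whole pipeline is testable without any
external data.

## Worked example

```python
import numpy as np
from acceptorkit import compare_feature, find_agez
from acceptorkit.synthetic_data import default_cohort_config, generate_cohort

cohort = generate_cohort(default_cohort_config(seed=1, n_per_group=20))
agez = {g: [find_agez(r).agez_length for r in cohort.regions_by_group(g)]
        for g in ("up", "down")}
res = compare_feature(agez["up"], agez["down"], "t")
print(f"mean AGEZ: up {np.mean(agez['up']):.1f} nt, down {np.mean(agez['down']):.1f} nt")
print(f"Welch t = {res.statistic:.2f}, p = {res.p:.2g}")
```

prints

```
mean AGEZ: up 71.7 nt, down 43.0 nt
Welch t = 8.36, p = 4e-10
```

i.e. the upregulated group's planted ~70 nt AG exclusion zones are
recovered by measurement and cleanly separated from the downregulated
group's ~40 nt zones.  The `examples/` directory has one short script per
capability (architecture features, site strength and the site-pair
binomial test, PU/delta-PU, APA classification, the full pipeline).

## Command line

```bash
acceptorkit generate     --out cohort_dir --seed 1     # synthetic inputs
acceptorkit architecture --out run_dir --seed 1        # features + stats
acceptorkit structure    --out run_dir --seed 1        # PU / delta-PU
acceptorkit apa          --out run_dir --seed 1        # APA + exon classes
acceptorkit all          --out run_dir --seed 1 [--config run.yaml]
```

Outputs are tab-separated tables (`features.tsv`, `comparisons.tsv`,
`pu_profile.tsv`, `delta_pu.tsv`, `apa_events.tsv`, …) plus a
`manifest.txt` echoing every constant; identical seed and config give
byte-identical tables.

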