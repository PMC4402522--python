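# Methods

## Coordinate and alphabet conventions

Genomic intervals are 0-based half-open (BED).  Inside an extracted
window, positions are signed offsets anchored at the 3′ splice site:
−1 and −2 are the G and A of the 3′ss AG dinucleotide, +0 is the first
exon nucleotide, and there is no zero on the intron side.  Position
labels of the "+1 = first exon base" style used in much of the splicing
literature correspond to this package's +0.  Minus-strand windows are
reverse-complemented at extraction so all downstream code sees 5′→3′
transcribed-strand RNA over {A, C, G, U, N}.  N is excluded from every
composition denominator and can never base-pair.  The default window is
100 nt of intron and 50 nt of exon, configurable; it covers the branch
point region (typically −17..−38) and the offsets analyzed by the
delta-PU statistic (to −50) with margin.  No canonical window length is
implied by the method itself — it is a declared choice.

## AG exclusion zone

Scanning 3′ss-proximal to distal, the first AG whose G lies at offset
≤ −3 bounds the zone; `AGEZ = |g_offset| − 3` counts the nucleotides
strictly between that G and the A of the 3′ss AG.  Windows with no
upstream AG are *censored* with `AGEZ = up_len − 2`; censoring is carried
as a flag so group statistics can be recomputed without censored values
if desired.  The convention that the zone excludes both bounding AGs is
declared here, not derived: reported AGEZ conventions differ by ±1–3 nt
and any fixed convention preserves between-group contrasts.

## Branch point and PPT

Branch points are scored with a position-frequency (log-odds) matrix over
a 7-mer with the branch adenosine fixed at position 6, trained by default
on a small packaged alignment of yUnAy-style 7-mers (pseudocount-smoothed,
`(count + c)/(n + 4c)`).  This is a deliberate approximation of published
SVM-based branch-point predictors, whose trained internals are not
reproducible from their descriptions; what matters downstream is only the
*argmax* site, and the PPT is anchored at the highest-scoring branch point
exactly as in the SVM-based workflow.  Candidates are every A in the
search range (default −9..−100) whose window fits in the region, sorted
by score with ties broken toward the 3′ss-proximal offset (determinism).

The PPT for a branch point is the maximal-scoring contiguous window in
`(bp, −3]` under pyrimidine +1, purine −2, with minimum length 5 and
pyrimidine fraction ≥ 0.6; ties prefer longer, then more proximal
windows.  The weights and thresholds are declared constants (exposed in
configuration): no standard closed-form PPT definition exists, and the
chosen scoring absorbs single purines into long tracts (e.g. UUUUAUUUU
scores 6 as one 9-nt tract rather than two 4-nt runs) while refusing
purine-rich stretches.

## Intrinsic splice-site strength

A frequency-matrix score in bits: `Σᵢ log₂(pᵢ(bᵢ)/q(bᵢ))` with uniform or
empirical background.  The pipeline trains its 3′ss model (offsets
−20..+2, a 23-mer) on the control group's own windows with empirical
background, so "strength" is relative to the cohort at hand.  A
maximum-entropy (inclusion–exclusion) scorer is intentionally not
implemented: every contract in the pipeline (feature tables, the
site-pair preference test) is scorer-agnostic, and one fully specified
scorer keeps results reproducible.  The site-pair preference test counts
pairs where the promoted site outscores its competitor and applies the
exact two-tailed binomial test at null 0.5; exact score ties are counted
as not-stronger and reported separately.

## Partition function and PU

The energy model is pair-additive: each admissible pair (GC/CG −3.0,
AU/UA −2.0, GU/UG −1.0 kcal/mol by default) contributes a fixed energy;
structures are pseudoknot-free with ≥3 unpaired bases in every hairpin
loop; kT = 0.616 kcal/mol (37 °C).  The Boltzmann weight of a structure
is exp(−E/kT) and the empty structure has weight 1, so Z ≥ 1.  Inside
recursions

    Zb[i,j] = w(i,j) · Z[i+1,j-1]
    Z[i,j]  = Z[i,j-1] + Σₖ Z[i,k-1] · Zb[k,j]

and an outside pass (decomposition by the innermost enclosing pair, with
an O(n³) accumulator) give exact pair probabilities; per-position
unpaired probability is `PUᵢ = 1 − Σⱼ p(i,j)`.  Arrays are rescaled by a
per-nucleotide factor when the raw Z would overflow double precision
(automatically, on demand).  This model is *not* the Turner
nearest-neighbor model used by full folding engines — no stacking,
loop-length or dangle terms — and absolute PU values will differ from
RNAfold's.  The package's claims rest on contrasts between groups folded
under the same model, and an adapter hook (`fold_fn`) lets any external
engine's PU vectors flow through the identical profile/statistics path.
Within its own model the implementation is exact: an exhaustive
enumeration oracle (lengths ≤ 22) agrees with the dynamic program to
10⁻⁹ on Z and on every pair probability, and `PUᵢ + Σⱼ p(i,j) = 1` holds
to 10⁻⁹ at every position.

One property worth noting: making *every* pair energy less favorable by
+δ provably lowers the expected number of pairs (d⟨m⟩/dδ = −Var(m)/kT),
but per-position PU is **not** monotone under such a shift — suppressing
many-pair structures fastest can concentrate probability onto a single
pair and lower one position's PU.  The test suite checks the provable
global form and documents a concrete counterexample to the per-position
form (verified by enumeration).

PU profiles fold each window once — optionally re-extracted with a flank
(default 30 nt) on each side so edge positions see realistic context —
and report only the unextended offsets.  The per-position quantity is
substring-length-1 PU; a constrained-partition-function `pu_substring`
(probability an entire substring is unpaired) is exposed but not used by
the pipeline, because positional averaging across regions is only
well-defined position-wise.

## Delta-PU statistics

At each offset covered by both groups, `Δ = mean PU(up) − mean PU(down)`;
per-offset two-sided Wilcoxon–Mann–Whitney tests use the exact null
distribution when both groups have n ≤ 12 and the data are tie-free, and
the tie-corrected normal approximation with continuity correction
otherwise.  Offsets with fewer than two regions in either group get no
p-value.  Benjamini–Hochberg q-values across offsets are reported
alongside, but the significance star uses the raw p < 0.05 — positional
stars are a descriptive device here, and the q column is provided for
readers who want the stricter criterion.

## Group statistics

Welch's unequal-variance t-test (group variances are not assumed equal);
the exact two-tailed binomial p by the point-probability method (sum of
all outcomes whose point probability does not exceed the observed one) —
under this definition 51 of 138 at null 0.5 gives p = 0.0028, printing as
0.003; Pearson χ² without continuity correction; upper-tail
hypergeometric enrichment; Pearson correlation with t-transform p; BH
step-up with monotonicity enforcement.  Zero-variance degenerate inputs
are handled by convention (equal constant groups compare with p = 1;
zero-variance correlations are refused as undefined).

## Synthetic cohorts

The generator builds each window outward from the 3′ss — fixed AG at
−2/−1, an AG-free zone of sampled length closed by a planted AG, a
branch-point 7-mer and a PPT of sampled length/composition inside the
zone, zone-specific base-composition modifiers, and background filler
that is resampled wherever an AG would arise inside the zone — so planted
AGEZ equals measured AGEZ exactly, by construction rather than by
filtering.  Expression changes are drawn with a configurable correlation
to the AGEZ z-score (Gaussian copula construction), so the planted r is
the population value of the measured pair.

Default ("architecture") conditions: AGEZ means 70/40/45 nt with sd
15/12/12 for up/down/control; adenine depletion over −17..−38 in the up
group; PPT length means 22/14/16; planted r = 0.4 in the up group only;
100 exons per group.  Structure-contrast conditions: 60 exons per group,
windows to −55, all groups purine-free outside the two AG dinucleotides
(so base-pairing partners are scarce), and a 10-bp stem + 6-nt loop
hairpin overwriting offsets −50..−25 in the down group only.  In this
pairing-poor setting the branch-point motif is not planted — its
adenosines would seed A–U pairs and blur the intended contrast — which is
why the structure cohort tests PU machinery and the architecture cohort
tests BP/PPT machinery.  Every region is embedded in its own small
contig (random strand) so the FASTA/BED/group-table round trip exercises
strand-aware extraction end to end.

A single seed drives one root generator; per-region substreams are
derived from (seed, group, index) counters, so cohorts are byte-identical
for a fixed seed regardless of generation order.

What the generator does **not** emulate: genome-scale base composition,
splice-site sequence realism beyond the planted motifs, transcript
structure diversity, coverage noise, or the read-level processes that
produce real differential-usage calls.  Passing recovery tests therefore
demonstrates that the measurement and statistics machinery is correct and
well-powered under the stated conditions — not that any particular
biological dataset will show these effects.

## APA classification

The rule cascade formalizes what is usually manual browser curation, in
order: (1) *tandem 3′UTR* — both poly(A) sites inside one annotated
terminal exon, blocked when terminal exons with distinct acceptors split
the two sites; (2) *intronic* — proximal site inside an annotated intron
of an isoform whose terminal exon holds (or precedes) the distal site;
(3) *alternative-3′ss* — overlapping terminal exons with distinct 3′ss,
one holding each site.  The shift is proximal/distal according to which
site the upregulated exons sit nearest; conflicting or missing evidence
flags the event ambiguous, and ambiguous events are excluded from
tallies rather than guessed.  Exon–transcript matching for the
start/internal/terminal classification is exact interval equality
(tolerance 0): annotations generated by this package are consistent by
construction, and fuzzy matching would hide coordinate bugs.  A
single-exon transcript's exon is classed terminal.

## Problem sizes and numerical choices

Cohort sizes in the shipped tests and the acceptance script are the
study conditions above (100/group architecture, 60/group structure,
10/group for the determinism check); folding windows are ≤ ~210 nt, where
the cubic recursions take well under 0.1 s each.  All tie-breaks
(branch-point candidates, PPT windows) resolve toward the 3′ss-proximal
option; all thresholds (p-star 0.05, PPT constants, energy defaults)
surface in the run manifest.  Degenerate inputs — non-canonical windows
(no AG at −2/−1), truncated windows at contig edges, censored AGEZ,
regions with no adenosine in the BP search range — are flagged and
propagated, never silently dropped.

## Known limitations

The weight-matrix BP scorer ranks plausible branch points but is not a
validated predictor of experimental branch-point usage; the pair-additive
energy model ranks single-strandedness contrasts but not absolute folding
stability; the APA cascade decides only from annotation geometry and the
up/down labels, not from 3′-seq quantification; and the binomial/χ²/
hypergeometric helpers assume the usual independence of observations,
which exon-level data drawn from shared genes need not satisfy.
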