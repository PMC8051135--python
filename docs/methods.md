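# Methods

## Scope and data model

The package post-processes chromatin-state segmentations, peak sets, gene
annotations, expression tables, genome sequence and signal tracks for a
paired progenitor/differentiated comparison. All coordinates are 0-based,
half-open (BED convention) everywhere internally; chromosome names are
matched by exact string equality, with a validation helper that warns on
disjoint vocabularies rather than guessing at "chr" prefixes. Strand is
carried on genes only — none of the analyses use peak or enhancer strand.
Segmentations may contain gaps; uncovered bases are "unmarked" chromatin and
count as not-active in every classification.

## Enhancer calling and stretch enhancers

Enhancers are maximal stitches of the enhancer-associated states (defaults:
states 2 and 3 of an 11-state model) merged across gaps of at most
`max_gap = 1` bp, mirroring `bedtools merge -d 1`: two intervals merge iff
`start_next − end_prev ≤ max_gap`. The stretch flag is strict:
`length > 3000` bp, so a 3,000-bp enhancer is typical and a 3,001-bp one is
stretch. Sharing between two sets uses bidirectional overlap: the overlap
must cover at least `min_fraction = 0.25` of *each* interval, and a single
satisfying partner suffices (overlaps are not summed across partners —
summing would need a justification the analysis design does not supply).
Because per-set "shared" counts can differ, the report carries both per-set
counts and a Venn-style count of connected components containing members of
both sets, plus the fraction shared of the union
`(shared_A + shared_B)/(n_A + n_B)`; no single denominator is privileged.

## Binding-site classification

Peak sharing uses ≥ 1 bp overlap — the weakest defensible convention, and a
parameter for sensitivity analysis. The chromatin state of a site is the
state of the segment containing the midpoint base `⌊(start+end)/2⌋`
(deterministic and robust to peak-width variation; maximal-overlap
assignment would change classifications only for peaks straddling state
boundaries). Transition classes partition every site:

| class | sharing | progenitor state | differentiated state |
|---|---|---|---|
| repressed→active | B-only | not active | active (1–6) |
| active→active | shared | active | active |
| active→repressed | A-only | active | not active |
| other | anything else | | |

TSS proximity is boundary-inclusive: a peak is promoter-proximal when the
distance from the peak interval to the nearest TSS is ≤ 1,000 bp, distance
being 0 inside the interval and otherwise measured to the nearest covered
base (`end − 1` on the right). FRiP consumes read *spans* (BED intervals),
not alignment files; a read counts when it overlaps any peak by ≥ 1 bp.

Aggregate profiles average signal in fixed-width offset bins around site
midpoints; the reported profile is the unweighted mean over anchors of
per-anchor bin means, and anchors whose window runs past the chromosome end
contribute only to the bins they cover.

## Motif scanning and density

PWMs are probability matrices over {A,C,G,T}; count matrices (JASPAR PFMs)
receive a pseudocount of 0.25 per cell before normalization so log-odds
scores stay finite. Scores are log2(p/background) summed over positions;
because positions are independent the score extrema are the sums of the
per-column minima and maxima, and the relative score is
`(s − s_min)/(s_max − s_min)` (for the degenerate all-uniform PWM, whose
score range is empty, every window scores the maximum and rel = 1 by
convention). The "80% threshold" keeps windows with rel ≥ 0.8; both strands
are scanned by default (reverse-complement matrix on the forward sequence,
coordinates reported on the forward strand) and windows containing N are
skipped. Density profiles place each hit at its window center
(`start + ⌊L/2⌋`, symmetric for palindromes), count all overlapping hits
(density, not annotation), and report hits per bp per site, so the profile
integrated over the window is the mean hit count per site. The default
window of ±500 bp with 10-bp bins is a declared choice, not an inference;
both are configurable.

## Expression-matched permutation test

The observed statistic is the number of **distinct** stretch enhancers with
at least one signature-gene TSS within `half_window = 50,000` bp of the TSS
(50 kb each side, i.e. a 100-kb window; an enhancer near several signature
genes counts once). The null redraws the gene set `N = 10,000` times:
universe genes are split into `n_bins = 10` quantile bins of
log10(FPKM + 1) in the differentiated condition, and each draw takes, per
target gene, one non-target gene uniformly without replacement from the
same bin — the sampled bin-occupancy vector equals the target's exactly.
Matching on quantile bins was chosen because it is simple and exactly
reproducible; the bin count and matching condition are parameters. The
empirical p-value is the plain fraction `#{null ≥ observed}/N` — the
convention under which 2 exceedances in 10,000 give 0.0002 — and the
add-one estimate `(k+1)/(N+1)`, which can never be zero, is always reported
alongside as the statistically safer value. Draws are without replacement
within a permutation. With a fixed seed the result, including the null
vector, is byte-reproducible.

## Companion statistics

- **Bound vs unbound expression**: two-sided Mann–Whitney U on FPKM
  (distribution-free, appropriate for heavy-tailed FPKM). Exact
  distribution when both groups have ≤ 20 observations and the pooled
  sample is tie-free; otherwise the normal approximation with tie
  correction and no continuity correction (this also returns p = 1 exactly
  for identical groups). Fully constant input returns U at its mean with
  p = 1.
- **Gene-family ANOVA**: classical one-way fixed-effects F with p from
  F(k−1, n−k); all-identical input returns F = 0, p = 1 with a warning.
  The grouping units are caller-supplied — the operation is generic.
- **Nearest-gene fold change**: log2((FPKM_B + 1)/(FPKM_A + 1)) of the gene
  with minimal TSS-to-enhancer distance; ties break to the
  lexicographically smaller gene id. The pseudocount of 1 keeps the value
  finite for unexpressed genes and monotone in the FPKM ratio; a dedicated
  differential-expression model is deliberately out of scope.
- **Top-percent selection**: genes with FPKM > 0 in either condition are
  ranked by log2 fold change; the top ⌈(percent/100)·n_expressed⌉ are
  returned.
- **Proportions**: integer percents round half up (8/26 → 31%, 8/270 → 3%,
  5/11 → 45%).

## The synthetic-data generator

The generator emulates the study conditions at desk scale: 3 chromosomes ×
2 Mb at 200-bp bins, 1,500 genes, 4,000 binding sites, two conditions.

- **Segmentation**: first-order Markov chain over 11 states per 200-bp bin.
  Within the enhancer-state pair {2,3} the dwell probability is 0.818
  (progenitor) and 0.838 (differentiated); since a merged enhancer run of
  k bins is geometric with P(k ≥ 16) = p^15, these dwell values put the
  stretch-enhancer fraction (strictly > 3,000 bp) at ~4.9% and ~7.1% — the
  fractions the pipeline is expected to report for the two states. The
  entry rate into enhancer states (0.028 per bin) sets ~700 enhancers and
  ~30–55 stretch enhancers per condition on the 6-Mb genome: enough to
  plant a 25-gene signature on distinct stretch enhancers, sparse enough
  that 50-kb windows cover only part of the genome and the permutation test
  retains contrast. Other states have a stay probability of 0.55 with the
  remainder spread uniformly.
- **Genes/expression**: TSSs uniform over the genome; FPKM is log-normal
  with a shared per-gene level (log-mean 1.0, log-sd 1.5, natural log) plus
  per-condition noise (sd 0.4). A random 10% of genes is "promoter-bound"
  and has differentiated-condition FPKM multiplied by 4. The 25-gene
  signature set is relocated so each TSS falls within 50 kb of a distinct
  differentiated-condition stretch enhancer; relocation changes position
  only, not expression.
- **Peaks**: sites are shared / A-only / B-only with probabilities
  (0.4, 0.3, 0.3); unique sites fall, with probability 0.9, in bins active
  in their own condition and inactive in the other (shared sites prefer
  both-active bins). Site midpoints stay ≥ 800 bp apart so planted classes
  are recoverable by ≥ 1-bp-overlap sharing. Widths are normal(400, 100)
  clipped to [150, 750] bp.
- **Sequence/motifs**: the genome is i.i.d. uniform {A,C,G,T}. Four
  synthetic consensus families (POU-like 9-mer, bZIP-like 11-mer, HTH-like
  palindromic 14-mer, bHLH-like 10-mer; consensus weight 0.97 per column)
  are planted at site midpoints, each independently with probability 0.5:
  POU-like at every site, bZIP-like at A-only sites, HTH- then bHLH-like at
  repressed→active sites. A later plant overwrites overlapping earlier
  plants; the truth table records survivors only, at offset 0. Family
  lengths of 9–14 bp keep the 0.8-threshold background rate (which admits
  roughly ⌊L/5⌋ mismatches) orders of magnitude below the planted rate.
- **Tracks**: triangular bumps (height 4.0, half-base 250 bp) on a flat 0.1
  baseline, sampled in 5-bp steps at step midpoints, so the aggregate
  center-bin mean has the closed form `baseline + h·(1 − 2.5/w)`.

Each component owns a seeded sub-stream (split via `SeedSequence` spawn
keys), so the full dataset is a pure function of the configuration and
changing one component's parameters leaves the others byte-identical.

What the generator does **not** emulate: read-level noise, GC bias,
nucleosome structure, correlated state emissions, realistic gene clustering,
linkage between enhancers and target-gene expression (stretch enhancers
carry no planted expression effect beyond the signature relocation), or
motif co-occurrence grammar. Passing tests therefore demonstrate that the
algorithms recover planted interval/expression/sequence structure at
realistic scales — not that the biological effect sizes in real data will
match.

## Problem sizes and numerical choices

The test suite and acceptance script run at the default scale above;
calibration checks use 400 null runs × 500 permutations and power checks 20
seeds × 1,000 permutations, sizes chosen to keep the whole suite in a few
minutes on one core while leaving binomial noise well inside the asserted
bands. Quantile-bin edges use `numpy.quantile` with right-closed
`searchsorted` assignment; merge operations are stable sorts; all RNG is
`numpy.random.default_rng` seeded explicitly. Degenerate inputs (empty
enhancer sets, empty gene sets, constant expression, uniform PWMs) return
defined values with warnings rather than raising, except where the
operation is meaningless (empty anchor sets, zero reads, empty groups).

## Known limitations

- The sharing "headline" number depends on the denominator; both the
  per-set counts and the component count are emitted, and users comparing
  against published Venn diagrams should check which convention applies.
- Peak inputs are treated as full intervals; if a peak caller emits point
  summits, widths of 1 make midpoint-state assignment trivially correct but
  sharing by ≥ 1 bp overlap very strict.
- Two co-staining proportions quoted in the motivating experimental work
  are internally inconsistent with their printed counts (87% vs 63/76 ≈
  82.9%, and 6% vs 63/872 ≈ 7.2%); the proportion operation here reproduces
  the arithmetic from counts and makes no attempt to match inconsistent
  rounded values.
- The Mann–Whitney exact path is limited to tie-free pooled samples; with
  ties it falls back to the tie-corrected normal approximation even for
  small groups.
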