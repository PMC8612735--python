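# Methods

## Overview

`aavscreen` implements the analysis side of a pooled, barcoded AAV capsid
screen read out by droplet single-cell RNA-seq. Each capsid variant in the
injected pool packages the same GFP transgene fused to a unique DNA barcode,
so every captured tagged mRNA reports which variant produced it and in which
cell. The package turns read-level barcode evidence into a per-cell,
per-variant infection table, attaches cell types, and computes the ranking
metrics and the statistics used to compare variants. It also covers the
upstream directed-evolution (DE) analytics used to nominate variants, and a
simulator of the barcode-capacity question (how many variants one sample can
resolve).

## Quantification model

A read is a tuple (source, cell barcode, UMI, payload). Sources are the
standard scRNA-seq run (`scrna`) and a targeted PCR re-amplification of the
same prepped single-cell library (`pcr`); because the PCR run re-amplifies
already-barcoded cDNA, the two sources see the same molecules under the same
cell barcodes and UMIs, just at different depth and error load.

Processing steps, in order:

1. **Cell-barcode correction.** Exact whitelist matches pass; a barcode at
   Hamming distance 1 from exactly one whitelist entry is corrected; at
   distance 1 from several, the entry with the highest exact-match read
   abundance wins and abundance ties discard the read; distance >= 2
   discards. This is a documented, deterministic stand-in for the droplet
   vendor's correction step.
2. **Variant assignment.** A payload is assigned to a variant iff it
   contains that variant's barcode and no other ("one hit" rule). Matching
   is exact by default; a substitution radius `max_mismatch` is allowed only
   when `2*max_mismatch` is strictly below the minimum pairwise Hamming
   distance of the library, otherwise "unique hit" would be ill-defined and
   the configuration is rejected.
3. **UMI collision resolution.** One UMI marks one molecule, so one variant
   per (source, cell, UMI). When several variants appear under one UMI the
   one with the most reads is kept; exact ties drop the UMI (determinism
   over recall). Distinct surviving UMIs per (cell, variant) are the counts.
4. **Source merging.** The deeper PCR table is the backbone; (cell, variant)
   pairs seen only in scRNA-seq are added; for pairs in both, the count is
   the size of the union of distinct UMIs across sources, so a molecule
   sequenced in both runs is counted once.
5. **Normalization.** tagged_per_100k = umi_count / nUMI(cell) x 100,000
   / dilution_factor(variant), where nUMI is the cell's total transcriptome
   UMI count.

**Dilution factor.** The injected pool is quantified by deep sequencing;
we define dilution_factor = pool_fraction x n_variants, so a perfectly
equimolar pool has factor 1.0 everywhere and correction is a no-op. Any
global rescaling of this definition cancels in rankings; absolute corrected
values depend on it, which is why it is stated here. Percent-infected
correction divides by the factor, boosting under-represented pool members.
An optional post-hoc flag additionally divides all values by the factor of
the variant infecting the most cells; it is off by default and never
changes rankings. Loading warns (never fails) when a pool fraction is more
than 10x from the pool mean, the band within which normalization across
samples is treated as reliable.

## Cell typing

Counts are log-normalized (ln(1 + count/nUMI x 10^4)), reduced to the top
50 principal components (fewer when the fixture has fewer genes), embedded
in a kNN graph with k = max(15, 0.5% of cells) on Euclidean PC distance,
and clustered with Leiden at a configurable resolution (default 1.0). The
floor of 15 neighbors keeps small fixtures connected. Externally computed
labels can be supplied as a TSV instead.

Per-cluster markers are ranked by a one-sided (overexpression), tie-corrected
Wilcoxon rank-sum z score of in-cluster versus all other cells on
log-normalized values; the top 100 genes (configurable) form the cluster's
list. For each (cluster, type) pair, the overlap k between the cluster list
and the type's marker set is scored with the upper-tail hypergeometric
probability P(X >= k) on the universe N = tested genes ∩ database universe.
p-values are Bonferroni-corrected with the joint multiplier
n_clusters x n_types, and each cluster gets the type minimizing the
corrected p, or "unassigned" when the minimum is not below alpha = 0.05.
Ties resolve to the lexicographically first type name and all tied types
are reported.

**Numerical note.** The hypergeometric tail is computed from an exactly
evaluated leading pmf term (integer combinatorics) extended by the pmf
ratio recurrence, starting at the support minimum max(k, n+K-N). The sum of
positive terms keeps relative error near machine precision (~1e-14
observed), substantially tighter than summing floating-point log-pmf terms;
a log-space fallback handles leading terms below double-precision range.

## Statistics

All inference is nonparametric, matching the heavy-tailed, zero-inflated
character of per-sample infection metrics. Shapiro-Wilk is provided as an
advisory screen only. The Friedman omnibus test ranks variants within each
sample block (mid-ranks on ties) and applies the standard tie-corrected
chi-square approximation; incomplete matrices are an error, never imputed.
Focal comparisons are one-sided Wilcoxon signed-rank tests of a chosen
variant against each other variant, paired across samples, zero differences
dropped; the exact sign-flip null is enumerated (via a subset-sum dynamic
program over doubled mid-ranks, equivalent to all 2^n patterns) for n <= 25
non-zero pairs, with the tie-corrected, continuity-corrected normal
approximation above that. The family of comparisons is Benjamini-Hochberg
adjusted per focal variant and metric, not pooled across metrics.

## Directed-evolution analytics

- **Insert extraction**: amplicons are translated on the standard codon
  table and scanned for the constant-linker window (LA + 7 random residues
  + A, 10 aa total); the translated window is the insert identity, so
  synonymous DNA collapses. Reads with stops inside the window, no linker
  match, or too short to span it are tallied and dropped.
- **Round-over-round ranking**: a pseudo-count of 1 is added to every
  variant's count in every round *before* the round total, so adjusted
  frequencies still sum to 1 within each round; fold increase is
  final-round frequency over plasmid-library frequency, ranked descending
  with lexicographic tie-break. The ranking is invariant to uniform depth
  rescaling of any round (exactly at pseudo-count 0, asymptotically at 1).
- **Subset-library ranking**: percent-of-total in the recovered sample over
  percent-of-total in the injected library. No pseudo-count is applied
  here: the injected library is deeply sequenced and a zero-injected
  variant indicates a data problem, so it is an error rather than silently
  regularized.

## Ranking metrics

Per (variant, cell type, sample): the infected-cell count, percent infected
(n_infected / n_cells_of_type x 100 / dilution_factor), and the mean of
tagged_per_100k over infected cells only (already dilution-corrected —
never corrected twice; reported as missing when no cell of the type is
infected). The "Total" row uses all cells passing QC, including cells whose
cluster stayed unassigned; unassigned cells appear in no per-type row.
Co-infection is summarized by exact variant-subset intersection sizes
(which sum to the number of infected cells, an asserted invariant) and
per-variant set sizes. The scatter view pairs percent infected with mean
expression and flags the Pareto frontier (no other variant >= on both axes
with one strict) per cell type and overall.

## Barcode capacity

The number of distinct length-L DNA barcodes is exactly 4^L. The
saturation simulator draws Poisson(MOI) infecting genomes per cell,
uniform over the 4^L space (every position equiprobable), then samples a
fixed number of expressed tagged UMIs per cell from that cell's genomes.
It reports distinct barcodes among captured UMIs (`unique_recovered`) and
among all infecting genomes (`unique_infecting`), since captured-vs-raw
distinct counts can differ in principle. Defaults — 8,000 cells, MOI
1,000, 100 captured UMIs per cell — are the experimental scale of the
saturation question; at that scale the 3 bp (64) and 6 bp (4,096) spaces
are exhausted with miss probabilities far below double precision, and the
conclusion is insensitive to the capture depth across at least two orders
of magnitude (asserted in tests). Recovered counts for 9 bp and 14 bp
libraries in a real experiment are dominated by synthesis and cloning
bottlenecks that this uniform model deliberately does not include, so no
claim is made about them beyond the 4^L bound.

The in vitro (cultured HEK293-style) summary downsamples reads uniformly
without replacement to 300,000 (seeded), corrects cell barcodes — against
the barcodes observed more than once when no external whitelist exists,
since droplet QC is inapplicable to targeted enrichment data — and reports
distinct corrected barcodes with >= 1 assigned tagged UMI as the cell
count, with mean distinct (cell, UMI) pairs per cell as expression.

## Synthetic data: what it does and does not emulate

The generator produces the joint structure the pipeline assumes:

- cell types drawn from configured proportions; per-gene UMI counts
  negative-binomial (dispersion 2.0, baseline mean 0.5 UMIs/gene) with each
  type's marker genes elevated 8-fold — NB is the standard overdispersed
  model for droplet UMI counts, and typing needs only this rank structure;
- infections Bernoulli per (variant, cell type); tagged molecules
  Poisson(expression rate, default 3 UMIs per infected cell), with a cell
  counting as truly infected only when >= 1 tagged molecule exists (an
  unexpressed infection is invisible to any transcriptome assay);
- each true molecule emits 1 scrna read and `pcr_capture_gain` (default
  20) pcr reads under the same cell barcode and UMI, with independent
  per-base substitution errors (default 0.005) on the variant barcode; an
  optional fraction of UMIs carries a one-read intrusion from another
  variant to exercise the collision resolver;
- variant barcodes are 25 bp with pairwise Hamming distance >= 5, as for
  distinct cloned tags, so single errors cannot convert one tag into
  another;
- DE round counts start uniform (plasmid library) and are multinomially
  resampled each round at fixed depth with per-variant enrichment
  multipliers.

Not emulated: ambient RNA, empty droplets, doublets (the corresponding QC
runs upstream of this package; a doublet fraction flag exists for ad-hoc
robustness checks but is never asserted on), batch effects, UMI sequencing
errors (no directional-network collapsing is implemented), cell-barcode
errors in the simulator itself, and library-synthesis bias. Passing tests
therefore demonstrate correctness of the analysis on data matching the
stated generative assumptions, not robustness to every artifact of real
droplet data.

Test fixtures use 500–2,000 cells, 4 cell types, 6 variants at infection
rate 0.10, and 10 marker genes per type — sizes at which per-type binomial
sampling error (the 3-SD recovery band) is a few percent and clustering
separates types essentially perfectly. Noiseless runs must reproduce
ground-truth infection tables exactly; default-noise runs must recover
per-(variant, type) infected fractions within 3 binomial SDs.

## Known limitations

- Exact barcode matching discards reads whose tag was hit by an error
  (~12% of 25-mers at the default error rate); with ~21 reads per molecule
  across sources the per-molecule loss is negligible, but single-read
  molecules at high error rates will be undercounted.
- The collision tie rule (drop the UMI) trades a little recall for
  determinism.
- Percent-infected dilution correction can exceed 100 for heavily
  under-represented pool members; values are reported as-is.
- Leiden resolution is a free parameter (default 1.0); the package makes
  no attempt to select it automatically.
- The Friedman and signed-rank machinery assumes exchangeable sample
  blocks; which blocks form a family is the caller's decision.
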