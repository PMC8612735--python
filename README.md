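# aavscreen

Quantitative, cell-type-resolved ranking of barcoded AAV capsid variants
from single-cell RNA-seq.

## The problem

Choosing a gene-therapy capsid means knowing, for every cell type in the
target tissue, how many cells each candidate AAV variant infects and how
strongly it expresses its cargo — ideally for many candidates at once, in
the same animal, so that between-animal variability cancels. A pooled
screen does this by packaging each variant with the same GFP transgene
fused to a variant-specific DNA barcode: every captured tagged mRNA in a
droplet scRNA-seq run then reports (cell, variant, molecule). `aavscreen`
is the analysis stack for such screens, for researchers ranking engineered
capsids (and for the upstream directed-evolution rounds that nominate
them).

## What it computes

Given a post-QC cell x gene UMI matrix, a variant-barcode library with
pool abundances, and read-level barcode evidence from the standard
scRNA-seq run plus a targeted PCR re-amplification of the same library:

- **Infection table** — cell barcodes corrected (whitelist + 1-Hamming),
  reads assigned to variants by a strict unique-hit rule, multi-variant
  UMI collisions resolved by majority, PCR and scRNA-seq views merged by
  distinct-UMI union. One row per (cell, variant) with its UMI count.
- **Normalization** — tagged transcripts per 100,000:
  `umi_count / nUMI * 1e5 / d_v`, where `d_v = pool_fraction_v * n_variants`
  is the variant's dilution factor (1.0 for every member of an equimolar
  pool).
- **Cell typing** — PCA (top 50 PCs) -> kNN graph (0.5% of cells, floor
  15) -> Leiden; per-cluster markers by one-sided rank-sum score; cluster
  -> cell type by the most significant hypergeometric marker-set overlap
  P(X >= k) with Bonferroni correction over clusters x types.
- **Ranking metrics** — per (variant, cell type): percent infected
  (`n_infected / n_type * 100 / d_v`) and mean tagged-per-100k over
  infected cells; co-infection subset sizes (upset counts); Pareto-frontier
  flags on the percent-vs-expression scatter.
- **Statistics** — Shapiro-Wilk screen, tie-corrected Friedman omnibus
  across variants with samples as blocks, one-sided exact Wilcoxon
  signed-rank tests of a focal variant vs each other (exact null
  enumeration for n <= 25), Benjamini-Hochberg correction.
- **Directed evolution** — 7-mer insert extraction/translation (LA + 7 aa
  + A window), pseudo-count-1 fold-increase ranking across rounds
  (`f_last / f_plasmid` on adjusted frequencies), and percent-of-total
  fold ranking of barcoded subset libraries.
- **Barcode capacity** — exact 4^L capacity and a saturation simulator
  (cells x Poisson(MOI) genomes, uniform barcodes, fixed UMI capture per
  cell).
- **Synthetic data** — a ground-truthed generator for all of the above
  (typed tissue with negative-binomial counts and elevated markers,
  Bernoulli x Poisson infections, duplicated/error-laden reads from both
  sources, DE round counts), so the whole pipeline is testable end to end
  without any download.

## Worked example

Simulate a 400-cell sample with 4 barcoded variants, quantify it, and
compute per-type metrics:

```bash
aavscreen simulate --n-cells 400 --n-variants 4 --seed 5 --out-dir sample
aavscreen quantify --reads sample/reads.tsv --matrix-dir sample \
    --variants sample/variants.fasta --abundance sample/abundance.tsv \
    --out-prefix q
aavscreen metrics --counts q.counts.tsv --expression q.expression.tsv \
    --cell-types sample/cell_types.tsv --variants sample/variants.fasta \
    --abundance sample/abundance.tsv --out-prefix m
head -4 m.metrics.tsv
```

```
sample_id  cell_type  variant_id  n_cells_type  n_infected  pct_infected  mean_tx_per_100k
sample     bipolar    VAR00       108           2           1.8518...     7631.43...
sample     cone       VAR00       101           5           4.9504...     5668.66...
sample     rgc        VAR00       96            4           4.1666...     7156.87...
```

Reading the first row: 108 bipolar cells were identified, 2 of them carried
at least one VAR00-tagged transcript (1.85% after dilution correction —
here the pool is equimolar, so the correction is a no-op), and within those
infected cells VAR00 transcripts averaged ~7,631 per 100,000 total
transcripts. Clustering and typing run the same way from the CLI
(`cluster`, `markers`, `assign-types`), and on this sample recover the four
simulated types exactly:

```bash
aavscreen cluster --matrix-dir sample --n-pcs 20 --resolution 0.3 --seed 0 --out labels.tsv
aavscreen markers --matrix-dir sample --labels labels.tsv --top-n 10 --out markers.tsv
aavscreen assign-types --markers markers.tsv --marker-db markerdb.tsv \
    --matrix-dir sample --out assign.tsv
# cluster 0: rod / cluster 1: cone / cluster 2: rgc / cluster 3: bipolar
```

The capacity tools answer "how many variants can one sample resolve":

```bash
aavscreen capacity 9          # -> 262144
aavscreen saturation --length 3 --n-cells 1000 --moi 100 --seed 2
# -> "unique_recovered": 64   (the 3 bp space saturates)
```

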