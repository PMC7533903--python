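# Methods

## The QC model

`tcrqc` treats droplet QC for paired GEX+V(D)J data as a windowing problem on
per-barcode UMI totals, with the window's upper bound anchored to an internal
biological control. The assumptions, in decreasing order of strength:

1. **Diploid chain ceiling.** A single T cell expresses at most two
   productive TCRα and two productive TCRβ chains (one per allele). A barcode
   whose contig table shows more than two productive chains at either locus
   must contain at least two cells. This is a structural statement, not a
   statistical one; its only failure modes are technical (ambient or
   chimeric contigs miscalled as productive and cell-associated), which is
   why the default counting rule also demands full-length, high-confidence
   contigs.
2. **Single-chain anchoring.** Barcodes with exactly one productive chain at
   either locus (and no locus above two) are predominantly live single
   cells, so their UMI distribution is a fair sample of the single-cell UMI
   distribution. Doublets can leak into this set only through chain dropout
   of one component cell.
3. **Multiplet UMI excess.** A multiplet's transcriptome is the sum of its
   component cells', so multiplets sit high in the UMI distribution. A
   percentile of the anchor distribution therefore separates most multiplets
   from most cells, and the sweep makes the trade-off explicit rather than
   assuming a universal cut.

Dual-chain biology sets the key frequencies: the two-chain groups are
dominated by allelic inclusion (TCRα ~10–19%, TCRβ ~6–7% of T cells), not by
doublets, which is why only the 3-plus group is treated as definitive
multiplet evidence and why two-chain barcodes still qualify as anchors when
the other locus shows one chain.

## Thresholds

**Lower threshold.** Histogram of log₁₀(UMI+1) with `histogram_bins` (100)
bins, smoothed by a centered moving average of width `smoothing_window` (5,
windows truncated at the edges). The mode is the global maximum of the
smoothed density (ties toward smaller UMI); the threshold is the
back-transformed upper edge of the nearest local minimum left of the mode.
Two numerical guards:

- *Prominence.* A local minimum only qualifies if its smoothed density is at
  most `min_dip_ratio` (default 0.5) of the mode density. On histograms of a
  few thousand barcodes, Poisson noise routinely produces shallow dips on
  the flank of the live-cell peak; without the guard the scan can stop
  there and misplace the threshold inside the cell population. The ratio 0.5
  is deliberately loose — any genuine ambient/cell valley in droplet data is
  far deeper — and `min_dip_ratio=1` restores the unguarded rule.
- *Fallback.* A monotone left flank (no qualifying minimum) returns `floor`
  (default 0), i.e. no lower filtering rather than an arbitrary cut.

**Upper threshold.** Nearest-rank percentile — the ⌈p·n/100⌉-th order
statistic — of the UMI totals of single-chain barcodes, default p = 85.
Nearest-rank is exact on small n, interpolation-free, and makes the
retention identity `retained ∈ [p/100 − 1/n, p/100]` hold by construction.
The anchor set is taken *after* the lower threshold (the spec of the anchor
is "presumed live cells", and sub-threshold barcodes are presumed dead);
passing `lower=0` flips to the unfiltered order. The barcode sitting exactly
at the percentile is an observed cell, so the window is `lower < UMI ≤
upper`. With zero single-chain barcodes the function refuses and instructs
the caller to fall back to a chain-independent rule rather than silently
guessing.

**Aggregation.** For pooled multi-sample matrices the arithmetic mean of the
per-sample upper thresholds is applied to every sample (second pass in
`run_multi_sample`).

## Filter cascade

Order: lower UMI → upper UMI → mitochondrial fraction → gene ceiling → gene
floor (cells) → gene prevalence floor → TCR/BCR mask. Boundary conventions
are literal: remove if mito ≥ 0.10, remove if n_genes ≥ 3000, keep if
n_genes ≥ 200, keep genes in ≥ 10 *retained* cells. Because the gene
prevalence floor depends on the retained cell set, re-running the cascade on
its own output removes no further cells but may re-evaluate genes; the fixed
point for cells is covered by a test. The TCR/BCR mask matches
`^TR[ABGD][VDJC]` and `^IG[HKL][VDJC]` plus the immunoglobulin heavy-constant
symbols (IGHA/IGHD/IGHE/IGHG/IGHM with allotype digits); the segment letter
must follow the locus code directly, so TRAF1, IGHMBP2 and similar symbols
are untouched. The cascade is deliberately sequential with attributed
counts: each rule's removals are counted against the survivors of the
previous rules, so counts sum to the input barcode count.

Removing one sample wholesale (e.g. an anatomically distinct biopsy) is a
caller-level selection, supported by the `--samples` manifest filter, not a
filter rule.

## Group statistics

For each locus, barcodes are grouped by productive chain count
(0 / 1 / 2 / 3+) and the UMI-total and mito-fraction distributions of each
group are compared with group 1 by a two-sided Wilcoxon rank-sum test
(`scipy.stats.mannwhitneyu`); groups under two members are flagged untested.
No multiple-testing correction is applied by default — the table is a
diagnostic, not an inference — and a Bonferroni flag exists for callers who
want one. The expected signature on healthy data: group 0 lower UMI and
higher mito (dead cells and ambient), group 3+ roughly doubled UMI
(multiplets).

## Simulator

The generator's defaults define the validation conditions:

| parameter | default | rationale |
| --- | --- | --- |
| `n_droplets` | 2000 | small enough for seconds-scale tests, large enough for stable percentiles |
| `doublet_rate` | 0.10 | high-load 10x capture (~16k cells loaded) |
| `dead_rate` / `ambient_rate` | 0.15 / 0.20 | realistic raw-matrix composition after loose barcode calling |
| `umi_logmean` / `umi_logsd` | 8.5 / 0.5 (natural log) | live median ≈ 4.9k UMIs, matching ~5k-cell, 60k-reads/cell captures |
| `dead_umi_scale` | 0.1 | dead cells retain ~10% of transcripts |
| `mito_live_beta` / `mito_dead_beta` | Beta(2,48) / Beta(9,21) | mito fractions ~4% (live) vs ~30% (dead) |
| `dual_tra_prob` / `dual_trb_prob` | 0.15 / 0.065 | midpoints of the reported 10–19% and 6–7% ranges |
| `chain_dropout` | 0.05 | V(D)J capture failure per chain |
| `n_genes_total` | 500 | see below |

Live cells draw a UMI total from a lognormal, a mito fraction from a Beta, a
binomial mito UMI split, and a multinomial allocation over a fixed
Dirichlet-drawn expression profile (plus a 13-gene mitochondrial block and a
few real TCR/BCR segment symbols so the gene mask has targets). Doublets are
the element-wise sum of two independent live cells with the union of their
chains; dead cells scale the UMI total down and draw mito from the dead
Beta; ambient droplets draw a low UMI total against the pooled profile.
Chains are dropped independently per chain before emission as productive,
full-length, high-confidence contigs. All randomness flows from one
`numpy` Generator seeded by `SimConfig.seed`, so identical configs give
byte-identical written outputs.

**What the simulator does not model** — and hence what passing tests do not
establish about real data: ambient *contigs* (contamination of the V(D)J
library itself, beyond an optional low-confidence injection knob), clonal
expansion and shared clonotypes, γδ T cells, empty-droplet ambient profiles
that differ from the cell profile, batch effects, and any realistic
gene-gene covariance. With only 500 genes, the 200-gene cell floor and
3000-gene ceiling are effectively inert on simulated data; those rules are
exercised against hand-built matrices instead. The simulator validates the
*thresholding logic*, not contig calling.

## Problem sizes

The bundled tests and the acceptance script run the default 2000-droplet
simulation for the end-to-end checks, 6000 droplets for the group-statistics
check (so every compared group holds ≥ 100 barcodes), and 10,000 droplets
for the structural-impossibility check; the whole suite completes in well
under a minute on one CPU.

## Known limitations

- The method presupposes sorted αβ T cells; barcodes without TCR chains are
  not necessarily empty in mixed-population captures, and the group-0
  interpretation (dead-enriched) would not transfer.
- Homotypic doublets of small cells can sit below the upper threshold and
  carry ≤ 2 detected chains; they are invisible to both the structural rule
  and the UMI window, exactly as for expression-based doublet callers.
- The lower threshold assumes a bimodal (ambient vs cell) log-UMI histogram;
  heavily pre-filtered ("filtered" Cell Ranger output) matrices may be
  unimodal, in which case the floor fallback applies and only the upper
  threshold acts.
- `filtered`-style contig tables are the expected V(D)J input; with `all`
  contig tables the counting rule's high-confidence requirement matters
  materially and should not be relaxed.
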