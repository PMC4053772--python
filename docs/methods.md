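# Methods

## Scope and data model

`prc1map` consumes the *outputs* of a standard ChIP-seq/RNA-seq primary
pipeline — per-factor, per-replicate peak calls (ENCODE narrowPeak or
BED6), a gene annotation (GTF or BED12) and per-gene read-count tables —
and produces candidate PRC1 target-gene tables, architecture
classifications, two-sample comparisons and expression-integration
summaries. Read alignment, duplicate removal, peak calling and RNA
quantification are out of scope.

All coordinates are held 0-based half-open (BED convention); GTF is
converted on read and back on write. Genes are represented by their
outermost span, so the TSS is the 5'-most annotated base; multi-isoform
structure below gene level is not modelled. Overlap between intervals
means ≥ 1 shared base unless a minimum overlap is requested.

## Co-occupancy compilation

Replicate peak calls for one factor/sample are merged either by **union**
(per-base union, joining gaps ≤ `gap`; the default, since pooling
replicates sharpens site definition more than demanding joint
reproducibility) or by **intersection** (regions retained only where peaks
from ≥ 2 replicates overlap, reported as the merged span of the mutually
overlapping peaks — deliberately the peak-level span, not the trimmed
shared bases, so a site keeps its full extent). Binding regions from all
factors are then pooled and merged with `link_gap` (default 1,000 bp) into
candidate spans; a span is a co-occupancy site iff the overlapping factors
include at least one CBX-class and one RING-class protein plus H3K27me3.
Factor→class mapping is configuration (a registry in the track manifest),
so additional PRC1 components can be added without code changes.

`link_gap` has no measured counterpart in the data this models; 1 kb joins
peaks of the same binding event called at slightly different positions by
different antibodies without bridging distinct loci, and it is exposed as
a parameter. Foothill filtering (dropping member peaks below a fraction of
the site's maximum score) is available but off by default: weak flanking
peaks are part of the binding body's structure, not noise. A site that
stops satisfying the criterion after filtering is flagged `rejected`
rather than dropped.

## Target assignment and architecture

Each site is assigned to the gene whose TSS is nearest its midpoint
(summit of the strongest member peak optionally), with two exceptions:

- a site overlapping both a coding and a noncoding gene body goes to the
  coding gene regardless of TSS distance;
- a site overlapping the bodies of ≥ 2 genes that lie within
  `2 × end_window` of each other is declared **AMBIGUOUS** for all of
  them. The nearest-TSS gene owns the site; co-members reference it with
  shared ownership noted, so site conservation (every site in exactly one
  owner or the unassigned sink) still holds.

Assignment distance is uncapped by default — genuine Polycomb domains sit
hundreds of kb from the nearest TSS — but every distance is reported so
users can filter. Sites on chromosomes without annotation land in an
explicit unassigned sink.

Architecture classification per gene uses `end_window` (default 10 kb, the
conventional promoter-proximal range) around TSS and TES:

- sites within the window at **both** ends → `BOTH_ENDS`;
- sites all lying within the gene body (≥ `body_overlap_fraction` of the
  site inside, default 0.5) and away from both ends → `BOTH_ENDS /
  INTERNAL`. This is a deliberate design choice: purely internal peak
  clusters belong with the both-ends group of complicated profiles, since
  a TSS/TES fallback would mislabel them by a coin-flip of distances;
- only a TES cluster, or no clusters with the TES strictly nearer →
  `TES_ASSOCIATED`; otherwise `TSS_ASSOCIATED`.

`BOTH_ENDS` subdivides into `FLANKING_DISCRETE` (no site overlaps the
body), `INTERNAL`, or `DISTRIBUTED`. Genes shorter than `2 × end_window`
are classified with the window shrunk to half the gene length and logged,
because the TSS/TES distinction is genuinely debatable there.

Spacing regularity of a peak array is `max(0, 1 − CV)` over successive
summit gaps, with CV the population standard deviation over the mean;
it is a summary statistic, not a periodicity test, and is reported only
for ≥ 4 peaks.

## Expression integration

A gene is **active** when its read count reaches the threshold (default
10) in *every* replicate — the strict reading of a per-duplicate
threshold; a sum-based mode is available. Counts are raw per-gene mapped
read counts; no length or depth normalisation is applied, and the report
header records this. Targets without an expression record are counted
silent with a warning. The promoter H3K4me3 flag uses a ±2 kb TSS window
(conventional; configurable).

## Two-sample comparisons

Strain comparison is exact set arithmetic on gene ids (a Venn of target
lists). Condition concordance is coordinate-level and deliberately
descriptive: reciprocal site-overlap fractions plus the median
matched-site ratio of maximum member-peak scores. No significance testing
is attached — the claim being checked (locations preserved, density
reduced) is qualitative, and differential-binding statistics are out of
scope.

## Synthetic data generator

The generator plants a complete labelled landscape:

- **Layout.** Genes occupy non-overlapping territories on 3 synthetic
  chromosomes: target genes 30–46 kb long with 55 kb clearance on each
  side (so every planted site is provably nearest its own TSS), background
  genes 2–40 kb with 8 kb clearance. Coordinate space grows with gene
  count (~hundreds of Mb); since no sequence is generated this costs
  nothing, and a full study-scale dataset generates in under a second.
- **Targets.** Category mix defaults to 0.66 TSS / 0.155 TES / 0.18
  both-ends (flanking:internal:distributed = 0.3:0.2:0.5), with the
  remaining 0.5% planted as ambiguous constructs — pairs of coding genes
  5 kb apart under one spanning peak cluster. Strain sharing defaults to
  685:301:414 (shared : A-only : B-only), so 1,400 planted loci reproduce
  the headline 986/1,099 strain totals exactly. Site centres keep ≥ 20%
  clearance from the end-window boundary, so planted categories are
  recoverable by construction at default noise.
- **Peaks.** Each bound locus draws a factor subset (all five PRC1
  factors 60% of the time, otherwise ≥ 1 CBX + ≥ 1 RING), per-replicate
  summit jitter ~ Normal(0, 50 bp), per-peak lognormal score noise around
  a Gamma-distributed locus mean, an H3K27me3 block covering each site,
  H3K4me3 at flagged promoters, foothill peaks (15% of the local maximum)
  at 20% of sites, and evenly spaced summit arrays at 30% of
  internal/distributed loci. Background decoys (lone factors, or marks
  without PRC1) exercise specificity without satisfying the criterion.
- **Counts.** Negative binomial (dispersion 0.1), mean 100 for active and
  1 for silent genes, clipped so planted activity labels are exactly
  recoverable under the ≥ 10-in-both-replicates rule (this is a threshold
  semantics fixture, not a model of library depth). Active targets are
  28% of each strain's targets; actives overall are 47% of all genes;
  38% of targets get promoter H3K4me3 (all active ones plus silent
  fill-in).
- **Senescence.** The senescent condition copies strain-B peaks with
  unchanged intervals and scores × 0.6 × lognormal(0, 0.05).

What the generator does **not** model: read-level noise, peak-shape
variation, mappability artefacts, copy-number effects, annotation errors,
or genuinely ambiguous intergenic assignment beyond the planted
constructs. Passing recovery tests therefore demonstrates the
correctness of the interval logic, the classification rules and the
bookkeeping — not robustness to the messiness of real ChIP-seq, where
target lists required manual curation.

## Numerical choices and determinism

All randomness flows through one `numpy` PCG64 generator seeded by the
user; fixture files and report files are byte-identical under a fixed
seed (the run log, which echoes configured paths, is the only exception).
Interval merging treats a separation of exactly `gap` bases as joined.
Nearest-TSS ties prefer coding genes, then the lexicographically smallest
gene id. Category proportions are reported over non-ambiguous calls (they
sum to 1) with the ambiguous share reported separately.

## Problem sizes

The bundled tests run the full chain at 2,500 genes / 1,000 planted
targets (the default configuration) plus many small randomized fixtures;
the acceptance script uses 3,000 genes / 1,400 planted targets. Both
complete in seconds on one CPU.

## Known limitations

- Exact reproduction of manually curated target lists is not a goal; the
  deterministic rules here approximate, but cannot recover, hand edits.
- The ambiguity rule (bodies within `2 × end_window` under one cluster) is
  one minimal operationalisation of "closely linked"; real loci may need
  locus-specific judgement.
- Whether TES-proximal fractions should be computed from summits or
  region midpoints is unresolved in the field; midpoint is the default
  and summit mode is provided.
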