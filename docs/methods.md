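# Methods

## Coordinates and interval algebra

All intervals are 0-based half-open (BED convention). "Overlap by ≥1 bp"
means `a.start < b.end and b.start < a.end`; bookended intervals do not
overlap and are never merged. Two-condition peak merging replaces every
connected component of overlapping peaks by its envelope `[min start,
max end)` and records which condition(s) contributed. The midpoint of an
interval is `⌊(start + end)/2⌋`, so fixed-width resizing is deterministic;
a window that would cross a chromosome edge is shifted, preserving its
width. Peaks are strandless; strand enters only through promoter windows
and gene TSS definitions.

## Coverage scores

A region's coverage score is the number of reads overlapping it by ≥1 bp
(intersect semantics — a read spanning two regions counts once in each),
normalized as

    score = raw × 10⁶ / library_size × 10³ / length_bp

i.e. reads per kilobase of region per million mapped reads. Histone-mark
assays are scored over fixed 800 bp windows centred on the region midpoint
and normalized by that fixed width, which makes length normalization a
constant factor and keeps rank order equal to raw counts; the fixed width
is also used as the length for the library normalization (with all-equal
lengths the choice cannot affect ranking or thresholds). A zero library
size is an error, never a silent NaN. No duplicate removal, fragment
extension or input subtraction is applied.

## Region classification

Fold changes use normalized scores with a pseudocount (default 1 on the
normalized scale): `fc = (x₊ + c)/(x₋ + c)`. The cascade is: Group I iff
`tf_fc ≥ 4`, `hist_fc ≥ 4` and induced histone **raw** count ≥ 50 (an
absolute floor is naturally a raw-read criterion); Group II iff `tf_fc ≥ 4`
but not Group I; Group III iff `max(fc, 1/fc) ≤ 2`. Regions between the
no-change band and the 4-fold threshold remain `unclassified` — the three
groups need not partition all regions, and an explicit remainder is the
honest reading. All thresholds are configurable (`thresholds.*` in the
config). The global summary reports peak counts per condition, the Venn
partition of merged regions by contributing condition, and the mean
coverage fold. The mean fold is the arithmetic mean of per-region
pseudocounted ratios (mean of ratios, not ratio of means); note that on
regions with de novo binding the uninduced score is only background, so
this mean is dominated by such regions when they are present — the planted
8× benchmark therefore uses regions bound in both conditions.

## Gene assignment

Cascade per region: (1) overlaps any promoter interval → `promoter`,
linked to the promoter's gene(s); (2) else overlaps a gene body →
`intragenic`, linked to every overlapped gene; (3) else `intergenic`,
linked to the nearest gene on each genomic side with edge-to-edge distance
≤ 50 kb (inclusive; 0 when touching; equidistant ties keep both — they are
different flanks); (4) otherwise `unassigned`. Promoter precedes gene body
because promoter windows can lie inside another gene's body. "5'/3'
flanks" are chromosome-coordinate sides, not transcript-relative, because
peak strand is undefined. Per-group distribution fractions use all regions
of the group as denominator, including unassigned ones.

## Differential expression

Columns are quantile-normalized (rank-average ties). Each probe is tested
with an equal-variance two-sample t-statistic whose per-probe variance is
shrunk toward a common prior by empirical Bayes: a scaled-F model is
fitted to the sample variances on the log scale (digamma/trigamma method
of moments, Newton inversion of the trigamma function), giving prior
degrees of freedom d₀ and prior variance s₀²; the moderated statistic uses
`s̃² = (d₀s₀² + d·s²)/(d₀ + d)` with d + d₀ degrees of freedom. This is
the standard microarray treatment for triplicate designs, where raw
per-probe variances with 4 degrees of freedom make a plain t-test lose
substantial power (~80–85% recovery of a 2-fold effect at noise sd 0.1,
versus ≥95% with moderation); the plain test remains available via
`moderation=False`. P-values are Benjamini–Hochberg adjusted; a probe is
significant iff adj-p ≤ 0.05 **and** linear fold change > 1.2, applied in
both directions by default (down-regulation passes below 1/1.2;
`de.two_sided_fc: false` restricts to up). Zero-variance, zero-difference
probes carry no evidence and get p = 1. When several probes map to one
gene, the probe with the smallest adjusted p represents the gene. The
optional detection-p matrix drops probes undetected (p > 0.01) in any
sample; absent matrix keeps all. Group-wise expression response reports
the mean *linear* fold change of array-significant genes linked to each
group (a shared gene contributes to every group that claims it) and
compares groups with a two-sided Mann–Whitney test on log2 fold changes —
a rank test is robust to the heavy-tailed fold distribution. The target
set is the plain intersection of a group's gene set with the significantly
up-regulated genes, with provenance counts kept.

## Co-binding

`cobind_fraction` reports the count and percentage (rounded to 1 decimal;
the raw fraction is kept unrounded) of query peaks sharing ≥1 bp with any
reference peak; an empty query leaves the percentage undefined rather than
raising. Three-way comparisons merge all three sets into atoms (connected
overlap components of the union) and count atoms per membership class;
atom counts, not input-peak counts, are reported, because one wide peak
overlapping two peaks of another set is a single shared site. No overlap
significance test is computed.

## Signature clustering

Samples are clustered on the signature genes present in the matrix
(missing genes are listed; fewer than two present is an error): distance
1 − Pearson correlation across signature genes, average linkage, cut at a
user-chosen k (no automatic selection; correlation distance makes the
result invariant to per-sample affine rescaling). Node stability is an
ordinary bootstrap: signature genes are resampled with replacement
`n_boot` times (features, not samples), the tree is rebuilt, and each
original internal node is scored by the fraction of replicates containing
a node with the identical sample set. With `n_boot = 0` the result is
fully deterministic. Cluster summaries report sizes, the mean of a named
marker gene per cluster with its argmax cluster, and, per categorical
metadata column, the count and fraction of each label's total falling in
each cluster (fractions sum to 1 per label). Cross-species application of
a signature is a user-supplied id-map concern; no ortholog mapping is
guessed.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed); truth tables are
written beside the fixtures so tests never reach into generator internals.

* **Annotation** — non-overlapping stranded gene bodies (2–8 kb) separated
  by ≥6 kb on equal chromosomes; promoters are −1000/+200 bp around the
  TSS, a conventional window recorded in config.
* **Binding experiment** — defaults plant 173/506/276 regions in Groups
  I/II/III (the study's 1734/5056/2761 at 1:10 scale) of 400 bp at 8×
  TF and 8× histone induced fold; uninduced means 30 (TF) and 50
  (histone) reads per region put the induced Group I histone mean at 400,
  comfortably above the 50-read floor. Half of the induced regions are de
  novo (no uninduced TF binding, absent from the uninduced peak call).
  Read counts are Poisson around the planted means — the minimal adequate
  noise model for sequencing counts — and every (assay, condition) library
  is filled to a fixed depth (default 10⁶ reads) with uniform background
  over a 200 Mb two-chromosome genome, so both conditions have equal
  library sizes and the background density (~4–5 reads/kb) matches a real
  library's genome-wide scatter; a proportionally smaller genome would
  concentrate background unrealistically and dilute planted folds. Truth
  group labels are derived from the planted means, so degenerate
  parameters (fold 1) honestly plant only Group III. When an annotation
  is supplied, Groups I/II are placed intergenically next to private
  target genes and Group III at promoters, and the intended target gene is
  recorded. Pre-existing CEBPA co-binding is planted at per-group rates
  (defaults 0.20/0.26/0.55, the study's observed proportions).
* **Expression matrix** — Gaussian log2 intensities (baseline N(8, 1.5),
  noise sd 0.1, 3 samples per condition) with planted up-regulated genes
  shifted by 1 log2 unit; these are the calibration conditions the DE
  benchmarks state. The pipeline plants the Group I target genes plus
  extra random genes so the derived signature has a known truth.
* **Labeled cohort** — per-cluster mean profiles over the signature genes
  drawn N(0, 1) and scaled by `separation` (0 ⇒ no structure), unit noise,
  background genes without cluster signal, an optional marker gene with
  cluster-specific levels, and categorical labels drawn per cluster from a
  configurable probability table.

The generators do **not** model read mappability, GC or fragment-length
effects, duplicate reads, peak-caller behaviour, probe-level array
artifacts, batch effects, or cross-platform probe mapping. Passing tests
therefore demonstrate that the pipeline's arithmetic and decision rules
are correct and recover planted structure under Poisson/Gaussian noise —
not that the thresholds are optimal for any particular real dataset.

## Problem sizes and numerical choices

The default end-to-end run uses 5000 genes on a 120 Mb genome, 955
regions, libraries of 3×10⁵ reads, 3 vs 3 arrays and a 60-sample cohort;
the classification benchmark uses 3000 regions at 10⁶-read depth, the DE
benchmarks 5000 probes (planted) and 50×1000 probes (null), the clustering
benchmark 10–20 cohorts of 40 samples. These sizes make every planted
effect detectable at the stated thresholds while a full run stays in the
seconds range. Ties in quantile normalization take the average of the
reference quantiles they span; equidistant flank genes are both kept;
region ids are assigned in (chrom, start, end) order; JSON and TSV outputs
are written with fixed float formats and sorted keys so a re-run on the
same inputs is byte-identical.

## Known limitations

Hard thresholds, not a statistical differential-binding model (no
dispersion estimation or FDR over regions) — deliberate, as the
classification contract is threshold-based. Histone library normalization
uses the fixed 800 bp window rather than the native region length (moot
for ranking, stated for completeness). The no-change band and the
mean-of-ratios convention are explicit config choices where the method
leaves the definition open. Bootstrap node support is plain reproduction
frequency, not a multiscale-corrected approximately-unbiased p-value.
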