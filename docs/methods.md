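# Methods

This note documents the models and procedures implemented in
`coexmap`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical conventions.

## Read counting

**Unit of assignment.** Each SAM record that is mapped, primary and
non-supplementary is one counting unit; paired mates are counted
independently. Reads with `NH > 1` go to `not_unique`, reads below
`min_mapq` (default 0, i.e. disabled) to `low_quality`. The
reference-consuming CIGAR operations (M/=/X and D) define the read's
aligned blocks; N gaps split blocks; insertions and clips are ignored.
Internally all coordinates are 0-based half-open; GTF (1-based
inclusive) and SAM POS (1-based) are converted at the parse boundary.

**Overlap-size mode (default).** The overlap of a read with a gene is
the number of aligned reference bases falling inside the gene's exonic
union (at transcript level: the transcript's own exons). The candidate
with the strictly largest positive exonic overlap receives the read.
Ties are *always* ambiguous — never broken by feature ID — because an
evenly split read carries no evidence for either gene. If every exonic
overlap is zero, the read is assigned to the intron counter of the gene
with the largest intronic overlap (any positive intronic overlap
qualifies; the choice of threshold is deliberately permissive since
exon evidence always wins first). Otherwise it is `no_feature`.

**Union mode.** For benchmarking compatibility, `htseq_union` ignores
overlap sizes: exactly one exonically overlapped gene receives the
read; two or more make it ambiguous; introns are not features.

**Strandedness.** Strand is parsed and stored but ignored during
assignment (an unstranded library is assumed).

**Transcript multi-counting.** Transcripts of one gene usually share
exons, so a per-transcript map built with strict disambiguation would
leave most transcripts empty. With
`transcript_ambiguous_multicount`, a read exonically overlapping *k*
transcripts increments all *k* and is not placed in ambiguous. The
documented consequence: transcripts from the same gene show inflated
mutual co-expression, which consumers of per-transcript maps must keep
in mind.

**Conservation.** At gene level, feature counts + intron counts +
special counters add up exactly to the number of primary mapped reads
processed; this is asserted in tests and makes silent read loss
impossible.

## Normalization and filtering

Expression of feature *f* in sample *s* is
`counts[f,s] / Σ_f counts[f,s]` — the fraction of the sample's total
*feature* count. Intron rows and the special counters are stored
outside the count matrix, so unassigned reads never enter numerator or
denominator. Length-corrected units (FPKM/TPM) are intentionally not
offered: correlation across samples is computed per feature, where a
fixed per-feature length factor cancels, and total-count normalization
keeps the pipeline auditable. The known cost is a compositional bias
toward positive correlation when a few features dominate a library.

The expression filter keeps a feature if it has ≥ `min_reads` (default
10) raw reads in at least `min_sample_fraction` (default 10%) of
samples, with boundaries inclusive. Filtering operates on raw counts
(the rule names reads, not fractions) and is applied *after*
normalization totals are computed: retained rows keep fractions
computed over all features, so filtered matrices no longer column-sum
to 1. Sample QC (≥ 10 million reads, ≥ 60% mapped, boundary values
pass) gates on externally supplied per-sample statistics; alignment
itself is out of scope.

## Sample redundancy weights

Public repositories over-represent popular sample types (cell lines,
stem cells); treating 50 near-identical libraries as independent
observations would let one condition dominate every correlation. The
weight of sample *i* is `w_i = 1/n_i`, where
`n_i = |{j : S_ij ≥ τ}|` counts samples whose expression column
correlates with sample *i* at or above τ (self included, so `n_i ≥ 1`).
Default τ = 0.95, configurable. This simple threshold-count inversion
has an exact, testable consequence: appending a duplicate of a sample
and re-weighting reproduces the original correlation matrix to within
1e-12 (duplicate-sample neutrality), which the suite asserts.

## Weighted correlation, ranks, mutual rank

The weighted Pearson correlation uses weighted means and weighted
(co)variances and is invariant to rescaling all weights. Correlations
are computed on normalized fractions without log transform by default;
`log_transform` applies `log10(x + 1e-8)` for users who prefer
variance stabilization.

All N(N−1)/2 correlations are computed as one dense matrix product;
full N×N correlation and rank matrices are kept in memory. This is the
correctness contract for desk-scale maps (N up to a few thousand;
~2.4 GB at N = 10,000 is the practical ceiling). Each feature's
partners are ranked by r descending with ties broken by neighbor ID
ascending so runs are bit-reproducible; forward ranks per feature are a
permutation of 1..N−1. The mutual rank of a pair is the arithmetic
mean of the two directional ranks (a geometric-mean option is provided
for comparability with databases that use it). Neighbor lists are
sorted by MR ascending (ties: r descending, then ID); negative lists by
r ascending. Serialized maps store the top `k_top` and bottom `k_neg`
entries per feature (defaults `max(⌈0.05N⌉, 1500, 50)` and 1500,
clamped to N−1 — large enough for every downstream query) plus a
key-value metadata sidecar.

Constant feature rows are an error by design: they should have been
removed by the expression filter, and silently skipping them would
desynchronize ranks.

## Scrambled-null calibration

The null model permutes each feature row independently across samples
with a seeded generator, preserving every marginal while destroying
covariance (a whole-matrix `global` shuffle is available). Positives
are weighted correlations of seeded random pairs from the true matrix;
negatives are a same-size sample from the scrambled matrix. The ROC
sweeps the union of observed values; AUC is the trapezoid over
(FPR, sensitivity) with (0,0)/(1,1) endpoints. FDR is computed from
rates — i.e. with both populations rescaled to equal size — and then
interpolated exactly as precision is in precision–recall curves: each
threshold reports the best FDR achievable at an equal-or-more-lenient
threshold, making FDR monotone in the threshold. The reported
operating point is the first threshold, sweeping strict → lenient,
whose sensitivity reaches the requested level (default 95%).

**Two positive-set readings, both implemented.** With
`positives="all"`, every sampled true-matrix correlation is a
positive. This answers "is there any structure at all": on data where
most pairs are genuinely uncorrelated the AUC *must* sit near 0.5 at
desk-scale sample sizes, because a true r ≈ 0 is indistinguishable
from a scrambled r ≈ 0 — and the suite asserts exactly that on
pure-noise data. With `positives="top5"`, only the strongest 5% of
sampled true correlations count as positives, mirroring a production
map that stores each feature's top-5% partner lists, so the ROC
measures how separable the *stored* co-expression values are from
scrambled values. On planted-module data this reading yields AUC near
1 and a meaningful (FDR, threshold) pair at 95% sensitivity; the
example and acceptance script print both readings side by side.

## Queries and enrichment

"Strongest co-expressed" means lowest mutual rank (ties: higher r,
then ID). A single-feature report returns the top 50 genes, the top
25 partners appearing in a user-supplied transcription-factor ID list,
and the top 20 enrichment terms computed over the top 1500 partners
whose correlation is individually significant at `α/N` (two-sided
t-test on `t = r√((n−2)/(1−r²))` with n−2 degrees of freedom, n =
number of samples; using Σw as an effective n is deliberately not the
default — the plain test is transparent and the cutoff arithmetic of a
Bonferroni α/N rule presumes it). Enrichment is the hypergeometric
upper tail P(X ≥ k) over the map's feature universe as background,
Bonferroni-corrected across the terms with at least one background
member. DAVID-style remote services are replaced by this local stage;
users supply annotation sets as GMT.

Seed lists aggregate by `mean_rank` (mean forward rank of each
candidate across seeds; candidates absent from a stored list contribute
rank N) or `vote` (number of seeds whose top-5% list contains the
candidate). Partner-list overlap between two features intersects their
top-5% lists after removing the pair itself, with the list size taken
from the full map size N — so two identical profiles overlap at
fraction 1.0, and a 114,936-feature map compares 5,747-entry lists.

## Synthetic data

`gen_module_matrix` draws log-intensities `μ_g + Σ_m L_gm f_ms + ε`
with per-module latent factors `f ~ N(0, factor_sd)`, gene noise
`ε ~ N(0, noise_sd)` and baseline `μ_g ~ N(0,1)`, then converts each
sample through a softmax to multinomial counts at a fixed library size
— coupling genes through the total-count constraint exactly where the
normalization operates. Anti-correlated pairs load ±f on a shared
factor; duplicated samples are exact column copies for exercising the
redundancy weights. The default spec (5 modules × 20 genes, 100
background genes, 60 samples, factor_sd 1, noise_sd 0.5, library
100,000) gives within-module correlations around 0.7–0.85 — strong but
noisy modules, the regime the method is meant for. What it does *not*
emulate: gene-length and GC bias, count overdispersion beyond the
multinomial, batch structure, or correlated background processes; a
passing suite shows the machinery is correct under the stated
generative model, not that real tissues behave like it.

`gen_filter_matrix` plants exact pass/fail splits for the expression
filter (passing features get ≥ min_reads in exactly the minimum
qualifying number of samples — the boundary case on purpose).
`gen_toy_alignments` emits GTF/SAM text for hand-written or randomized
gene/read layouts together with expected counts from an embedded
straight-line assigner that works on sets of integer base positions —
deliberately a second, independent implementation of the assignment
rules, kept free of interval arithmetic so it can disagree with the
production counter when one of them is wrong.

All generators are pure functions of (spec, seed); the module
generator re-draws with seed+1 (deterministically, up to 10 attempts)
in the unlikely event of a zero-variance count row.

## Problem sizes used in the checked runs

The test suite and the acceptance script run the filter censuses at
their full printed sizes (63,678 and 215,170 features × 100 samples),
counting-oracle agreement on 100 random fixtures (≤ 50 reads, ≤ 4
genes, both modes), map-oracle agreement on 50 random matrices with
N ≤ 30, and calibration/recovery at the default ModuleSpec with 10,000
sampled pairs. These sizes were chosen so the whole suite completes in
seconds while every check still exercises the full code path.

## Known limitations

- Single-end semantics; mate pairing, duplicate marking and UMIs are
  out of scope.
- Counting is unstranded; stranded libraries lose the strand signal.
- The in-memory map targets desk-scale N; a streamed/blocked builder
  for six-figure feature counts is not included.
- BAM/CRAM require external conversion to SAM text (`samtools view`).
- The t-test p-values treat samples as independent after weighting;
  the weights correct the correlation estimate, not its null
  distribution, so significance near the cutoff should be read
  conservatively.
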