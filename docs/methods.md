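# Methods

`oomics` re-implements, as a tested library, the computational analysis
used to characterise the multi-omic state of growing mouse oocytes in
conditional knockouts of the H3K9 methyltransferases EHMT1/EHMT2: broad
H3K9me2 domain calling from windowed ChIP-seq, CpG-tiled differential
DNA methylation, negative-binomial differential expression with ERV
quantification, moderated-t differential protein abundance, and the
cross-omics overlap/rank/correlation layer. All stages run end to end
on synthetic data with planted truth, so every engine has a
parameter-recovery test.

Coordinates are 0-based, half-open (BED convention) throughout.

## ChIP-seq domain calling

The genome is tiled into consecutive, non-overlapping 10-kb windows (a
terminal tile is kept when it is at least half the window width).
Per-window signal is RPKM, `count / ((width/1000) x (library/1e6))`;
log2RPKM uses a pseudocount of 2^-4 so that zero-count windows sit far
below any plausible threshold. Windows whose mean input RPKM exceeds a
threshold in any replicate set of input libraries are masked as mapping
artifacts (strict `>`; the replicate-set mean, rather than any single
library, triggers the mask). Enriched windows are those with mean
log2RPKM of the reference ChIP samples strictly above a threshold;
called windows separated by at most 10 kb merge into domains, the gap
being absorbed into the domain span. A matched null is built by
sampling windows uniformly without replacement and applying the same
merge. Composite "probe trend" profiles rescale each domain to 20
interior bins plus five 1-kb flank bins per side, with per-bin values
being overlap-weighted window means averaged over domains.

**Thresholds and genome scale.** When reads are distributed over
windows that tile the whole genome, the expected background RPKM is
`1e9 / genome_length`, independent of depth and window width. The
default absolute thresholds (log2RPKM > 2.5 for enrichment, RPKM > 6
for artifacts) are calibrated to a mammalian-scale genome (~2.7 Gb,
background RPKM ~0.4). On the desk-scale synthetic genome (3 x 5 Mb,
background RPKM ~67) the pipeline therefore uses scale-appropriate
values: the enrichment threshold is placed at the median log2RPKM plus
half the expected fold in log2 units, and the artifact threshold at 3x
the median input RPKM. The planted-artifact recovery test instead uses
a thin 600-Mb single-chromosome genome, where background RPKM <= 2 and
the absolute RPKM > 6 rule is meaningful as stated.

Promoters are the strand-aware `[TSS-500, TSS+500)` interval;
expression classes use FPKM cuts at 0.1 and 1.0, closed on the left
(0.1 -> "low", 1.0 -> "high").

## CpG-tiled differential methylation

Tiles are consecutive groups of exactly 100 CpGs (equal CpG content,
variable bp span; the trailing partial group is dropped; the span runs
from the first CpG to one past the last). A tile is analysed only if
every sample has >= 10 observed cytosines in it. The tile-level
percentage is, by default, the unweighted mean over covered CpGs of
per-CpG methylation percentages ("per-base-mean"); a coverage-weighted
"pooled" mode is available for sensitivity analysis.

The differential test is a beta-binomial likelihood-ratio test on
per-replicate (methylated, unmethylated) tile totals, with mean m and
dispersion phi parameterised as `a = m(1-phi)/phi`,
`b = (1-m)(1-phi)/phi` (phi = 0 is pure binomial). Dispersion is
estimated by method of moments from the group-conditional Pearson
chi-square and floored at zero. Because a duplicate design leaves only
~2 residual degrees of freedom per tile, the per-tile estimate is far
too noisy to plug into a chi-square reference: measured under the null
(2,160 tiles, phi = 0.02, 30x coverage, 2 vs 2), per-tile estimation
gives an empirical size of 0.077 at alpha = 0.05. The default
therefore pools the moment estimate across all tiles
(`dispersion_shrink = 1.0`), which restores calibration (size 0.053,
and Kolmogorov-Smirnov uniformity of null p-values at phi = 0); a
partially or fully per-tile estimate remains available through the
parameter. With ~3,000 observations per tile at 30x, power for a
30-point shift is essentially 1.

DMRs require a Benjamini-Hochberg adjusted p below alpha (default
0.05) *and* an absolute difference of at least 20 percentage points —
the original cutoffs are not published, and 20 points matches the
convention the study applies to its external hypomethylated-region
comparison. Same-direction DMR tiles that are adjacent, or separated by
at most one intervening tile, merge into differentially methylated
domains; hyper and hypo never merge. Domains are clustered across
genotypes (Ward linkage, Euclidean distance, tree cut at k = 2 within
each direction); the cluster whose single-knockout mean difference is
closer to the double-knockout column is labelled "common", the other
"unique". Ties break toward the lower cluster index, making the
labelling deterministic.

## Differential expression

Size factors are median-of-ratios over genes with nonzero counts in
all samples, rescaled to geometric mean 1. The per-gene model is NB
with a method-of-moments dispersion floored at 1e-8 and averaged 50/50
with an `a0 + a1/mean` trend fitted across genes — a deliberately
simpler stabiliser than full empirical-Bayes machinery; the engine is
validated by its operating characteristics (null false-discovery
fraction, planted-effect recovery, exact group-swap antisymmetry)
rather than numeric identity with any reference tool. The Wald
statistic is the log2 ratio of size-factor-normalised group means over
its delta-method standard error; two-sided normal p-values are BH
adjusted. DEG calls additionally require |log2FC| >= 1.5 (the
boundary is included).

Down-sampling to a common depth (default 1.9 M reads) draws a
multivariate hypergeometric sample per library, conserving column
totals exactly; shallower libraries pass through with a warning. ERV
expression is the percentage of total library counts falling in ERV
intervals, after removing ERVs whose end-to-start gap to the nearest
gene is strictly less than 2 kb (an ERV at exactly 2 kb is retained):
read-through from genic transcription would otherwise masquerade as
derepression. Union DEGs are clustered (Ward/Euclidean on
row-standardised log2 expression, k = 3) and the clusters labelled
down-in-both / up-in-both / up-in-double-KO-only by matching cluster
mean fold-change vectors to the three reference patterns with the
minimum-cost assignment.

## Proteome

TMT reporter log2 signal-to-noise matrices are median-aligned per
channel. The differential test is an empirical-Bayes moderated t: the
prior (d0, s0^2) is estimated by matching the first two moments of
log s^2 (Newton inversion of the trigamma equation, 50 iterations,
tolerance 1e-10); the posterior variance `(d0 s0^2 + d s^2)/(d0 + d)`
gives a t statistic on d0 + d degrees of freedom. When the spread of
log s^2 does not exceed its chi-square expectation, d0 is infinite and
the test degenerates to a z-test against the pooled variance. Calls
gate on the *raw* two-sided p < 0.05 and |log2FC| >= 0.3 — raw rather
than adjusted p intentionally mirrors the published analysis and is a
documented deviation from common practice.

## Integration

Overlap enrichment compares hit rates of a query set against a random
background on a 2x2 table: two-tailed Fisher's exact test (two-sided
defined as the sum of all equally-or-less-likely tables), or a
chi-square without continuity correction that falls back to Fisher
whenever an expected cell is below 5; Bonferroni adjustment multiplies
by the caller's family size, capped at 1. Interval overlap means >= 1
shared base pair.

Barcode rank enrichment places the up- and down-regulated protein sets
within the transcript fold-change ranking: the "worm" is the set
density in a centred rectangular window of width 0.25 N, relative to a
uniform spread (baseline 1; the published display uses an unpublished
weighted moving average, so acceptance is property-based). Each set is
tested with a one-sided normal-approximation rank-sum test in its
nominal direction, and Spearman's rho is reported over paired
transcript/protein effect sizes. Methylation-expression coupling is
Spearman's rank correlation between per-gene methylation differences
and expression log2FC (>= 4 pairs required; constant vectors are
rejected).

## Synthetic data

The generator defines the study conditions; every simulator is a pure
function of (configuration, seed).

* **Genome** — default 3 chromosomes x 5 Mb with a size knob. CpGs are
  laid down by geometric inter-CpG gaps: 0.008/bp background (the
  mammalian out-of-island density) and 0.08/bp inside CGIs. 400 genes
  with log-normal spans (median 10 kb) and random strands; 150 CGIs;
  60 ERVs of which half are deliberately placed within 2 kb of a gene
  and half at least 2 kb away, so the exclusion rule is always
  exercised.
* **ChIP** — multinomial reads over windows, weight proportional to
  window length times the enrichment fold (default 6) inside planted
  domains; input libraries are uniform except for planted artifact
  windows inflated 10x. Counts sum exactly to the library size.
* **Bisulfite** — per CpG and replicate, coverage ~ Poisson(30) and
  methylated counts ~ Binomial(coverage, p) with p ~ Beta at the group
  mean and dispersion phi (default 0.02, matching between-replicate
  scatter of oocyte libraries); planted tiles shift the mutant group
  mean by +/-30 points, clipped to [0, 100] with a warning.
* **RNA** — NB counts via gamma-Poisson (mean = size factor x
  baseline x 2^log2FC; dispersion 0.05); planted fold changes default
  to 90% up / 10% down, mirroring the strong derepression asymmetry of
  the knockout phenotype.
* **Proteome** — protein fold changes are built from the *normal
  scores* of the transcript fold-change ranks mixed with independent
  Gaussian noise; the mixing weight `2 sin(pi rho / 6)` makes the
  expected Spearman correlation equal the target (default 0.43) —
  exact for bivariate normal scores, and measured to hold within
  Monte-Carlo error at n = 2,933. Replicate intensities add
  N(0, 0.2) channel noise around the group means. (A direct
  "truth + scaled noise" construction cannot hit a prescribed Spearman
  target when the transcript vector carries heavy ties at zero; the
  rank-coupling construction sidesteps that while preserving the
  intended coupling semantics.)

What the generator does **not** emulate: read-level sequence content,
mappability structure, GC or length biases, bisulfite conversion
failure, TMT ratio compression, batch effects, and correlated
biological covariance between omic layers beyond the single
transcript-protein (and optionally methylation-expression) coupling.
Passing recovery tests therefore demonstrates the correctness of the
statistical machinery under the stated models, not robustness to the
full messiness of real libraries.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale problems chosen to give
stable statistics: 1,500 windows for domain recovery; ~2,150 100-CpG
tiles (one 5-Mb chromosome at 0.042 CpG/bp) for DMR calibration; 5,000
genes for the DE null and 2,000 for effect recovery; 3,000 proteins
for moderated-t calibration; n = 2,933 genes for coupling recovery
(the size of the shared transcript-protein universe in the study).
Scalar likelihood optimisations are bounded Brent with xatol 1e-10;
merge and clustering tie-breaks are fixed (stable sorts, lower index
first), making every pipeline output byte-reproducible for a given
configuration and seed.

## Known limitations

* The DMR engine is a re-implementation with documented behaviour, not
  a numeric clone of the original SeqMonk/edgeR internals (which are
  unpublished); agreement is established at the level of operating
  characteristics and a phi = 0 exact-test oracle.
* The NB engine omits outlier handling (Cook's distance) and
  independent filtering; the moderated t assumes a common variance
  model across both groups.
* Interval overlap uses any-overlap (>= 1 bp); no minimum-fraction
  rule is offered.
* The barcode worm uses a rectangular window; its absolute values near
  the extreme ranks depend on window truncation at the edges.
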