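# Methods

`lamshift` implements the computational workflow for studying NET-directed
gene repositioning during myogenesis: DamID log-ratio processing and LAD
calling in myoblasts (MB) and myotubes (MT), a randomization-test caller
for regions with differential lamina association (IP: interior-to-periphery,
PI: the reverse), microarray-style moderated differential expression,
position-expression concordance statistics, and equal-area shell
quantification of radial position in nucleus midplane images. Because the
original sequencing and array data are not packaged, a synthetic-data module
generates every input with planted ground truth, and the test suite scores
the pipeline by how well it recovers what was planted.

All genomic coordinates are 0-based, half-open (BED convention).

## DamID model and tracks

The resolution unit is the DpnI fragment: the interval between consecutive
GATC motif starts (`digest_gatc`). Per fragment and condition the package
holds two read counts, Dam-only and Dam-LaminB1, and forms

    r = log2((lamin * s_L + c) / (dam * s_D + c))

with pseudocount `c = 1` and library scale factors `s_L, s_D` that equalize
the two channel totals within a condition (neither is specified by standard
DamID conventions at this granularity; both are parameters). Fragments empty
in both channels get ratio 0 rather than missing so windows stay defined; a
`mask_empty` flag provides the alternative.

Two windowed statistics exist and are deliberately distinct:

- `running_mean` — the unweighted mean of per-fragment ratios whose
  midpoints fall in each window (100 kb window, 10 kb step by default).
  This is the statistic used for gene-level scores (`gene_delta`).
- `running_ratio` — counts are pooled over the window before the ratio is
  formed. At low coverage the per-fragment ratio is shrunk toward 0 by the
  pseudocount (at 0.5 reads/fragment the shrinkage eats ~70% of a 1.2 log2
  effect), whereas the pooled ratio is unbiased at any depth. The LAD and
  shift callers therefore operate on pooled windows.

`gene_delta` scores a gene as the MT minus MB mean ratio either over the
gene body or over the gene span extended symmetrically by 50 kb per side
("flank_100kb"); the extension is configurable since "a 100 kb window
surrounding the gene" admits several readings.

## LAD calling and sharing

LADs are segmented per condition from 10-kb pooled-ratio bins with a
2-state Gaussian HMM (hmmlearn, Viterbi path); the higher-mean state is LAD
provided its mean is positive. If the two states are closer than 0.2 log2
units or the fit fails, a threshold-at-zero fallback is used. Gaps under
30 kb are merged and LADs under 100 kb dropped (both configurable).
`lad_sharing` decomposes the union coverage of the MB and MT LAD sets into
shared / MB-only / MT-only by interval arithmetic.

## The IP/PI differential caller

The caller follows the published recipe — mean MT-MB differences of
log2(LaminB1/Dam) along a running 100-kb window, a 2-fold threshold
(|delta log2| >= 1), Fisher's exact test against randomized fragment sets
over 1,000 iterations, and rejection of candidates with p > 0.01 — with the
following concrete realizations, which the recipe leaves open:

1. **Window delta.** Pooled-count window ratios per condition, subtracted,
   then median-centered genome-wide (`center_delta=True`). The residual
   library-composition offset between conditions (up to ~0.07 log2)
   otherwise biases IP against PI sensitivity; the genome-wide median is a
   robust null estimate because most of the genome does not shift.
2. **Candidates.** Maximal same-sign runs of windows with |delta| >= 1; the
   extents of passing windows are unioned, and same-sign candidates closer
   than one window length are bridged, so a single noisy window cannot
   split a region.
3. **Boundary refinement.** Candidate boundaries inherit the 100-kb window
   smoothing, so each region is re-localized on 10-kb pooled-delta bins.
   Three estimators are computed per boundary — the penalized max-subarray
   edge (per-bin score `sign*delta - 0.6*cut`), an anchored maximum-
   likelihood edge (best step-fit with the far end fixed at the region
   midpoint), and the half-height crossing of the centered running window
   (a window centered on a step boundary averages half in-region, half
   flank) — and the per-boundary median is taken. Each estimator alone has
   ~5% heavy-tail failures of 50-135 kb at 0.5 reads/fragment; their
   failure modes are distinct, so the median suppresses them.
4. **Region statistics and tests.** `mean_delta` is the pooled-count log
   ratio difference over the refined span (offset-corrected); regions with
   |mean_delta| < 1 or fewer than 10 fragments are dropped. The Fisher
   table per iteration is [fragments with sign-matching per-fragment
   |delta| >= 1 vs not] x [candidate vs an equal-size random fragment set];
   drawing the random set without replacement is realized exactly as a
   hypergeometric draw of its pass count, and the two-sided exact p is
   computed by hypergeometric enumeration. The reported `p_empirical` is
   the median over iterations (mean available via `aggregate`); raw p <=
   0.01 is the cut, with optional Benjamini-Hochberg correction behind
   `bh_correct`.
5. Called regions never overlap: same-direction overlaps merge, opposite-
   direction overlaps are trimmed at the earlier region's boundary.

At the depths the tests use, the realized region-level delta of a planted
1.2 log2 region is approximately N(1.2, 0.104); the ~2.7% of regions whose
realized fold change lands below 2-fold are correctly not called, which
bounds attainable recovery.

## Expression statistics

`quantile_normalize` maps every sample onto the common distribution of
row-rank means (ties averaged; idempotent). `moderated_stat` implements the
empirical-Bayes moderated t: gene-wise pooled variances s^2 with d residual
df are shrunk toward a prior, s~^2 = (d0 s0^2 + d s^2)/(d0 + d), with
(d0, s0^2) estimated by moment matching of log s^2 against the scaled-F
model (Newton iteration on the trigamma function); the statistic is
referred to t with d + d0 df. `moderated_f` provides the multi-group F.
The implementation reproduces R limma's lmFit/eBayes to machine precision
on shared inputs (tested via Rscript). FDR control is Benjamini-Hochberg
(statsmodels). Calls: up/down require |log2FC| strictly above 0.5 and
q <= 0.05. `fold_class` additionally classifies condition means by an
at-least-1.4-fold change (inclusive threshold).

## Integration

Genes are assigned to called regions by >= 1 bp gene-body overlap; a gene
touching both directions goes to the larger overlap and is flagged
ambiguous. Concordance is evaluated per gene among genes that are in a
region and have a non-nc expression call: concordant means IP & down or
PI & up. The 2x2 test is Pearson chi-square without continuity correction,
chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)), with a Fisher's exact fallback
when an expected cell is below 5. Effect-magnitude asymmetry uses a
two-sample KS on |log2FC|; knockdown set overlaps and the
counter-directionality fraction are plain set/sign bookkeeping.

## Radial imaging

Equal-area shells are realized by area-quantiles of the interior Euclidean
distance transform: mask pixels are ranked by distance to the boundary and
split into five groups whose sizes differ by at most one pixel (shell 1
peripheral, shell 5 central; remainders go to the peripheral shells; ties
in distance break deterministically by raster order). The
20%-erosion-per-step description specifies the target areas; quantiles
guarantee them exactly on arbitrary shapes, which repeated morphological
erosion does not. On a disk, shell boundaries land at r*sqrt(k/5). Spots
are scored by the shell label at the nearest pixel to their centroid;
territories by the fraction of in-mask intensity per shell (optional
median-background subtraction). Population comparisons use chi-square on
per-shell counts or KS on per-cell shell indices. Distances to a
compartment (e.g. nucleoli) are Euclidean distances to the nearest
compartment pixel, zero inside, summarized as an ECDF. Masks may be given
directly or derived by Otsu thresholding + hole filling + largest
component; segmentation sophistication is out of scope.

## Synthetic data: what is emulated, what is not

`make_genome` draws i.i.d. uniform DNA, so GATC spacing is geometric with
mean 256 bp. `plant_architecture` places, in order: IP/PI shift regions
(uniform sizes in 300-600 kb, 150 kb clearance), LADs (log-normal sizes,
median ~450 kb, clipped to 0.1-2 Mb), and condition-unique LAD segments
sized so the shared fraction of the union coverage equals the request
exactly (remainder split evenly MB-only/MT-only). IP regions sit at
inter-LAD level in MB and gain `shift_delta` (default 1.2 log2) in MT; PI
regions sit at LAD level in MB and lose it; planted LAD truth and shift
truth are kept on disjoint territory so each is recoverable independently.

Counts are negative binomial (gamma-Poisson; variance m + a m^2, a = 0.1
by default, Poisson at a = 0) with Dam-only mean `depth` and LaminB1 mean
`depth * 2^(mu + eps)`, `eps ~ N(0, 0.3)` drawn once per fragment and
shared between conditions so the planted MT-MB delta is exact. Default
depth is 5 reads/fragment; the study-condition tests override it to 0.5
where stated. Defaults for the levels are mu_LAD = +0.8 and
mu_interLAD = -0.8, matching the separations the LAD-calling tests assume.

Expression: per-gene baselines N(8, 2) log2 intensity, replicate noise
N(0, 0.25), three replicates per condition. Planted |log2FC| for
region-member genes is |N(1.0, 0.3)| clipped at 0.3. The concordant
fraction is planted exactly — round(concordance * n) genes per membership
class change opposite to their repositioning, the assignment randomized —
rather than i.i.d. Bernoulli, so the planted rate is a controlled design
quantity and recovery error measures the pipeline, not binomial sampling.
Concordant and discordant effect magnitudes are drawn from the same
distribution, keeping the concordance estimator unbiased.

Images are analytic ellipses with a Gaussian spot at a requested radial
fraction and a territory channel that is piecewise-constant over analytic
equal-area shells.

Not emulated: read-level sequencing artifacts (mappability, PCR, GC),
GATC-density covariation with chromatin state, probe-level array effects,
3D nuclear geometry, segmentation of crowded fields, and any asymmetry
between concordant and discordant effect sizes. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to those real-data complications.

## Problem sizes and numerical choices

Planted-truth tests run on 5 x 20 Mb genomes (~390k fragments), 40 shift
regions, ~11k genes for concordance, and 20-seed batches for calibration
checks; these sizes make every recovery target statistically decisive while
keeping the full suite under a minute of compute for the genomics portion.
All randomness flows from explicit integer seeds; fixed seeds give
byte-identical outputs, including the full CLI pipeline
(simulate -> call-lads -> call-shifts -> de -> integrate -> radial ->
report). Degenerate inputs (empty sequences, all-zero channels, all-missing
tracks, empty masks, out-of-bounds spots) raise errors rather than
propagate silently; out-of-bounds reads are skipped with a logged count.

## Known limitations

- The LAD caller is a self-contained 2-state HMM, not a reimplementation of
  any published LAD caller; boundary conventions may differ from other
  tools by a bin.
- The Fisher randomization test inherits the selection bias of testing
  candidates that were found by thresholding the same data; its p-values
  are calibrated for randomly chosen regions, so the raw 0.01 cut is
  anti-conservative for borderline candidates (any procedure that tests
  threshold-selected candidates against random sets shares this property).
- Boundary localization at 0.5 reads/fragment is information-limited
  (~10-20 kb typical error, occasional 50 kb+ tails); deeper data localizes
  proportionally better.
- Shell analysis is strictly 2D midplane, as in the quantification it
  reproduces.
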