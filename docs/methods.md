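# Methods

## The measurement model

Two-channel aCGH co-hybridizes a test genome (Cy3) and a diploid reference
genome (Cy5) to a whole-genome tiling array; the per-probe intensity ratio
estimates relative copy number.  `cghcnv.simulate` generates data with the
statistical structure this assay actually has.  Per probe *p* at array
position (row, col):

    log2 T_p = log2 B + b_p + log2(c_p / 2) + g(row, col) + e_p^T
    log2 R_p = log2 B + b_p                 + g(row, col) + e_p^R
    T_p     <- a · T_p^beta                    (test-channel dye bias)

* **B** — baseline intensity (default 1000 fluorescence units).
* **b_p ~ N(0, probe_effect_sd²)** — probe-specific hybridization
  efficiency, *identical in both channels* (sequence composition, GC, probe
  synthesis).  Default sd 1.0 log2 units.  This shared spread dominates
  real aCGH intensity distributions and is what makes the two channels
  statistically comparable; without it, quantile-based normalization of a
  genome with appreciable CNV content is ill-posed, because the two channel
  distributions then genuinely differ and the normalizer would erase part
  of the signal it should preserve.
* **c_p** — test copy number at the probe midpoint (`floor((start+end)/2)`,
  the single membership rule for boundary probes); 2 outside planted CNVs.
  Zero-copy probes keep `deletion_residual` (default 0.4) effective copies
  of background/cross-hybridization signal, putting homozygous deletions at
  log2(0.2) ≈ −2.3 — the magnitude range short-oligo arrays report, and a
  value that keeps the channel intensity distribution continuous rather
  than creating an isolated far tail.
* **g(row, col)** — smooth spatial artifact: a plane plus one low-frequency
  sinusoid over the unit-scaled array grid, peak-to-peak `gradient_amplitude`
  (default 0.3 log2 units) across the diagonal.  Applied to both channels
  (a hybridization-surface effect).
* **e ~ N(0, noise_sd²)** — independent per-channel noise, default sd 0.15
  (typical aCGH ratio dispersion: per-probe ratio sd √2·0.15 ≈ 0.21).
* **Dye bias** — monotone power distortion of the test channel on the
  linear scale, default (a, β) = (1.2, 0.95): the intensity-dependent bias
  that q-spline normalization exists to remove.

One seeded generator per simulation; draws in documented order (probe
effects, test noise, reference noise), so a fixed seed gives bit-identical
arrays and every simulated value can be re-derived by a scripted
re-application of the formula (tested).

Probe designs tile each chromosome with start-to-start gaps uniform in
`mean_spacing·(1±jitter)` (defaults 1650 bp ± 20%), matching the tiling
density of the horse survey the bundled example tables come from; array
(row, col) positions are assigned row-major over a near-square grid.
Planted CNVs are non-overlapping, sizes uniform on [6.1 kb, 570 kb] (the
survey's observed range), copies drawn from {0, 1, 3, 4}.

What the simulator does **not** model: sequence-level probe design and
cross-hybridization structure, position-dependent probe gaps at repeats,
scanner saturation, replicate/dye-swap designs, X-chromosome dosage.
Passing recovery tests therefore demonstrate correctness of the analysis
chain under a realistic noise/bias/artifact model, not performance on any
particular real array.

## Preprocessing

Order: spatial correction → q-spline normalization → log2 ratios.  Neither
step reorders, adds, or drops probes, and ratios are only formed at the
end.  No background subtraction is applied.

**LOESS spatial correction** fits, per channel, a locally weighted linear
surface of log2 intensity over (row, col) rescaled to the unit square:
tricube weights, bandwidth = the distance enclosing a `span` fraction of
probes (default 0.3).  The surface is evaluated at a 12×12 anchor grid and
bilinearly interpolated to probes — O(grid²·n) instead of O(n²), and exact
for planar artifacts (a local linear fit reproduces a plane at each anchor,
and bilinear interpolation of a plane is the plane; tested to <1% of the
planted amplitude).  The fitted surface *minus its own grand mean* is
subtracted, so each channel's mean log2 intensity is preserved to 1e-9 and
intensities stay positive.  Correction is per channel, not on ratios.

**q-spline normalization** computes each channel's log2-intensity quantiles
at 100 evenly spaced probabilities in [0.005, 0.995]; the per-probability
target is the mean of the two channels' log2 quantiles (= log geometric
mean, symmetric in the channels).  Each channel maps through a monotone
PCHIP spline over its (quantile, target) anchors; duplicate anchor
abscissae are averaged, extrapolation beyond the anchor range is linear
with the endpoint derivative.  A degenerate channel (fewer than 5 distinct
anchors) triggers median-scaling fallback with a warning.  The mapping is
idempotent to within 1% and equalizes channel deciles to within 1% after a
monotone power-law distortion (both tested).

Two intrinsic properties of symmetric quantile normalization are worth
knowing when interpreting output.  First, a dye slope β ≠ 1 is split
between the channels: ratios come out scaled by ≈ (1+β)/2 (0.975 at the
default β = 0.95), so a 3-copy gain's expected segment mean is ≈ 0.56
rather than log2(1.5) = 0.585 — close to the 0.5 calling threshold, which
is exactly why single-copy gains are the hardest class.  Second, CNV mass
itself perturbs the quantile map; at the simulated CNV fill (≈5% of the
genome) the induced baseline shift and extra ratio dispersion are small but
visible, and they vanish toward the ≈0.6% fill of a real 2.2 Gb genome.

## Segmentation

`dp_segment` computes, for every k ≤ k_max, the *global* minimum over all
contiguous k-partitions of the within-segment sum of squared deviations
from segment means, via the classical O(k_max·n²) dynamic program with
prefix sums of x and x² (numba-compiled; a vectorized numpy fallback keeps
the package functional without a JIT).  Ties break toward fewer segments,
then lexicographically earliest breakpoints.  Costs and breakpoints are
validated against an independent exhaustive enumerator (`brute_force_segment`,
per-segment variance computed directly, n ≤ 25) on hundreds of random
sequences.

**Model selection.**  k minimizes SSE_k + λ·k·log n.  Default
λ = 2σ̂², with σ̂ = 1.4826·median|Δx|/√2 (robust to level shifts).  The
factor 2 is the classical Gaussian-changepoint BIC penalty (2σ²·log n per
segment); with half that penalty the optimizer will occasionally isolate a
five-probe noise excursion beyond ±0.5 on a ~30 k-probe self-self array,
i.e. manufacture exactly the false positives the retention rule is supposed
to exclude.  λ is exposed (`--penalty`) because the reference
implementation this mimics does not publish its stopping rule.

`segment_track` segments chromosomes independently with
k_max = ⌈10 per Mb⌉ (generous at 1650 bp spacing, capped at the probe
count).  Segment genomic spans run from the first probe's start to the last
probe's end, so inter-probe gaps belong to the preceding segment
(conservative boundaries).  A probe-count-weighted mean of segment means
equals the track mean to 1e-9 (conservation test).

## Calling

Retention: |mean log2| ≥ 0.5 **and** ≥ 5 consecutive probes, boundaries
inclusive (+0.5 → gain, −0.5 → loss, interior → unchanged).  Raising either
threshold never increases the call count (tested as a property).

**Stitching.**  Exact least-squares segmentation is an outlier detector:
inside a long CNV it will isolate a 1–4-probe run of heavy-tailed mapped
noise, the run fails the 5-probe filter, and one biological event becomes
two adjacent calls — which then fails reciprocal-overlap matching and
inflates apparent call counts.  `stitch_calls` therefore merges consecutive
same-status calls of a sample separated by ≤ 20 kb, or by ≤ 5% of the
joined span (the convention of CNV post-processors that join call
fragments whose gap is a minor share of the event).  The cap is small
relative to a credible diploid segment (20 kb ≈ 12 probes), so distinct
nearby CNVs of the same status are not fused.  `call_cnvs` itself remains
the bare retention rule; stitching is a separate, documented step of
`run_sample_pipeline`.

Recovery benchmarking treats a planted CNV as recoverable when ≥ 5 probe
midpoints fall inside it and |log2(copies/2)| ≥ 0.5; matching is
reciprocal 50% overlap (a benchmarking convention, chosen over
breakpoint-exact matching because segment boundaries are only defined to
probe resolution).

## CNVR analysis

Interval arithmetic is 1-based inclusive (length = end − start + 1);
overlap needs ≥ 1 shared bp, so book-ended intervals do not merge.  CNVRs
are transitive closures of overlapping calls across samples, spanning the
member union; Σ CNVR lengths equals the exact per-bp union length (tested
against a bp-marking oracle), merging is idempotent, and |CNVRs| ≤ |CNVs|.
Status: all-gain → gain, all-loss → loss, mixed → both.  Sharing: a call
overlapping a call from ≥ 1 other sample is shared, annotated with the
number of distinct samples in its overlap component; otherwise
breed-specific.

Summary tables round half-up to 2 decimals.  The chromosome-distribution
totals row computes genome coverage percent over **autosomes only** while
listing the full genome length — the convention of surveys that call CNVs
on autosomes but tabulate the X for completeness.  With the bundled example
totals (13,586,559 bp of CNVR over a 2,242,939,370 bp autosome complement)
this yields 0.61%; including X would give 0.57%.  Size bins are half-open
in Kb: [1,10), [10,50), [50,100), [100,500), [500,∞), so a 50,000 bp CNVR
falls in the third bin.

## qPCR

Relative copy number = 2^−ΔΔCt, with ΔCt = mean target Ct − mean
reference-gene Ct over exactly three replicates (a triplicate range > 0.5
cycles raises a QC warning), and ΔΔCt the test-minus-calibrator difference.
No amplification-efficiency correction.  Status thresholds: gain at
RCN ≥ 1.4, loss at ≤ 0.6 — midpoints-with-margin between diploid (1.0) and
one-copy changes (1.5/0.5) on a diploid background.  RCN is exactly 1 for
a sample compared with itself, strictly decreasing in ΔΔCt, and invariant
to a constant shift of all Ct values (all tested).  Concordance against
the array treats a sample with no overlapping call as "unchanged".

## Problem sizes and defaults used in the shipped benchmarks

The recovery benchmark simulates 20 replicates of a 56-scaffold × 3 Mb
genome (168 Mb, ~102 k probes) with 30 planted CNVs each (~5% fill), all
artifacts on; the ablation arm disables both normalizations.  Scaffold
count rather than length is scaled down because the DP costs O(k_max·n²)
per chromosome, i.e. cubically in chromosome length at fixed probe density
and k_max per Mb.  The self-self benchmark uses 10 replicates of a
16-scaffold genome.  These sizes are the package's chosen compromise
between statistical resolution and a test suite that runs in minutes.

## Known limitations

* The segmentation penalty is a surrogate for an unpublished proprietary
  stopping rule; calls near the 0.5 threshold can differ from NimbleScan's.
* Symmetric q-spline slightly compresses true effect sizes under dye slope
  β ≠ 1 (see above); single-copy gains at ≈ 0.56 expected mean are
  occasionally missed or called partially.
* Sharing labels and CNVR merging use ≥ 1 bp overlap with no minimum
  reciprocal fraction; dense call sets merge aggressively.
* The qPCR module models the pure 2^−ΔΔCt form only (no efficiency
  calibration, no melt-curve QC).
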