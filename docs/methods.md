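# Methods

This note documents the models and procedures implemented in `dialion`,
the parameters that matter, the design choices made where the design was
genuinely open, what the synthetic-data generator does and does not
emulate, and known limitations.

## Coordinate calibration

Each run gets one calibration model per axis (retention time; ion mobility
when both a library value and observations exist). Anchor precursors must
carry an observed coordinate in at least `calib.min_runs` (default 3) runs
and have a cross-run coordinate standard deviation below the
`calib.variability_quantile` (default 0.95) quantile of all candidates.
The map itself is a cubic least-squares spline with up to `calib.knots`
(default 5) interior knots placed at anchor quantiles, evaluated on a dense
grid and isotonized by pool-adjacent-violators so that it is monotone
non-decreasing over the anchor range; outside the range it continues
linearly with the boundary secant slope (prediction targets can fall
outside the anchors). Duplicate library coordinates are averaged before
fitting, and clumped anchors that violate the spline's interlacing
condition fall back to linear interpolation. A seeded 20 % holdout split
yields an RMSE self-diagnostic per model; the final map is refitted on all
anchors. At least 8 anchors are required, otherwise calibration fails
loudly for that run.

## Observable isotope envelope

The expected number of heavy-isotope substitutions of a peptide of
monoisotopic mass *m* Da is λ = 0.00052·*m*, and the envelope follows the
Poisson pmf. A peak is observable when its pmf is at least 10 % of the
envelope mode; the observable count runs from M+0 through the highest
qualifying peak (M+0 is always included). The 10 % rule is evaluated as a
ratio to the maximum, which is equivalent to normalizing the pmf to the
mode. Isotope spacing is 1.0033548 Da (mean ¹³C−¹²C difference) divided by
the charge. The count is non-decreasing in mass, so heavier precursors
contribute more MS1 cross-run ion vectors by construction.

## XIC extraction and quantification

Traces are extracted at `xic.tol_ppm` (default 15 ppm, matching common
DIA search settings) within ±`xic.rt_halfwidth` (default 1.0 min) of the
precursor's run coordinate; MS2 extraction is restricted to scans whose
isolation window contains the precursor m/z; when ion mobility is present,
scans outside ±`xic.im_halfwidth` (default 0.05 1/K0) are excluded. Scans
with no matching peak contribute explicit zeros.

The representative elution profile per precursor-run is chosen from the
pooled MS1+MS2 candidate set (one representative serves both levels) by a
composite score with weights (0.4, 0.4, 0.2) for correlation, shape and
intensity. Correlation is the mean Pearson correlation to sibling traces
mapped from [−1, 1] to [0, 1]; shape is r⁺·b where r⁺ is the clipped
correlation to a moment-matched Gaussian and b = 1 − |L−R|/(L+R) measures
apex balance; intensity is the rank percentile of the integrated raw area
among the candidates. Ties break lexicographically on ion id, so candidate
order never changes the winner. The first ranked candidate with shape ≥
`xic.min_shape` (0.5) and raw apex intensity ≥ `xic.min_apex_intensity`
(0, configurable) wins.

Apex location uses the 3-point moving average (parabolically refined);
the intensity criterion and the FWHM use the raw trace. FWHM is measured by
linear interpolation of the half-height crossings around the parabolically
refined raw apex; when only one side crosses, the crossed side is
reflected; when neither does, FWHM falls back to half the trace span. On
noiseless Gaussians this estimator is accurate to within 1 % for peaks
sampled at ≥ 2 points per σ.

Every ion is integrated (trapezoid) over [apex − FWHM, apex + FWHM], with
interpolated samples inserted at the exact window edges. Interference is
truncated against the representative profile scaled by the median
near-apex intensity ratio (points above `xic.scale_ms1` = 3 or
`xic.scale_ms2` = 2 times the expectation are clipped); the median ratio
makes re-truncation a no-op whenever clipping touches a minority of
near-apex points. The XIC-quality score is the clipped Pearson correlation
to the representative inside the window.

## LION inference

Entries with quality below `lion.min_quality` (0.3) or zero/absent
quantity are missing; ions missing in more than `lion.max_missing_fraction`
(0.5) of runs are excluded. Each remaining missing entry is filled with
`lion.scale` (default 1.0) times the minimum observed quantity of the same
ion among same-condition runs; the neighborhood is the biological
condition from the sample metadata (batch is deliberately not part of it).
MS1 and MS2 vectors never borrow from each other, conditions never borrow
from each other, and an ion with a fully missing condition is dropped
rather than guessed. Filling is idempotent and, at scale 1.0, preserves
the condition-wise minimum exactly.

`sweep_lion_scale` re-runs inference and summarization over a grid of
scales and reports median protein CV and median fold-change deviation per
scale; only imputed entries change between scales, so the differences are
systematic rather than sampling noise. On the synthetic benchmark the CV
curve falls and then plateaus with increasing scale, with its minimum near
the ratio of the condition's typical intensity to its observed minimum.
The fold-change-deviation curve is V-shaped around that same pivot rather
than monotone: with minimum-based filling and multiplicative noise, the
scale that best restores fold changes and the scale that minimizes CV
coincide, so below-pivot scales exaggerate fold changes of the
missingness-imbalanced species while above-pivot scales compress them.
This coupling is a property of the synthetic data family, discussed under
*Limitations*.

## Summarization

One scheme serves both levels: log2-transform the feature-by-run matrix,
center each feature row by its cross-run mean, take per-run medians of the
centered values, rescale by the mean cross-run mean log2 intensity of the
`summarize.top_n_rescale` (3) most abundant features, and back-transform.
The scheme is exactly equivariant under per-run scaling and ignores a
constant log-offset corruption of a minority feature row. Precursor
quantities are computed per level from complete (post-inference) ion
vectors. Protein quantities pool precursor vectors — MS1-only, MS2-only,
or integrated, where each precursor contributes its MS1 and MS2 vectors as
separate unweighted rows; proteins with fewer than
`summarize.min_precursors` (3) contributing rows use the vector of the
qualified precursor with the highest mean XIC quality. A qualified
precursor retained ≥ 1 ion through inference and has mean quality ≥
`lion.min_quality`. The full pipeline produces a protein matrix with no
missing cells for every protein whose retained ions survived exclusion in
all conditions.

## Differential abundance and benchmark metrics

Quantifiable proteins need ≥ `da.min_valid_per_group` valid values in
every group (default: 5-of-8 pro rata, i.e. ⌈5·n/8⌉ for n replicates) and
≥ `da.min_precursors` (2) supporting precursors. Testing is a re-implemented
empirical-Bayes moderated t-test: per-protein pooled variances are shrunk
toward a scaled-F prior whose parameters (d0, s0²) come from method-of-
moments on log s² (digamma/trigamma inversion), t uses d0 + d degrees of
freedom, and P values are Benjamini–Hochberg adjusted. The implementation
is cross-checked against Bioconductor limma in the test suite and agrees
to within 2 % on P values. A Welch-t switch exists for cross-checking.

Calls at |log2FC| > `da.fc_cut` (0.5) and adjusted P < `da.p_cut` (0.05)
are scored against species ground truth: expected-direction calls are TP,
wrong-direction or unchanged-species calls are FP, missed changing
proteins FN, quiet unchanged proteins TN; daFDR = FP/(FP+TP), defined as 0
when no calls are made. The ROC ranks proteins by adjusted P (ties broken
by |log2FC| descending) with changing species as positives; pAUC is the
unnormalized trapezoidal area restricted to FPR ≤ `da.fpr_max` (0.1), so
its maximum is 0.1 and a diagonal ROC gives 0.005. CV is sd/mean per
protein per group in percent; fold-change error is the per-species median
|observed − expected| log2 ratio (median chosen for robustness;
configurable).

## Synthetic experiment generator

The generator emulates a two-condition HYE-style mixture: 150 human-like
proteins (unchanged), 75 yeast-like (2× up) and 75 E. coli-like (4× down),
each with 2–3 precursors, over two conditions × four replicates. Protein
abundances are log-normal (mean 10⁵, σ = 0.6 decades); precursor m/z sits
on a jittered collision-free grid inside 25-m/z isolation windows tiling
400–1000 m/z; fragment m/z are drawn collision-free per window in
200–1500. Elution peaks are Gaussian (σ ≈ 0.05 min on a 10-min gradient
scanned every 0.02 min), MS1 peaks carry the Poisson envelope's relative
heights, and each precursor's six fragments carry library intensities.
Retention times follow a smooth monotone per-run warp of iRT with a
sinusoidal component; 15 % of reported coordinates are deleted to exercise
calibration.

The noise and missingness model aims at the structure neighborhood-minimum
inference addresses: multiplicative log-normal noise whose CV rises from
10 % at high abundance to ~50 % near the detection region (shot-noise
behaviour); a per-ion detectability offset (σ = 0.5 decades) that makes
missingness partly ion-idiosyncratic; sporadic suppression events at low
effective intensity that attenuate a measurement ~10-fold, 85 % of which
fall below detection entirely (so a missing entry's true signal usually
lies far below the same-condition observed minimum, while surviving
measurements stay essentially unbiased); scan-level noise that grows as
the realized signal approaches the detection floor, so
barely-detected ion-runs produce ragged traces that the XIC-quality rule
flags as missing; and a small residual intensity-dependent dropout. The
defaults yield ≈ 10 % ion-run dropout and ≈ 13 % flagged-missing entries,
in the range the method targets, with missingness greatest at the ion
level and absent from the final protein matrix. Everything is regenerable
bit-identically from the config seed.

What the generator does **not** emulate: chimeric/interfering spectra by
default (an `interference_rate` knob adds contaminant peaks for stress
tests), co-eluting isomers, split peaks, mobility-resolved peak shapes,
sequence-dependent fragmentation, and real calibration drift beyond smooth
warps. Passing tests therefore demonstrate correctness of the machinery
under clean chromatography and calibrated mass accuracy, not robustness to
heavily chimeric real data.

## Problem sizes

The default test suite runs the full pipeline on a 40-protein and a
300-protein experiment (≈ 100 and ≈ 750 precursors over 8 runs) and the
scale sweep on a 160-protein, 16-run study; these sizes give stable
benchmark statistics (hundreds of tested proteins) while keeping a full
test run around a minute of pipeline compute.

## Limitations

- The representative elution profile is shared between MS1 and MS2; runs
  where all candidate traces are flat or sub-threshold mark the whole
  precursor-run missing rather than attempting deconvolution.
- The moderated test supports exactly two conditions; multi-factor designs
  and batch covariates are out of scope.
- In the synthetic data family (multiplicative noise + minimum-based
  filling), the fold-change-accuracy optimum and the CV optimum of the
  inference scale coincide, so the scale diagnostic shows a V-shaped
  deviation curve rather than one monotone in scale; separating the two
  optima appears to require real-data structure (e.g. estimators
  insensitive to low fills but sensitive to high ones) outside this
  family.
- mzML support is read-only and interprets the common cvParam subset
  (ms level, scan start time, isolation window, inverse reduced mobility,
  32/64-bit float arrays, zlib or no compression).
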