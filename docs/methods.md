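# Methods

This note documents the models, conventions and numerical choices behind
`nadhcycle`, and what the synthetic data does and does not emulate.

## Image model and flat-field correction

A raw fluorescence pixel is modeled as

    raw(x, y) = B + I(x, y) · L + S(x, y) + ε

with CCD baseline *B* (an electronic offset, default 500 AU), smooth
illumination field *I* (low-order 2-D polynomial, mean ≈ 1), background
emission level *L*, cell signal *S* and camera noise ε.  Blank positions
(fields without cells) measure `B + I·L`.  The correction

    corrected = (experimental − blank) / (blank − B) · mean(blank)

is exact for this model: the numerator isolates *S·(x,y)-modulated* signal,
the denominator removes the shading *I·L*, and the scalar blank mean
restores an intensity scale.  Two conventions are deliberate:

* `mean(blank)` is the **raw** blank mean by default, exactly as the
  formula is written; because that factor is inflated by the offset *B*, a
  baseline-subtracted variant is available (`blank_mean_uses_raw=False`).
  The choice rescales all corrected values by a constant and cancels in
  every downstream quotient-normalized statistic.
* Corrected values may be negative and are **not clipped**; sub-noise
  pixels are only removed at ROI quantification.

Background noise is estimated per frame as the nearest-rank 90th percentile
(the smallest observed value ≥ 90% of the pixels) of a > 5000-pixel
cell-free region, and per experiment as the median of the per-frame values.
Nearest-rank is chosen because the definition is "a value greater than 90%
of the selected pixels"; the interpolated convention is available by flag.
When estimation is skipped the default threshold is 10 AU.

ROI intensity on corrected frames: pixels below the threshold are removed
and a normal distribution fitted to the survivors by maximum likelihood,
whose mean (the plain-MLE fit equals the survivor sample mean) is the ROI
value.  Because thresholding censors the left tail, a truncated-normal MLE
is offered (`truncated=True`); it noticeably de-biases ROIs whose
distribution straddles the threshold but is not the default, since for
well-exposed cells the censored mass is negligible.  Fewer than 5 surviving
pixels yields NaN with a warning rather than a biased value.

## Growth rates and photodamage

The observed ROI area halves at division (one of the two sisters is
followed).  Multiplying by 2^(divisions so far) reconstructs a division-free
exponential; the growth rate is the least-squares slope of log(area) vs
time over hours 4–10 (log-linear rather than nonlinear fitting: identical
for clean exponentials, stable under multiplicative noise; a nonlinear
refinement is available).  Photodamage is phenomenological: a table of
(energy, interval) → fractional growth-rate reduction anchors,
piecewise-linear in energy within an interval class and linear across
classes.  Only two anchors are measured quantities (0.10 at 9 μJ/15 min,
0.89 at 56 μJ/5 min); the rest are defaults shaped by three qualitative
facts — reduction is zero at zero energy, non-decreasing in energy, the
intervals coincide at ≤ 9 μJ and the 5-min interval is worst above it.
Energies above the largest anchor are clamped with a logged warning.

## Division-cycle analysis

**Boundary convention.**  A division frame is the last frame of the ending
cycle; cycles therefore partition a track's interior frames.  The recorded
`duration_min` is `(end_frame − start_frame) × frame interval` per the data
contract (one interval less than the inter-division spacing; only relative
phase matters downstream).

**Detrending.**  Quotient normalization divides each track by a cubic
smoothing spline minimizing `p·Σ(y−s)² + (1−p)·∫(s″)²` with p = 0.004 on a
frame-index abscissa (scipy's `make_smoothing_spline` with
`lam = (1−p)/p`, the same objective).  At a 10-min frame interval this
spline has an equivalent bandwidth of roughly 4 frames — it tracks drift on
the hour scale while leaving most intra-cycle structure in the quotient.
The abscissa units matter for a fixed p: per-minute abscissae would need a
different p for the same bandwidth; frame index is the package convention.
The alternative linear-residual normalization subtracts, per cycle, the
line through the first and last intensity points, forcing zero endpoints.
Both methods must agree on the pattern call (tested).

**Resampling.**  Every cycle is mapped to 21 points: the two endpoints plus
19 linearly interpolated, evenly spaced interior time points.  For the
adjacent-cycle extension the same phase step (1/20 of the cycle) is
continued 2 points into each neighbor (10% of the cycle per side → 25
values); under quotient normalization the track-level spline normalizes the
neighbor frames naturally, under linear-residual the current cycle's
endpoint line is extrapolated.  Missing single frames are gap-filled
linearly; cycles with longer gaps, fewer than 3 frames, or missing
neighbors (when extending) are dropped and logged.

**Pattern call and null controls.**  The population profile is the
columnwise median (mean optional — the elongated-profile statistic differs
between sources, so both are exposed).  The profile is flagged
"increase-drop" when its argmax is strictly interior and its amplitude
(max − mean of endpoints) exceeds a self-calibrating threshold: 3× the
largest absolute deviation from the null level across the six
fixed-division-time null profiles (60–110 min in 10-min steps).  The null
re-cuts each track into consecutive fixed-length pseudo-cycles anchored at
frame 0, destroying phase alignment; its residual deviation is dominated by
the sampling noise of a median over n cycles, so the threshold tightens as
the data set grows.  The frame-shift test redraws every cycle boundary
±1 frame (uniform on {−1, 0, +1}, independently at both ends) ten times and
reruns the pipeline; cycles shortened below 2 frames are dropped.  k-means
(k = 4, 10 restarts, fixed seed) clusters the cycle matrix; clusters are
reported in descending order of mean mid-cycle (phase 0.25–0.75) value, and
the fraction of cycles whose maximum falls at phase > 0.5 is reported, not
asserted.

**Perturbations.**  Medium arrival is the first frame at which the
3-frame-median-smoothed dye trace crosses the midpoint between the pre- and
post-switch plateau medians (plateaus estimated from the first/last 10% of
frames and required to separate by > 4× their SD).  The fold change of a
cell is its intensity at the last frame within the response horizon divided
by the median of the 3 frames before arrival.  The horizon-end value (not a
window median) is used so that "2-fold within 20 min" means exactly that;
a window-median option exists for very noisy traces.

## Synthetic data: what it emulates

Defaults reproduce the study conditions of a 10-min-interval, ≥10-h
time-lapse of *E. coli* in glucose minimal medium:

| parameter | default | basis |
|---|---|---|
| frame interval / duration | 10 min / 10 h | acquisition protocol |
| division-time law | log-normal, median 82 min | positive support, right skew |
| division-time sigma | calibrated: P(60–110 min) = 0.80 | observed window coverage |
| basal growth rate | 0.6 h⁻¹ | batch growth on glucose |
| cycle amplitude | 5% peak-to-trough | unreported; exposed guess |
| cycle peak phase | 0.65 | pattern peaks in second half |
| drift sd | 0.05 log-units/√h | slow long-term dynamics |
| frame noise CV | 5% | noisy single-cell traces |
| cell/background ratio | 0.45 | measured regression slope |
| CCD baseline | 500 AU | camera setting |

The intra-cycle shape is a monotone piecewise cubic through trough values
(1 − A/2) at both boundaries and peak (1 + A/2) at phase 0.65, with low
shoulders (at 60% of the rise and 55% of the fall, 15% of the amplitude
above the trough) so that the maximum stays localized after phase
resampling and averaging; the curve is rescaled to unit cycle mean
(analytically exact).  The initial age of each simulated cell is uniform
over its first cycle, so the population is asynchronous, as cells loaded
into a flow channel are — without this, fixed-division pseudo-cycles would
stay spuriously phase-locked near t = 0.  After each division one sister is
followed, chosen uniformly at random (the choice is unobservable because
sisters are equal halves).

Rendered images are deliberately simple: capsule-shaped cells with uniform
interior intensity, fixed positions, no motility, no segmentation errors,
Gaussian read noise and optional Poisson shot noise.  Passing the
render→correct→measure round trip therefore validates the *quantification
algebra* (correction formula, ROI statistics), not robustness to
segmentation error, cell crowding, focus drift or photobleaching — real
data adds all of those.  Likewise the perturbation generator builds in the
expected response shapes (saturating 2-fold rise reaching 2× at 20 min; a
30-min delay then exponential decline), so end-to-end perturbation tests
validate arrival detection and fold-change computation, not biology.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the package's
own defaults: 10,000 draws for the division-time law (SE of the window
fraction ≈ 0.4 pp), 20 tracks per arm for growth-reduction recovery
(noiseless: recovery is exact up to the fit), 20 cells × 4 energies for the
exposure-ladder slope, 30 cells for the upshift, and ~100 tracks (≈ 600
cycles) for the oscillation analysis, where the self-calibrating threshold
(3× a null order statistic) needs the null sampling noise comfortably below
a third of the 5% signal amplitude.  Root finding for the division-time
sigma uses Brent's method on the closed-form log-normal CDF within a
[10⁻³, 10] bracket (windows needing sigma outside it are rejected as
infeasible rather than silently returning a degenerate law).  All
randomness flows through `numpy.random.default_rng` with explicit seeds;
identical seed + configuration gives bit-identical outputs.

## Known limitations

* Divisions are inputs (from masks or metadata); no detection from images.
  The frame-shift test bounds the impact of ±1-frame call errors only.
* ROI masks are assumed registered to the fluorescence frames; no XY offset
  correction.
* The photodamage table beyond its two measured anchors is a plausible
  default, not data.
* No FLIM, no separation of NADH from NADPH, no photobleaching model, no
  spectral analysis of the oscillation.
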