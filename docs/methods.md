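# Methods

This note documents the models, estimators, defaults and known
limitations of the package, and the design choices made where several
reasonable options existed.

## Synthetic signals

**Canonical systems.**  The logistic map (default r = 4, x₀ = 0.3) is
iterated directly; its largest Lyapunov exponent is ln 2 by conjugacy
with the tent map, which the estimators must recover.  The Lorenz
system (σ = 10, ρ = 28, β = 8/3) is integrated with a fixed-step
classical 4th-order Runge–Kutta scheme at dt = 0.01, discarding the
first 1000 steps; the returned observable is the x-coordinate.  In this
regime the literature values are λ₁ ≈ 0.91 per time unit and
D₂ ≈ 2.05.  Sine and white-noise generators provide the periodic and
stochastic controls.

**Synthetic MCG.**  Each cardiac cycle is a sum of five Gaussian bumps
(P, Q, R, S, T) on a flat baseline; amplitudes are in units of the R
amplitude, positions and widths in seconds relative to the R peak
(defaults: P at −0.20 s amplitude 0.15, Q −0.035 s/−0.10,
R 0 s/1.0, S +0.035 s/−0.15, T +0.30 s/0.35; widths 25/10/12/10/50 ms).
The default sampling rate is 1000 Hz with a 1 s mean cycle.  Segment
boundaries sit at ±3σ of the bounding bumps, so the seven segments
(pre-P, P, post-P, QRS, ST, T, post-T) partition every cycle exactly
and are returned as ground-truth fiducials.  The ischemic class adds a
constant −0.1 × R-amplitude offset over the ST window, scales the T
amplitude by 0.5, and triples the beat-to-beat cycle-length jitter
(1% → 3% SD).  These effect sizes are a morphological stand-in chosen
to echo the classic surface signatures of ischemia (ST
depression, T-wave flattening, increased variability); they are **not**
clinically calibrated, and nothing downstream should be read as a
clinical performance claim.  All 36 channels share the template with
independent Gaussian sensor noise (SD 2% of the R amplitude) and a
per-channel gain (SD 5%) — no volume-conductor or sensor-geometry
modeling.  Per-subject seeds derive from the master seed through
numpy's splittable `SeedSequence([master, index])`, so any cohort
member can be regenerated independently.

What passing tests on these data do and do not show: the generator
carries a large, localized class difference in the ST window (effect
size well above 1), so a high end-to-end accuracy demonstrates that the
pipeline preserves and extracts class signal without leakage — it does
not reproduce, and cannot be compared with, accuracy on clinical
recordings whose class differences are far subtler.

## Preprocessing

The denoising chain is median despike (window 5), 0.5–150 Hz band-pass
(4th-order Butterworth), 50 Hz notch (Q = 30), each recursive stage
applied forward–backward so the effective phase is zero and fiducial
timing is preserved.  The median filter runs first because a transient
single-sample spike can only be rejected before linear filtering
spreads it across the filter's impulse response.  The separate 0.5 Hz
high-pass and 150 Hz low-pass stages sometimes quoted alongside a
band-pass duplicate its edges and are folded into the single band-pass.
Channel fusion is the pointwise mean followed by a moving average
(reflection padding), which reduces independent channel noise by
√36 = 6.

Cycle extraction uses ground-truth fiducials when present.  Otherwise R
peaks are detected by thresholding the smoothed squared derivative
(31 ms energy window, 25% of peak energy, 250 ms refractory period,
peak refinement within ±50 ms) and segment boundaries are placed at
fixed physiologic offsets from R (defaults mirroring the generator's
template: cycle −400…+600 ms, P −275…−125 ms, QRS ±65 ms, ST to
+150 ms, T to +450 ms).  This is deliberately not a full P/QRS/T
delineator; on real data with abnormal conduction the fixed offsets
would mislabel segments.

Chaos metrics are computed on the continuous multi-cycle series by
default (attractor reconstruction benefits from length); rendering uses
single cycles.

## Phase-space estimators

**Delay.**  Non-centered autocorrelation with fixed divisor n, no mean
subtraction (a `centered` flag is available); the delay is the first
lag below (1 − e⁻¹) R(0) — note this is the complement of the more
common 1/e convention.  A constant series never crosses the threshold
and raises a dedicated error carrying the last R value.

**FNN.**  For each candidate m the nearest neighbor of every point
(Euclidean metric, ties to the smallest index) is found in m
dimensions and the squared-distance growth ratio into m+1 dimensions is
compared against R₀ = 15.  A second criterion flags a neighbor as false
when its (m+1)-dimensional separation exceeds 2× the series SD; without
it, iid noise's ratio-criterion fraction decays with m and noise can
masquerade as low-dimensional — with it, noise correctly fails to
converge and is reported with a warning flag.  Selection stops at the
first fraction below 1%, or at a plateau after the fraction has fallen
below 10%.  On Lorenz x (20k samples, τ = 10) the false fractions are
(99.7%, 11.8%, 1.2%, 0.3%) for m = 1…4, so the selected dimension is 4;
the fraction at m = 3 is already near 1%, consistent with an attractor
dimension just above 2.  Exact recurrences (perfectly periodic series)
produce neighbor distances at rounding-error scale; a 10⁻⁹·SD floor
keeps their meaningless ratios out of the count.

**Correlation dimension.**  C(r) counts ordered pairs j ≠ k normalized
by N², evaluated on 40 log-spaced radii (squared-distance comparisons,
chunked O(N²) pass).  An optional Theiler window excludes temporally
close pairs; the default is the plain j ≠ k sum.  The scaling region
defaults to radii between the 0.2nd and 2nd percentiles of the nonzero
pairwise distances: measured local slopes on the Lorenz attractor show
the log–log curve is linear only below a few percent of the attractor
diameter and bends toward saturation well before the median distance,
where a wider window (e.g. 5th–50th percentile) would underestimate D₂
by ~20%.  Quantiles and explicit radius bounds are configurable.  The
slope is an ordinary least-squares fit of ln C on ln r and requires at
least three radii with C > 0 in the window.

**Lyapunov exponent.**  Wolf-style tracking with evolution segments of
3 samples.  Scales: `min_sep` defaults to the 0.5th percentile of the
pairwise distances (noise floor), `max_sep` to 10× that; replacement
candidates come from the 64 nearest neighbors of the fiducial point,
preferring separations above the floor, then minimal orientation
change, then the smallest index.  The Theiler window defaults to τ.
These scales keep the measured growth inside the linearization regime —
at coarser scales (percentiles a few times larger) the estimate on the
Lorenz benchmark drifts upward by 10–20% as segments traverse folds of
the attractor.  Validation: logistic ln 2 ± 0.01 observed, contracting
map −ln 2, sine |λ₁| < 10⁻⁴, Lorenz 0.95 vs. 0.91 literature.

**Surrogates.**  Phase randomization preserves the amplitude spectrum
exactly (DC and Nyquist phases fixed); embedding parameters are
estimated once on the original and reused for every surrogate.  For the
λ₁ statistic the *rejection direction is "less"*: a deterministic
chaotic map's divergence is bounded by its true exponent, while its
linearized surrogates behave like colored noise whose apparent
neighbor divergence is much larger (≈ 1.3 per step for logistic-map
surrogates vs. ln 2 ≈ 0.69 for the original).  The same direction
applies to D₂.  A test that treated "greater" as evidence of
nonlinearity would never reject.

## Rendering and augmentation

Maps are drawn as connected Bresenham polylines of the (xᵢ, xᵢ₊τ)
projection on a white 256×256 canvas (single scale for both axes, 5%
margin), each line segment colored by the cardiac segment of its
starting sample; rasterization is pure numpy and bit-exact
deterministic.  The projection is always two-dimensional regardless of
the FNN-selected m, which is still used for the chaos metrics.
Augmentation families: rotation U(−10°, +10°), translation U(±5%) of
each dimension, additive Gaussian noise (SD 2% of the intensity range),
contrast–brightness (gain U(0.8, 1.2), offset U(±25 levels)); outputs
are clipped to 0–255, dimensions and provenance preserved, and each
source image yields exactly one output per family (originals are not
duplicated), so 200 sources per class become exactly 800 images per
class.

Two protocols exist because augment-then-split and split-then-augment
bookkeeping differ: the default is leakage-safe (split subjects first,
augment only the training side); `augment_before_split` expands all
sources first and then splits the expanded dataset at the subject
level, reproducing the 1600-image/320-test-sample arithmetic.  Both
keep every image of a subject on one side.

## Features and classification

Images are converted to grayscale with standard luminance weights
before either descriptor.  HOG: 8×8-pixel cells, 2×2-cell blocks, 9
unsigned orientation bins, L2 block normalization with clipping at 0.2
(34 596 values at 256×256).  LBP: P = 8 neighbors at radius R = 1,
sampled counterclockwise from the rightmost neighbor with bilinear
interpolation off-grid; s(x) = 1 for x ≥ 0 with a 10⁻¹² epsilon so the
convention survives bilinear-weight rounding on flat regions; the
256-bin code histogram is normalized to sum to 1.  Features are the HOG
block followed by the LBP histogram, with the layout recorded.

The Random Forest is scikit-learn's, tuned by stratified grid search
(default trees ∈ {100, 200, 500}, depth ∈ {∞, 10, 20}, 5-fold) on the
training side only; prediction is an explicit majority vote over the
fitted trees, with even-split ties resolved to the lexicographically
smaller label and the score defined as the fraction of trees voting the
positive class ("ischemic").  Evaluation reports the confusion matrix
and Accuracy, Sensitivity, Specificity and F1 as percentages rounded
half-up to two decimals (0/0 rates are defined as 0 and flagged), plus
a threshold-swept ROC with trapezoid AUC.  The ROC score is a
documented construction — vote fractions are not calibrated
probabilities, so AUC is not comparable across score definitions.

## Problem sizes and numerical choices

The validation suite uses 20k samples for Lorenz, 5k for the logistic
map and planar noise, and 3k for sines; the scaled-down end-to-end run
uses 40+40 subjects, 4 cycles at 500 Hz, 128×128 images and a fixed
200-tree forest, chosen so the whole chain exercises every stage in
well under a minute.  Nearest-neighbor ties, replacement ties and
vote ties all resolve deterministically (smallest index /
lexicographic), and every stochastic step is driven by a seed derived
from the run's master seed, so identical configuration and seed
reproduce byte-identical evaluation reports.

## Known limitations

* The waveform generator has no biophysical forward model; effect sizes
  are didactic, and classifier accuracy on it is a pipeline sanity
  floor, not a clinical estimate.
* The fixed-offset segmenter assumes near-template morphology; it is
  not a delineation algorithm.
* Only the largest Lyapunov exponent is estimated, not the spectrum;
  Rosenstein/Kantz-style estimators and mutual-information delay
  selection are out of scope.
* D₂ and λ₁ at these problem sizes carry finite-sample biases of a few
  percent; tolerances in the tests reflect that, not measurement noise
  alone.
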