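# Methods

## Signal model and coordinate correction

A knee-worn triaxial accelerometer (32 Hz, ±8 g, 0.34 m above ground)
measures body acceleration plus gravity in an arbitrarily tilted device
frame. Over a short straight walk the mean acceleration vector is dominated
by gravity, so the device frame is corrected by two elementary rotations
(about y, then x) that map the recording-mean vector onto the vertical axis;
the rotations are orthonormal, hence norm-preserving per sample and exactly
invertible. The magnitude of the mean vector — rather than a nominal 1 g —
is then subtracted from the vertical component, so all three corrected
series are zero-mean even when the quasi-static estimate is slightly off
1 g. A mean-vector norm outside [0.5, 1.5] g is rejected: such a recording
cannot serve as a gravity reference. Recordings shorter than 2 s are
rejected for the same reason (the tilt estimate would be dominated by gait
dynamics).

Filtering is a 4th-order Butterworth low-pass, applied forward–backward
(`sosfiltfilt`) so that event timing is not phase-shifted; the magnitude
response is consequently squared. The default 15 Hz cutoff sits just below
the 16 Hz Nyquist frequency of the 32 Hz device — legal, but the filter then
has almost no stop band, so the package warns when the cutoff exceeds 90% of
Nyquist.

## Initial-contact detection

Heel strikes are detected from the filtered vertical acceleration in three
steps:

1. **Integration smoothing** — cumulative trapezoidal integration (a 1/f
   low-pass) followed by linear detrending, which removes the ramp any DC
   residue would produce.
2. **Gaussian CWT differentiation** — convolution with a first-derivative-
   of-Gaussian kernel (implemented with `scipy.ndimage.gaussian_filter1d`,
   `order=1`), which differentiates while smoothing at a chosen scale. Since
   differentiation undoes the integration, the processed signal is in effect
   the Gaussian-smoothed vertical acceleration.
3. **Minima picking** — local minima with prominence at least
   `prominence_frac` (default 0.5) times the processed signal's standard
   deviation (so detection is amplitude-scale invariant), separated by at
   least `min_separation_s` (default 0.25 s, comfortably below any
   physiological step time). When two candidates conflict, the deeper
   minimum wins, ties to the earlier index. Minima within one scale width of
   either end are discarded as edge-contaminated.

The CWT **scale** defaults to `sampling_rate / (2 · f_step)` samples, where
f_step is the periodogram argmax of the vertical acceleration in the
0.5–3 Hz band — i.e. the smoothing tracks the subject's cadence. The
kernel's standard deviation is scale/8, so its effective ±4σ support spans
one scale width. The kernel is deliberately narrow: at 32 Hz one sample is
31 ms, and event-timing precision degrades quickly with heavier smoothing —
a sharp contact signature decays like 1/σ³ under Gaussian smoothing while
white-noise amplitude decays only like 1/√σ, so widening the kernel loses
signal faster than it loses noise; the integration stage already supplies
the low-frequency noise suppression.

## Inverted-pendulum step length

Between consecutive initial contacts the body vaults over the stance leg;
the vertical excursion D of a sensor at height Wp maps to step length as

    step length = KG · 2 · √(2·Wp·D − D²)

with KG = 4 a generic factor relating the knee-sensor position to the centre
of mass (a fixed generic value avoids per-patient calibration). The formula
is monotone in D on [0, Wp] and exactly 0 at D = 0 and D = 2·Wp; inputs
outside [0, 2·Wp] are a domain error. Steps whose estimated D exceeds 2·Wp
are dropped with a logged warning rather than failing the subject.

**Estimating D.** The vertical acceleration between two contacts is
converted to m/s² (× 9.80665 — the single point where units leave g),
trapezoid-integrated to velocity, drift-corrected, integrated again to
displacement, drift-corrected again, and D is the max − min of the result.
Drift correction subtracts the straight line through the segment's first and
last samples — the pendulum assumption that the sensor state repeats at
successive contacts. This boundary-anchored line is essential: a
least-squares detrend would remove a non-trivial line from a full-period
sinusoid (sine correlates with time over one period) and distort the
recovered excursion by tens of percent, whereas the boundary line leaves a
full-period sinusoid exactly intact while still annihilating the ramp (in
velocity) and quadratic growth (in displacement) caused by any constant
accelerometer bias.

Two conditioning steps precede integration, because double integration at
32 Hz amplifies low-frequency artefacts to the millimetre scale of D itself:

- **Impact-transient repair**: the heel-strike impact is a near-impulsive,
  high-amplitude artefact with no counterpart in the centre-of-mass
  trajectory; one ±1-sample window around each detected contact is replaced
  by cubic-spline interpolation from the surrounding samples. The arc is
  smooth at the contact, so the interpolation error is negligible, while an
  unrepaired 0.5 g one-sample transient would corrupt D by several
  millimetres.
- **Centre-of-mass band low-pass**: a zero-phase 4th-order Butterworth at
  4 Hz (the step-frequency content lies below ~2.3 Hz even at the fastest
  pathological cadence in scope; attenuation of the arc itself is under 1%).

Temporal parameters need no such care: step time is the difference of
consecutive contact times, and stride time is computed as the **sum of
adjacent step times** (not the difference IC(i+2) − IC(i)) so the identity
stride(i) = step(i) + step(i+1) holds exactly in floating point. Walking
speed is mean step length over mean step time; stride length is exactly
twice step length — identities enforced per subject (cohort-level averages
of ratios need not satisfy them). When both knees are available, the
subject's summary is the unweighted mean of the two sides.

## Features and PCA augmentation

The 14-feature vector, in fixed order: the five gait parameters; per-axis
sample standard deviations (ddof = 1) of the raw device axes; the three
pairwise zeroth-lag cross-correlation coefficients of the mean-removed raw
axes (equal to product-moment correlations, undefined — an error — for a
constant axis); and per-axis harmonic ratios. The harmonic ratio splits the
signal into consecutive one-stride windows (stride frequency =
1 / average stride time, so DFT bins fall on stride harmonics), sums the
amplitudes of even and odd harmonics up to `n_harmonics` (default 20,
truncated below Nyquist — ≈ 17 usable at typical stride frequencies), and
averages the even/odd ratio over strides; for the medio-lateral axis
(config `features.ml_axis`, default y) the ratio is inverted (odd/even)
because ML acceleration repeats once per stride rather than once per step.
Signal features are computed on raw device axes, before realignment, since
they are defined per physical sensor axis.

PCA is fitted on **standardized** features (correlation-matrix PCA — the 14
features carry heterogeneous units), via SVD of the standardized training
matrix. All 14 components are kept and their scores appended to the 14
original (unstandardized) features, giving the 28-column matrix used for
classification. Loadings carry a deterministic sign (largest-magnitude
loading positive) so results are identical across runs and row orders. The
standardization statistics and loadings are frozen from the training rows
and applied unchanged elsewhere; at least 15 training rows are required, and
a rank-deficient training matrix warns (trailing components carry zero
variance).

## Classification protocol

The stratified split draws, per class, round(0.7 · class size) subjects
(round half up) into training — with the 36/15 cohort that is 25 + 11 = 36
training and 11 + 4 = 15 validation subjects — permuted by the simulation
seed. Each of the (default 10) simulations re-seeds the split with
base_seed + s, re-fits the PCA augmentation and the feature standardization
on its training fold only, trains the four classifiers, and evaluates
accuracy, sensitivity and specificity on the validation fold, FoG positive.
Hyperparameters are conventional defaults, all exposed in config: RBF SVM
with C = 1 and gamma = 1/(n_features · variance); 5-nearest-neighbour with
Euclidean distance; Gini decision tree of unlimited depth; Gaussian naive
Bayes. A metric with an empty denominator (no positives, or no negatives,
evaluated) is reported as NaN, never as 0. Reported means are plain
arithmetic means of the per-simulation percentages.

Note that with a 36:15 imbalance the chance level of *accuracy* is the
majority rate (≈ 73% in a 15-subject validation fold), not 50%: on
uninformative features the SVM in particular converges to majority-class
prediction. Sensitivity/specificity should always be read alongside
accuracy for this cohort shape.

## Synthetic data generator

`simulate_walk` constructs the vertical sensor trajectory analytically: per
step of duration T, the height follows z(t) = (D/2)(1 + cos(2πt/T)) — a
full-cosine arc with the sensor lowest mid-step, peak-to-trough excursion
exactly D, and zero vertical velocity at the contacts, so excursions are
exact per step regardless of step-to-step variation. The acceleration is the
analytic second derivative (a closed-form oracle for the double-integration
path), and its minimum falls exactly at each initial contact. At each
contact a heel-strike transient is added: a 3-sample symmetric pattern
(+s/2, −s, +s/2) with peak 0.5 g. Its zeroth and first moments vanish, so it
carries no net impulse — it marks the contact sharply for the detector while
leaving only a one-sample displacement blip that the transient repair
excises. Gravity is added, the triple is rotated by the sensor tilt
(default 5°), and white Gaussian noise is added per axis.

Generator defaults are the package's reference recording conditions: 30
steps, step time 0.55 ± 0.02 s, D = 8 ± 2 mm (the middle of the few-mm-to-cm
excursion range this sensor geometry produces), tilt 5°, noise 0.01 g (an
accelerometer noise floor; impact artefacts are modelled separately by the
transient), 1.5 s of quiet standing before and after the walk.
`simulate_walk_cohort` adds between-subject variability — per-subject mean
step time uniform in 0.50–0.60 s and mean excursion uniform in 5–11 mm —
without which between-system Pearson correlations would be meaningless.
`simulate_feature_cohort` draws the 14 features from an exchangeably
correlated multivariate normal (default ρ = 0.3, CV = 12%) with a
standardized mean shift (default 1.5 SD) on the five gait features for the
FoG class, signed so FoG gait is slower.

What the generator does **not** emulate: actual freezing episodes
(trembling-in-place spectra), turning, double support, asymmetry between
legs, soft-tissue resonance, or any relationship between a subject's walk
recordings and their feature-cohort row. Passing tests therefore demonstrate
that the pipeline recovers pendulum-consistent kinematics and separates
statistically separated cohorts — not clinical validity on real FoG
patients.

## Numerical choices and degenerate inputs

- Time base is index / sampling_rate everywhere; a provided time column is
  validated for uniformity (10% of the sample period) and discarded.
- File I/O round-trips floats exactly (`%.17g` on write, round-trip parsing
  on read).
- Detection on an empty or constant signal returns an empty contact series
  (not an error); fewer than 3 contacts is an insufficient-data error naming
  subject and side.
- Mean error rates use the absolute percentage per subject (the signed
  variant is available behind a flag) and sample (n−1) standard deviations;
  a zero reference value is an error naming the subject, and correlations of
  constant series are errors rather than NaNs.
- All stochastic stages consume explicit seeds; simulation s of a run uses
  base_seed + s, and identical seeds give bit-identical outputs end to end.

## Known limitations

- 32 Hz sampling bounds event-timing accuracy at ±1 sample (31 ms) and makes
  the trapezoidal double integration underestimate D by ~3% at the fastest
  cadence in scope (T = 0.45 s); this is within the package's 5% recovery
  tolerance but not removable without a higher sampling rate.
- The generic KG = 4 trades per-subject accuracy for calibration-free
  operation; step-length errors scale directly with its mismatch.
- Accuracy under class imbalance overstates performance (see above);
  the protocol reports it because it is the field's convention, not because
  it is the best-behaved metric.
- Left/right fusion (unweighted mean) and the per-axis feature averaging are
  conventions, not estimated from data.
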