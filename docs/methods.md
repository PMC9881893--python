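# Methods

This note documents the models and procedures `vswim` implements, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices inside
the fits.

## The measurement model

Animals swimming in the vertical plane are filmed against a static
background. Per frame, the tracker reports the body centroid (x, z in
mm, z up), the head centroid, and the pitch angle — the elevation of the
head-minus-body vector above the horizon, nose-up positive and invariant
to left/right heading. A contiguous run of frames in which exactly one
animal of plausible size is detected forms an *epoch*; any rejected
frame (no animal, several animals, blob outside the pixel-count band,
body and head not separable) ends the current epoch.

Swim bouts are discrete locomotor events: maximal spans where the
instantaneous speed (body-centroid displacement per frame interval,
optionally smoothed by a 3-frame centered average) strictly exceeds
5 mm/s. Each qualifying span is aligned at its speed maximum (t = 0;
earliest frame on ties) and kept if the full −500…+300 ms window fits
inside the epoch. Inter-bout intervals are the sub-threshold spans
between consecutive bouts, shortened by a 100 ms buffer at each end to
absorb detection edge error; bout frequency is the reciprocal of the
buffered duration, and the IBI pitch is the mean pitch over the buffered
interval.

Epochs qualify for analysis when longer than 2.5 s (strict), containing
a maximum speed above 5 mm/s, and passing quality control. The QC rules
are: no frame-to-frame centroid jump above `qc_max_jump_mm` (default
0.5 mm/frame, ≈83 mm/s at 166 Hz — far above genuine fast-bout speeds,
whose distribution reaches ≈28 mm/s at mean + 3 SD, and far below a
chamber-scale identity switch; a threshold below the animal's own top
speed would censor real bouts and bias the speed distribution), fish
length within ±40% of the session median, and no missing frames
(inter-frame gap ≤ 1.5 frame intervals). Every exclusion is logged with
its reason.

## Per-bout features and the four kinematic fits

From each aligned bout: initial pitch (−250 ms), pitch at peak (0 ms),
post-bout pitch (+100 ms), end pitch (+200 ms), sampled at the nearest
grid points; the trajectory as the elevation angle `atan2(dz, |dx|)` of
the displacement between the frames flanking t = 0; net displacement
over the super-threshold span containing t = 0; steering rotation
(initial → 0 ms); steering-related rotation (initial → the time of peak
angular velocity, linearly interpolated because the pitch ramp is
steepest there); righting rotation (0 → +100 ms); attack angle
(trajectory − pitch at peak, exact); trajectory deviation
(trajectory − initial pitch, exact).

The time of peak angular velocity is estimated per experimental repeat:
pitch smoothed by an 11-frame centered average, differentiated, the sign
flipped for bouts whose mean pre-peak (−250…0 ms) angular velocity is
negative (so all bouts start nose-up), the median trace across the
repeat's bouts taken per time point, and the maximum before t = 0
located. A fixed 40 ms lead is used where per-repeat estimation is not
warranted (resampling loops, feature tables at default settings).

The fits, all on raw per-bout / per-IBI points (binned averages exist
for plotting only):

- **Bout timing**: least-squares parabola `f = a(p − b)² + c` of bout
  frequency on IBI pitch. Implemented as the unconstrained quadratic
  least-squares solution reparameterized to vertex form; standard errors
  of (a, b, c) by the delta method from the polynomial covariance. The
  sensitivity `a` is reported in mHz/deg². `c` (baseline rate) is fit
  unconstrained and flagged with a warning if negative.
- **Steering**: OLS of pitch-at-peak (y) on trajectory (x); the slope is
  the steering gain (1 = trajectory fully explained by posture at peak).
- **Fin-body**: bouts at ≥ 7 mm/s; among those, bouts whose steering
  rotation exceeds the 50th percentile *of the kept set* while having a
  negative attack angle are excluded (large rotations without lift are
  deceleration artifacts); then least squares of
  `y = a + h/(1 + e^{−k(x+b)})` with bounds k ∈ [0, 10] deg⁻¹,
  h ∈ [0, 90]°, from 5 data-driven starts (sigmoid least squares is
  multimodal), tolerance 1e-10; best SSE wins. The fin-body ratio is the
  curve's maximal slope, exactly `kh/4`; its variance uses the product
  formula `(E_k²V_h + E_h²V_k + V_kV_h)/16` with the (k, h) variances
  from the fit covariance.
- **Righting**: OLS of righting rotation on initial pitch. The behavior
  is corrective, so the slope is negative; the righting gain is the
  negated slope (equal to its absolute value for corrective fits — a
  non-negative slope is reported with a warning rather than rejected)
  and the set point is the x-intercept, `−intercept/slope`.

Per-repeat analysis fits every parameter within each experimental repeat
and reports mean (SD) across repeats alongside the pooled fit; condition
comparisons are signed percent differences `100·(other/ref − 1)`.

## Resolution and power analysis

For CI width versus sample size, N points (IBIs for sensitivity, bouts
otherwise) are drawn with replacement, the parameter fitted, and the CI
width taken as `2·z_{0.975}·SE` under the normal approximation; 20
resamples per N give a mean ± SD width. For effect sizes, an altered
dataset is built by scaling one coefficient by (1 + fraction) while
keeping the x values and the y residuals (`y_new = f_alt(x) + (y −
f_orig(x))`); for the fin-body curve the fraction is applied to k, so
the maximal slope kh/4 scales by exactly (1 + fraction). Original and
altered datasets are bootstrapped independently (inner_reps = 200 fits
each by default), and Cohen's d = (μ_sim − μ_ori)/σ computed with σ the
SD of *all* fitted values from both groups pooled — note this σ includes
the between-group separation, so d saturates at 2 for fully separated
distributions (classic pooled-within-SD d does not). The whole procedure
repeats outer_reps = 20 times and the mean d is reported. Failed fits
are redrawn and the redraw count reported, so silent bias is visible.
Resampling draws are independent between the original and altered
datasets; paired draws would reduce the variance of d but are not what
the procedure specifies.

## The synthetic-data generator

The generator's defaults are the reference measurement conditions: a
166 Hz acquisition, and per-stage parameter sets (4, 7, 14 dpf) whose
values are the published stage references — e.g. at 7 dpf a steering
gain of 0.67, righting gain 0.18, set point 19.47°, sensitivity
1.06 mHz/deg² with baseline rate 0.51 Hz, fin-body ratio 2.27 with
sigmoid height 10.28°, IBI pitch 8.06 ± 12.66°, and peak speed
12.90 ± 4.91 mm/s with pitch-at-peak 8.48 ± 15.23° (the pooled 7–9 dpf
values). Where a stage's spread is published as an interquartile range,
it is converted to an SD via IQR/1.349 under approximate normality.

**Latent chain (session mode).** Per bout: IBI pitch ~
Normal(μ_p, σ_p); the IBI duration is ε/λ(p) with λ the bout-timing
parabola and ε lognormal with mean exactly 1 (σ = 0.6 by default) —
inverse-rate-times-noise rather than exponential waiting times, so the
expected bout frequency is finite and proportional to λ(p); initial
pitch = IBI pitch + Normal(0, 1°); steering-related rotation ~ Normal
with moments derived from the profile's IBI-pitch and pitch-at-peak
marginals so that pitch_at_peak = initial + 2·(steering-related
rotation) reproduces the stated pitch-at-peak mean and SD; attack angle
= sigmoid(steering-related rotation) + Normal(0, 3.5°); trajectory =
pitch_at_peak + attack angle exactly; righting rotation =
−gain·(initial − set point) + Normal(0, 2°); peak speed from a normal
truncated below at 5 mm/s whose *parent* parameters are solved
numerically so the truncated distribution has the stated observed
moments (recorded bouts are conditioned on exceeding the detection
threshold, so the published moments describe the truncated law).

**Trace construction.** The session is a sequence of epochs separated by
out-of-view gaps (per-bout epoch-break probability 0.05, gap 0.5–1.5 s).
Each bout contributes a raised-cosine speed bump `pk·cos²(πt/W)` with
its peak on the frame grid and width W chosen so the displacement
accumulated above 5 mm/s approximates the stage's bout displacement
(W clipped to 0.12–0.30 s); displacement points along the bout's
trajectory angle, with a per-epoch left/right heading. Pitch is a
piecewise-linear drift toward each bout's initial pitch plus, per bout,
a smooth steering ramp whose angular velocity is a raised-cosine bump
symmetric about the configured lead time before the peak (40 ms at
7 dpf) — hence the factor 2 between total steering rotation and the
rotation completed by the angular-velocity peak — and a righting ramp
completing 100 ms after the peak. Between bouts the fish drifts at
0.3–0.8 mm/s (sub-threshold) so it never parks on one spot, which also
keeps median background estimation honest. Sampled IBI durations are
clipped at 0.4 s so adjacent speed bumps never merge into one
super-threshold span.

**Targeted mode** draws (x, y) pairs directly from one relationship with
`E[y|x]` exactly on the model curve, so a downstream fit recovers the
generating coefficients in expectation. This exists because the four
fitted relationships cannot in general hold simultaneously and exactly
in one causal chain: session mode is for end-to-end pipeline tests and
distribution-level checks, targeted mode for coefficient recovery.
Timing noise in targeted mode is a multiplicative lognormal with mean 1;
note that in *session* mode the measured bout frequency λ/ε has
expectation λ·e^{σ²} > λ, so session-mode timing fits recover the shape
but not the scale of the parabola — another reason recovery tests use
targeted mode.

**Rendering.** Frames are a static noisy background plus an
anti-aliased body ellipse (semi-axes 0.40 L × 0.12 L) and a brighter
head disc (radius 0.13 L) centered half a body length along the pitch
axis; default 400 × 400 px at 0.1 mm/px (desk scale; the full
1200 × 1216 acquisition format is a config away). The sidecar ground
truth stores the coverage-weighted centroids of the painted body and
head regions — the pose an ideal detector would recover — so tracking
error can be measured without conflating it with shape-model mismatch.

**What the generator does not emulate**: swimming kinematics beyond the
latent chain (no hydrodynamics, no tail kinematics, no bout-type
repertoire), multi-animal interaction (a second rendered animal exists
only to exercise rejection), illumination drift, water-surface
reflections, or the dependence of bout timing on angular velocity that
accounts for much of the real residual variance. Passing tests therefore
demonstrate that the *pipeline* measures what the generator encodes —
not that real recordings satisfy the generative assumptions.

## Tracker details

Foreground is the absolute background difference thresholded at the
initial-cut band (polarity-agnostic, since imaging polarity varies),
labeled with 8-connectivity; components under 5 px are noise. Zero
animal-scale components (area ≥ size_low) → frame rejected as empty;
more than one → rejected as multi-animal; one component above size_high
→ rejected as out of range. Head pixels are the blob's pixels whose raw
intensity falls in the head band; body pixels are the remaining blob
pixels in the body band, excluding pixels 8-adjacent to head pixels
(the anti-aliased rim around the head is ambiguous between the parts and
would otherwise drag the body centroid toward the head). Centroids are
intensity-weighted (background-subtracted brightness), which localizes
to ≈0.3 px RMS on noise-free renders; fish length is the blob's extent
along its principal axis. Background estimation is a per-pixel median
over an evenly subsampled stack (or a first-25-frames mean). The named
threshold presets (zebrafish ≤ 12 dpf and juvenile, fly, worm) follow
the standard recording-parameter table for these organisms. Intensity
bands are applied to the raw frame within the foreground mask; applying
them to the background-subtracted image instead is a one-line variant
that would matter only for non-uniform backgrounds.

## Numerical and interface choices

- Raw records: tab-separated, no header, 6-decimal floats, columns
  time / body x, z / head x, z / pitch / epoch id / length, coordinates
  in mm — fixed so golden-file tests are byte-stable and
  locale-independent.
- The 5 mm/s comparison is strictly greater; ties at the bout peak take
  the earliest frame; one bout per super-threshold span (the span
  maximum), since epochs are segmented by bout, not by local maxima.
- Windows: −500/+300 ms extracted; the −250…+200 ms core carries the
  features. Window length is round(0.5·fps) + round(0.3·fps) + 1
  samples.
- Day filtering keeps timestamps inside the 14 h light phase of the
  14/10 light/dark schedule from the session metadata; absent schedule
  → pass-through with a warning.
- All randomness flows through `numpy.random.Generator` seeds; identical
  (inputs, seed) reproduce results bitwise.
- Default problem sizes in the test suite (sessions of minutes to a few
  hours, resampling grids up to N = 8000 with 50 inner replicates) were
  chosen so the full suite exercises every stage at statistically
  meaningful depth; all scale up linearly via configuration.

## Known limitations

- The between-bout pitch-drift law (linear drift plus jitter toward the
  next initial pitch) is a stand-in; no published law exists for it.
- Session-mode pooled fits interact (see targeted mode above); e.g. the
  pooled steering gain of a session reflects the attack-angle variance
  realized by the chain, not the profile's gain parameter alone.
- The tracker handles a single animal per frame by design; overlapping
  animals are rejected, not disambiguated.
- No between-condition hypothesis testing is provided, only descriptive
  percent differences and the resampling resolution analysis.
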