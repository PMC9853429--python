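# Methods

This note documents the models, algorithms and numerical choices behind
`trailgait`, in the order data flows through the package, and states what
the synthetic-study generator does and does not emulate.

## 1. Study design being modeled

Thirty runners complete a 1.57 km trail loop with three sections —
uphill (580 m, mean +4°), technical top (520 m, +2°), downhill (470 m,
−6°) — four times, alternating two closure configurations of the same
shoe (Wrap vs. Lace) in a randomized counterbalanced A-B-B-A block, which
neutralizes familiarization and fatigue trends.  Before each lap the
runner performs three synchronizing hops, then starts the GPS watch and
runs.  A runner whose lap times span more than one minute is excluded
from analysis; the packaged configuration slows one lap of one subject by
2 min 23 s so that exactly one of thirty is excluded, reproducing the
cohort the summary statistics describe (N = 29).

## 2. Sensor model and fusion

The heel-counter IMU records a low-g accelerometer (±16 g, 1125 Hz,
16-bit) and gyroscope (±2000 °/s, 1125 Hz) on one clock, and a high-g
accelerometer (±200 g, 1600 Hz, 13-bit) on its own clock; all samples are
UNIX-timestamped.  Trail-running heel strikes routinely exceed 16 g, so
the low-g channel clips.  Fusion linearly interpolates the high-g stream
onto the low-g timestamps and substitutes it per sample *and per axis*
wherever |low-g| ≥ 16 g − ½ LSB (clipping is a per-channel ADC
phenomenon; the half-LSB margin catches rail-limited codes).  Outside the
high-g time span the nearest high-g sample is used with a warning.  With
no clipping the fused stream equals the low-g stream bitwise.

## 3. Gait events

* **Zero-phase filtering.**  All metric extraction uses forward–backward
  (zero net phase) second-order Butterworth low-passes: 50 Hz for
  acceleration, 30 Hz for the gyroscope (kinematic band; suppresses the
  contact transient in the rate signal).  Two passes square the magnitude
  response, so the gain at the cutoff is 0.50.
* **Hop gate.**  The three hops appear as the first three bursts of
  |‖a‖ − g| above 30 m/s² in the opening minute; the run start is the
  first sample after the third burst settles below 5 m/s².  All metrics
  use samples at or after this gate.
* **Stride segmentation.**  Impacts are peaks of the squared jerk
  magnitude (first difference of fused acceleration × rate, summed over
  axes) exceeding 10 × a centred 2 s rolling median, separated by a
  0.4 s refractory period; candidates below 1 % of the median accepted
  peak are discarded as swing-phase motion.  Each contact is then refined
  backwards from the peak to the transient onset (squared jerk below 2 %
  of the peak, searched ≤ 40 ms) so the whole impact lies inside its own
  stride.  A stride runs contact-to-contact of the instrumented foot.
  Stride times outside 0.4–2.0 s are flagged and excluded from metrics.
  The detector's constants are this package's own specification; the
  idea — jerk-based impact detection — is standard foot-mounted-IMU
  practice.

## 4. Running speed (ZUPT dead reckoning)

Per stride: midstance is the sample of minimum smoothed gyro magnitude
within 25–75 % of the contact-to-contact interval (foot-flat is the
rotational minimum; a 60 ms moving average prevents momentary swing-phase
zero crossings from masquerading as foot-flat).  Orientation is
initialized at midstance from the accelerometer gravity direction (the
foot is quasi-static there, so specific force ≈ gravity) and propagated
by trapezoidal quaternion integration of the gyro.  Heading is
unobservable without a magnetometer and irrelevant: stride length is a
horizontal *norm*.  Gravity (9.81 m/s², configurable) is subtracted in
the aligned frame; velocity is the cumulative trapezoidal integral; a
linear ramp is removed so velocity is exactly zero at both bounding
midstance ZUPT instants (this absorbs any constant accelerometer bias
exactly); displacement integrates the corrected velocity; speed =
horizontal stride length / contact-to-contact stride time.  Integration
windows therefore run midstance-to-midstance while metric windows run
contact-to-contact.  The final stride of a lap has no closing anchor and
is dropped from speed.  Horizontal (rather than 3-D) displacement is the
conventional reading of "running speed" on sloped ground; a 3-D option
exists (`horizontal_only=False`).

On synthetic laps this estimator recovers per-stride speed to ~0.4 % at
the default sensor noise and better than 1 % noise-free.

## 5. Per-stride and per-step metrics

* Peak acceleration and peak jerk: maxima of the 3-axis norms of the
  50 Hz-filtered fused acceleration and of its central-difference time
  derivative, over the stride.
* Mediolateral range: max − min of the mediolateral axis, 50 Hz filtered.
* Peak eversion velocity: the signed maximum toward eversion of the
  30 Hz-filtered frontal-plane gyro channel within the first 20 % of the
  stride after contact.  The sign convention is mirrored by foot side via
  `AxisMap`; the signed (not absolute) peak is reported because "peak
  eversion" names a direction.
* Pressure: stance intervals are detected on total insole force
  (Σ sensel pressure × sensel area).  Candidate contacts/toe-offs come
  from crossings of 5 % of the lap's median per-step peak force; each is
  refined by walking down the force curve from the adjacent
  steepest-gradient frame to the local baseline, stopping when the next
  decrease is below 0.2 % of the median peak (the noise-flat criterion);
  contact is the first loaded frame, toe-off the first baseline frame.
  The heel region is the rear ⌈20 %⌉ of grid rows, the toe region the
  front ⌈20 %⌉ (row 0 is the toe end).  Contact area is the percentage
  of a region's sensels above 2.5 kPa (a typical capacitive noise
  floor), averaged over stance frames; regional peak pressure is the max
  sensel value over stance.

## 6. Course segmentation and QC

The loop is a closed polyline of boundary waypoints (packaged as a
synthetic stand-in geometry with the printed section lengths and slopes;
the study trail's true coordinates are not published).  Each 1 Hz GPS
sample takes the section of its nearest densified course point; because
start and finish coincide spatially, raw nearest-point arc positions are
unwrapped by time continuity so position noise cannot flip a sample onto
the wrong end of the lap.  Section path lengths are haversine sums
(spherical Earth, R = 6371 km — sub-metre ellipsoidal accuracy is
irrelevant at consumer-GPS noise) over consecutive same-label samples.
GPS t = 0 is mapped to the IMU run-start instant (the watch is started
right after the hops); strides and steps inherit the section of their
contact-time GPS sample.  Heart rate is averaged per section per lap.
Lap QC retains a subject iff max − min lap duration ≤ 60 s (the rule is
"greater than one minute excludes", so exactly 60 s is retained).

## 7. Mixed-effects analysis

Outcomes are analyzed per trail section (they are speed-dependent).
Stride- and step-level outcomes use a random-intercept + random-slope
model (`Outcome ~ Config + (Config | Subject)`, correlated effects),
fitted by REML via statsmodels MixedLM; per-lap-section heart rate and
0–10 questionnaire ratings use the random-intercept form.  A variant adds
stride speed as a covariate.  Config is coded with Lace as reference.

* **Optimizer**: lbfgs with bfgs and Powell fallbacks; a fit whose REML
  log-likelihood is non-finite is treated as failed and retried.
  A singular random-slope fit (non-finite SEs or a degenerate 2×2
  random-effects covariance) falls back to the random-intercept form
  with a warning and is flagged in the results.
* **Inference**: the condition effect is tested against a
  t(n_subjects − 1) reference at α = 0.05.  The shoe condition varies
  within subject, so the effect estimate carries essentially one
  independent piece of information per subject; a normal reference is
  anticonservative at small n (simulated Type-I ≈ 7.5 % at 10 subjects),
  while t(m − 1) is near-nominal (≈ 4.4 %).  A plug-in Satterthwaite
  approximation was evaluated and rejected: with few subjects the REML
  slope variance frequently estimates near zero, inflating the effective
  df and the Type-I error (≈ 6.2 %).  At the study's size (29 subjects)
  t(28) and z are indistinguishable.
* **Marginal means**: every observation is predicted under both
  configurations at its observed covariates and the predictions are
  averaged (equivalent to prediction at covariate means for a linear
  model, and equal to emmeans on these designs).  Percent differences
  are always computed from emmeans relative to the Lace emmean, never
  from raw means.

## 8. The synthetic-study generator

The generator's role is to make every pipeline assumption true *by
construction* with known truth, at the published study conditions.

**Outcome truth.**  Each stride/step outcome is drawn hierarchically:
population mean per section and configuration (the published
per-condition summary values), plus a subject intercept
~ N(0, 0.6 × SD), plus (for Wrap) a subject response slope
~ N(0, max(0.5 × |effect|, 0.04 × SD)), plus stride noise
~ N(0, 0.8 × SD), where SD is the printed total spread (0.6² + 0.8² = 1,
so the marginal spread matches the table).  The slope scale encodes
modest inter-individual response heterogeneity, consistent with the
uniformly significant per-section findings.  Per-section speed effects
span the reported 0.03–0.05 m/s band (uphill +0.03, top +0.03, downhill
+0.05).  Strides are laid down sequentially along the loop, so section
stride counts follow from geometry and speed.  Stride time ~ N(0.80 s,
0.04 s) plus a N(0, 0.03 s) subject offset; stride length = speed ×
stride time exactly.

**Waveforms.**  One stride template (contact at phase 0): stance
occupies 0–0.35 with a motionless foot-flat window ending at 0.32;
forward swing velocity is a raised-cosine bump on [0.36, 1] whose
integral is exactly the stride length; vertical lift is a C³ sin⁴ bump
(12 cm); mediolateral motion is a zero-displacement wiggle scaled
analytically so its acceleration range equals the drawn M/L range.  The
true orientation trajectory is frontal-plane roll only: an eversion
burst (sin², 8 % of the stride wide, peaking at the drawn eversion
velocity), an inversion return that cancels its angle, and a mid-swing
oscillation (80 °/s) that keeps the gyro magnitude well above its
foot-flat minimum so the midstance search is unambiguous.  Restricting
the true rotation to one axis keeps sensor-frame synthesis exactly
consistent with the emitted gyro while remaining vectorizable; the
dead-reckoning pipeline still does real work (roll excursions reach
~20°).  Sensor acceleration is the world specific force rotated by this
trajectory.

**Impact transients.**  Heel strikes are a 10 ms sin² pulse plus a
decaying 42 Hz oscillation (ring ratio 1.0, τ = 28 ms) on the sensor
vertical axis.  Printed peak-acceleration values are *post-filter*
measurements, so the generator pre-compensates: at configuration time it
pushes the unit template through the exact measurement chain (1600 Hz
sampling → linear interpolation to 1125 Hz → 50 Hz zero-phase filter)
and scales each stride's raw amplitude so the measured peak equals the
drawn truth.  Peak jerk is emergent from this transient shape (≈ 190 ×
the filtered peak, close to the printed jerk/acceleration ratios) rather
than independently drawn.  Raw amplitudes routinely exceed ±16 g, which
exercises the fusion path; `clipping_fraction` can force or forbid
saturation.  Eversion bursts are pre-compensated the same way against
the 30 Hz filter using a retention-vs-width curve.  The low-g stream is
clipped at ±16 g and quantized to 16 bits, the high-g stream to 13 bits
over ±200 g.  A self-check double-integrates the emitted forward
template of the first stride of every lap and raises if it misses the
true stride length by more than 1 %.

**Pressure.**  During each stance, a drawn number of heel/toe sensels
(stochastically rounded so lap means are unbiased) is loaded above the
detection threshold for the whole stance, one designated sensel carries
the drawn regional peak pressure, and 40 % of midfoot sensels carry a
plausible load; the realized (rounded) areas replace the drawn truth.

**GPS and heart rate.**  The track follows the course at the true
stride speeds with AR(1) position error (stationary SD 2 m, ρ = 0.98 at
1 Hz — consumer-GPS error drifts slowly; white noise would inflate
haversine path sums far beyond what real devices show).  Heart rate is
the per-section mean plus AR(1) noise (SD 2 bpm, ρ = 0.9), rounded to
integers.  Questionnaire ratings are latent-normal draws thresholded to
0–10.

**What the generator does not emulate** (and what passing tests
therefore do not show about real data): terrain-resolved foot placement
and surface irregularity; sagittal/transverse foot rotation (real swing
has large pitch rates, so real orientation propagation is harder than
the frontal-plane model exercises); soft-tissue artifact; physiological
heart-rate dynamics; inter-lap fatigue or environmental drift (laps are
independent); sensor-clock drift between devices (the synthetic streams
share one clock, as the hop-alignment design intends).

## 9. Problem sizes

The packaged study configuration used by `scripts/acceptance.py` and the
study-level tests runs all 30 subjects × 4 laps at the full printed loop
geometry (~700 strides per lap, ~84 000 strides in total), completing in
a few minutes on one CPU.  Unit tests use geometrically scaled loops
(`scale` = 0.05–0.2) for speed; scaling shrinks only the loop, never
speeds, effects, SDs or sensor rates.  Metric-recovery checks
(uphill Wrap lap means) use 24 subjects × 1 Wrap lap on a 160 m
uphill-dominated loop (~1 800 strides), sized so the standard error of
the grand mean is dominated by between-subject spread at roughly the
published cohort's scale.  Type-I calibration uses 500 null replicates
of 10 subjects × 50 strides per condition, drawn directly at the
outcome level.

## 10. Known limitations

* The jerk-detector constants (k = 10, 0.4 s refractory) and the stance
  refinement epsilon are tuned for running; walking or highly irregular
  gait may need different values.
* The orientation propagator is exact for the synthetic single-axis
  rotation; on real data its error grows with swing-phase pitch rate and
  the quality of the midstance gravity estimate.
* Percent heel/toe areas are grid-row-band definitions, not anatomical
  regions; absolute values depend on the insole geometry.
* With very few subjects the random-slope model is frequently singular;
  the intercept-only fallback changes the estimand's uncertainty, and
  results flag when it was used.
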