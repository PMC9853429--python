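# trailgait

Wearable-sensor biomechanics for trail running: from raw foot-mounted IMU,
insole-pressure, GPS and heart-rate streams to per-stride gait metrics,
per-section summaries, and mixed-effects contrasts between two footwear
configurations (a Wrap vs. a Lace closure of the same trail shoe).

The package is written for movement scientists and footwear researchers who
test product "in the wild": subjects run a fixed three-section trail loop
(uphill, technical top, downhill) four times in a randomized
counterbalanced A-B-B-A shoe order, instrumented with

* a heel-counter IMU — low-g accelerometer (±16 g, 1125 Hz, 16 bit),
  high-g accelerometer (±200 g, 1600 Hz, 13 bit) and gyroscope
  (±2000 °/s, 1125 Hz);
* a capacitive pressure insole (sensel grid, 100 Hz);
* a GPS watch with heart rate (1 Hz).

Because the corresponding raw field recordings are not publicly available,
the package ships a first-class synthetic-study generator
(`trailgait.synthetic`) that emulates all of the above — including low-g
saturation at heel strike, midstance zero-velocity windows, injected
condition effects with per-subject random slopes, and the three-hop
synchronization ritual — with exact stride-level ground truth, so every
pipeline stage is testable end to end.

## The pipeline

1. **Fusion** (`sensor_io`): the high-g accelerometer is interpolated onto
   the low-g timestamps and substituted, per sample and axis, wherever the
   low-g channel is railed at ±16 g.
2. **Gait events** (`gait_events`): the three synchronizing hops gate the
   lap; strides are segmented at peaks of the squared jerk magnitude
   ‖da/dt‖², contact to contact; zero-phase (forward–backward) Butterworth
   filters serve all metric extractors (50 Hz for acceleration, 30 Hz for
   the gyroscope).
3. **Speed** (`speed`): per-stride running speed v = L/T by strapdown dead
   reckoning — orientation initialized from the gravity vector at
   midstance (the rotational minimum of the cycle), propagated by gyro
   integration, gravity removed, acceleration double-integrated with a
   linear velocity de-drift anchored on the midstance zero-velocity
   updates (ZUPT), stride length L the horizontal displacement norm.
4. **IMU metrics** (`imu_metrics`): peak acceleration ‖a‖ and peak jerk
   ‖da/dt‖ (loading-rate surrogates), mediolateral acceleration range, and
   the signed peak eversion angular velocity in the first 20 % of the
   stride.
5. **Pressure metrics** (`pressure_metrics`): stance phases from the total
   insole force (threshold crossings refined by gradient descent to the
   local force baseline); heel/toe regions are the rear/front 20 % of grid
   rows; contact area = % of loaded sensels averaged over stance; regional
   peak pressures.
6. **Course** (`course`): GPS samples are matched to the loop by nearest
   boundary-waypoint segment (haversine geometry), every stride and step
   inherits the section of its contact-time GPS sample, heart rate is
   averaged per section, and subjects whose laps differ by more than one
   minute are excluded.
7. **Statistics** (`stats`): statsmodels-style model objects.  For an
   outcome y of subject j in configuration c,

       y ~ Config + (1 | Subject)            (heart rate, ratings)
       y ~ Config + (Config | Subject)       (per-stride/step outcomes)
       y ~ Config + Speed + (Config | Subject)   (speed-adjusted variant)

   fitted by REML, Lace as reference.  Contrasts are estimated-marginal-
   mean (emmean) differences with percent differences relative to the Lace
   emmean; the condition effect is tested at α = 0.05 against a
   t(n_subjects − 1) reference.

## Worked example

```python
import warnings
import numpy as np
from trailgait.pipeline import run_study
from trailgait.stats import analyze_study
from trailgait.synthetic.config import paper_config

cfg = paper_config(scale=0.2, n_subjects=8, seed=3, qc_outlier=False)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    study = run_study(cfg)                      # synthesize + process
    res = analyze_study(study.strides, study.steps, study.hr,
                        study.questionnaire,
                        retained_subjects=study.retained_subjects)
print(res.fits[("peak_eversion_velocity", "uphill")].summary())
```

prints

```
ConditionLMM [random_slope]  outcome: peak_eversion_velocity
  n obs: 1757   subjects: 8   converged: True
  fixed effects:
    Intercept                337.8362  (SE 18.9923)
    Config[Wrap]             -21.8218  (SE 6.7040)
  variance components: intercept_sd=53.2179, residual_sd=76.2679, slope_sd=15.8815, correlation=0.0550
  emmeans: Wrap=316.0144  Lace=337.8362
  contrast: diff=-21.8218  (-6.46%)  p=0.01396  [t(7.0)]
```

Reading: across 1 757 uphill strides from 8 subjects, the Wrap closure
lowered peak eversion velocity by 21.8 °/s (−6.5 % of the Lace marginal
mean of 337.8 °/s), a significant effect (p = 0.014) on top of substantial
between-subject spread (intercept SD 53 °/s) and stride-to-stride noise
(residual SD 76 °/s).  The generator injected a ~16 °/s population effect
for this small cohort; the estimate sits within two standard errors of it.

The same workflow is available from the shell:

```bash
trailgait simulate --seed 1 --scale 0.2 --subjects 8 --out study/
trailgait process  --study study/ --out processed/
trailgait analyze  --processed processed/ --out report/
trailgait report   --results report/
```

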