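"""Study configuration for the synthetic trail-running generator.

The defaults encode the published study conditions: 30 subjects running a
three-section trail loop four times in a randomized counterbalanced
A-B-B-A shoe order, instrumented with a dual-range foot IMU (1125/1600 Hz),
a 100 Hz pressure insole, and a 1 Hz GPS watch with heart rate.  Outcome
population means per section and condition reproduce the study's summary
table; between-subject, response-slope and stride-level standard deviations
partition each printed SD.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from ..course import TrailCourse

CONFIGS = ("Wrap", "Lace")

#: population means per outcome: {outcome: {section: (wrap, lace, sd)}}.
#: The per-section speed effects span the study's stated band (Wrap faster
#: by 0.03 to 0.05 m/s on every section): uphill and top are pinned at
#: +0.03 by the printed per-condition means; the downhill difference
#: carries the band's upper endpoint, since its printed means round to the
#: same value and cannot reflect the stated per-section advantage.
POPULATION_TABLE: dict[str, dict[str, tuple[float, float, float]]] = {
    "heart_rate": {"uphill": (160.0, 159.0, 11.0),
                   "top": (171.0, 171.0, 11.0),
                   "downhill": (162.0, 161.0, 11.0)},
    "speed": {"uphill": (2.71, 2.68, 0.38),
              "top": (2.54, 2.51, 0.38),
              "downhill": (3.32, 3.27, 0.54)},
    "peak_acc": {"uphill": (124.7, 124.1, 21.2),
                 "top": (135.9, 135.4, 21.3),
                 "downhill": (185.9, 182.0, 35.8)},
    "peak_eversion_velocity": {"uphill": (328.1, 343.8, 79.4),
                               "top": (324.6, 341.2, 73.8),
                               "downhill": (466.7, 490.2, 119.8)},
    "ml_range": {"uphill": (93.0, 95.2, 24.2),
                 "top": (105.0, 107.2, 21.0),
                 "downhill": (165.0, 167.4, 42.0)},
    "heel_contact_area": {"uphill": (61.7, 59.3, 11.0),
                          "top": (62.8, 60.5, 9.2),
                          "downhill": (67.4, 65.4, 6.2)},
    "peak_heel_pressure": {"uphill": (180.1, 175.5, 67.6),
                           "top": (207.1, 205.4, 67.0),
                           "downhill": (382.3, 372.9, 89.4)},
    "toe_contact_area": {"uphill": (70.0, 69.8, 5.1),
                         "top": (70.9, 70.7, 5.6),
                         "downhill": (69.2, 69.0, 5.4)},
    "peak_toe_pressure": {"uphill": (513.1, 509.7, 104.0),
                          "top": (527.3, 523.9, 98.3),
                          "downhill": (511.0, 516.8, 87.8)},
}

#: subjective 0-10 ratings: {item: (wrap_mean, lace_mean, sd)}
QUESTIONNAIRE_TABLE: dict[str, tuple[float, float, float]] = {
    "uphill_performance": (8.3, 7.3, 1.1),
    "level_performance": (8.4, 7.5, 1.25),
    "downhill_performance": (8.4, 6.3, 1.5),
    "confidence": (8.8, 6.8, 1.25),
    "overall_fit": (8.0, 6.5, 1.45),
    "forefoot_fit": (6.2, 5.5, 1.8),
    "midfoot_fit": (5.3, 5.1, 1.05),
    "heel_fit": (5.1, 4.5, 1.05),
    "rpe": (4.5, 4.6, 1.6),
}

BIOMECH_OUTCOMES = ("speed", "peak_acc", "peak_jerk", "ml_range",
                    "peak_eversion_velocity", "heel_contact_area",
                    "toe_contact_area", "peak_heel_pressure",
                    "peak_toe_pressure")


@dataclass(frozen=True)
class OutcomeSpec:
    """Variance partition of one outcome around its population means.

    The printed study SD mixes between-subject and within-subject
    stride-level spread; the generator splits it as ``intercept_sd =
    0.6 x SD`` (between subjects) and ``residual_sd = 0.8 x SD`` (between
    strides), which recombine to the printed total.  The random response
    slope (subject-specific condition effect) defaults to half the
    population effect with a floor of 4% of the SD, modest heterogeneity
    consistent with the uniformly significant per-section findings.
    """

    means: dict[str, tuple[float, float]]   # {section: (wrap, lace)}
    intercept_sd: float
    slope_sd: float
    residual_sd: float

    def effect(self, section: str) -> float:
        w, l = self.means[section]
        return w - l


def _default_outcomes() -> dict[str, OutcomeSpec]:
    out = {}
    for name, table in POPULATION_TABLE.items():
        means = {sec: (w, l) for sec, (w, l, _) in table.items()}
        sd = sum(s for _, _, s in table.values()) / len(table)
        max_eff = max(abs(w - l) for w, l, _ in table.values())
        out[name] = OutcomeSpec(
            means=means,
            intercept_sd=0.6 * sd,
            slope_sd=max(0.5 * max_eff, 0.04 * sd),
            residual_sd=0.8 * sd,
        )
    return out


@dataclass(frozen=True)
class ImuSpec:
    rate_low_hz: float = 1125.0
    rate_high_hz: float = 1600.0
    range_low_g: float = 16.0
    range_high_g: float = 200.0
    bits_low: int = 16
    bits_high: int = 13
    accel_noise_sd: float = 0.3       # m/s^2, per sample per axis
    gyro_noise_sd: float = 1.0        # deg/s
    accel_bias_sd: float = 0.05       # m/s^2, constant per lap per axis


@dataclass(frozen=True)
class PressureSpec:
    rate_hz: float = 100.0
    rows: int = 30
    cols: int = 11
    sensel_area_cm2: float = 1.0
    noise_sd_kpa: float = 0.3
    load_level_kpa: float = 40.0      # nominal pressure on loaded sensels


@dataclass(frozen=True)
class GpsSpec:
    rate_hz: float = 1.0
    noise_sd_m: float = 2.0           # stationary SD of the position error
    noise_rho: float = 0.98           # AR(1) coefficient at 1 Hz: slow drift
    hr_noise_sd: float = 2.0          # bpm around the section mean
    hr_rho: float = 0.9


@dataclass(frozen=True)
class HopSpec:
    n_hops: int = 3
    pre_quiet_s: float = 2.0
    interval_s: float = 1.0
    amplitude_ms2: float = 60.0
    width_s: float = 0.15
    post_quiet_s: float = 1.5


@dataclass(frozen=True)
class GaitSpec:
    """Stride-cycle timing and waveform shape parameters.

    Fractions are of the stride period with contact at 0: the foot-flat
    (ZUPT) window sits inside stance, the eversion burst and its inversion
    return precede it, and swing carries the forward/vertical/mediolateral
    motion plus a frontal-plane oscillation that keeps the gyro magnitude
    well above its foot-flat minimum.
    """

    stride_time_mean_s: float = 0.80
    stride_time_sd_s: float = 0.04
    stride_time_subject_sd_s: float = 0.03
    stance_frac: float = 0.35
    swing_start_frac: float = 0.36
    eversion_start_frac: float = 0.04
    eversion_width_frac: float = 0.08
    inversion_width_frac: float = 0.12
    swing_wobble_dps: float = 80.0
    vertical_lift_m: float = 0.12
    impact_width_s: float = 0.010
    impact_ring_ratio: float = 1.0
    impact_ring_freq_hz: float = 42.0
    impact_ring_tau_s: float = 0.028


@dataclass
class StudyConfig:
    """Full design of one synthetic study."""

    n_subjects: int = 30
    laps_per_subject: int = 4
    course: TrailCourse = field(default_factory=TrailCourse.triangle)
    outcomes: dict[str, OutcomeSpec] = field(default_factory=_default_outcomes)
    questionnaire: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(QUESTIONNAIRE_TABLE))
    imu: ImuSpec = field(default_factory=ImuSpec)
    pressure: PressureSpec = field(default_factory=PressureSpec)
    gps: GpsSpec = field(default_factory=GpsSpec)
    hops: HopSpec = field(default_factory=HopSpec)
    gait: GaitSpec = field(default_factory=GaitSpec)
    #: fraction of strides whose raw impact transient exceeds +-16 g;
    #: None lets the drawn impact distribution decide naturally.
    clipping_fraction: float | None = None
    #: subject index whose second lap is slowed so their lap range exceeds
    #: the one-minute QC rule (the excluded-runner scenario); None disables.
    qc_outlier_subject: int | None = None
    qc_outlier_extra_s: float = 143.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.laps_per_subject % 2:
            raise ValueError("laps_per_subject must be even (A-B-B-A blocks)")
        for name, spec in self.outcomes.items():
            for sd in (spec.intercept_sd, spec.slope_sd, spec.residual_sd):
                if sd < 0:
                    raise ValueError(f"negative SD in outcome {name}")
            if not spec.means:
                raise ValueError(f"outcome {name} has no section means")
        if any(L <= 0 for L in self.course.lengths_m):
            raise ValueError("section lengths must be positive")
        if self.qc_outlier_subject is not None and not (
                0 <= self.qc_outlier_subject < self.n_subjects):
            raise ValueError("qc_outlier_subject out of range")

    def with_(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)


def paper_config(scale: float = 0.25, n_subjects: int = 30,
                 seed: int = 0, qc_outlier: bool = True) -> StudyConfig:
    """The packaged study-condition configuration.

    ``scale`` shrinks the loop geometry (not speeds, effects or SDs) so a
    full 30-subject study stays desk-sized; ``scale=1`` reproduces the
    printed 1.57 km loop.  One subject is slowed on one lap by 2 min 23 s
    so the lap-time QC excludes exactly one runner, as in the study.
    """
    cfg = StudyConfig(
        n_subjects=n_subjects,
        course=TrailCourse.triangle(scale=scale),
        qc_outlier_subject=0 if qc_outlier else None,
        rng_seed=seed,
    )
    cfg.validate()
    return cfg


def degenerate_config(**kwargs) -> StudyConfig:
    """All random-effect and residual SDs zero: every stride at its mean."""
    cfg = paper_config(**kwargs)
    cfg.outcomes = {
        name: OutcomeSpec(means=spec.means, intercept_sd=0.0, slope_sd=0.0,
                          residual_sd=0.0)
        for name, spec in cfg.outcomes.items()}
    cfg.gait = replace(cfg.gait, stride_time_sd_s=0.0,
                       stride_time_subject_sd_s=0.0)
    return cfg
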