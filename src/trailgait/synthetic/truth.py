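"""Ground-truth draws for one synthetic subject.

Every stride's true outcome value is drawn hierarchically:

    value = population_mean[section, config]
            + subject_intercept            ~ N(0, intercept_sd)
            + 1[config == Wrap] * subject_slope ~ N(0, slope_sd)
            + stride_noise                 ~ N(0, residual_sd)

so the condition effect, its between-subject heterogeneity, and the
stride-level spread are all known exactly and can be recovered by the
pipeline plus the mixed model.  Strides are laid down sequentially along
the course loop, so per-section stride counts follow from the geometry and
the per-section speeds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CONFIGS, StudyConfig

#: outcomes drawn per stride (IMU side) and per step (pressure side)
STRIDE_OUTCOMES = ("speed", "peak_acc", "ml_range", "peak_eversion_velocity")
STEP_OUTCOMES = ("heel_contact_area", "toe_contact_area",
                 "peak_heel_pressure", "peak_toe_pressure")


@dataclass
class LapTruth:
    """Everything the generator knows about one lap."""

    subject: int
    lap: int
    config: str                      # "Wrap" or "Lace"
    strides: pd.DataFrame            # one row per stride (see columns below)
    hr_section_mean: dict[str, float]
    duration_s: float                # first foot contact to final contact
    t0_unix: float                   # recording start (before the hops)
    run_start_s: float               # t0-relative end of the 3rd hop landing
    first_contact_s: float           # t0-relative time of the first stride

    @property
    def n_strides(self) -> int:
        return len(self.strides)


@dataclass
class GroundTruth:
    """Per-subject simulation truth across all laps."""

    subject: int
    condition_order: list[str]
    laps: list[LapTruth]
    questionnaire: pd.DataFrame      # item, config, rating
    subject_effects: dict = field(default_factory=dict)


def condition_order(rng: np.random.Generator,
                    laps_per_subject: int) -> list[str]:
    """Randomized counterbalanced A-B-B-A block order per subject."""
    first = rng.integers(0, 2)
    a, b = CONFIGS[first], CONFIGS[1 - first]
    block = [a, b, b, a]
    reps = laps_per_subject // 4
    rem = laps_per_subject - 4 * reps
    return (block * reps) + block[:rem]


def generate_subject_kinematics(config: StudyConfig, subject_id: int,
                                rng: np.random.Generator) -> GroundTruth:
    """Draw the full stride-level ground truth for one subject."""
    config.validate()
    if not 0 <= subject_id < config.n_subjects:
        raise ValueError("subject_id out of range")
    gait = config.gait
    order = condition_order(rng, config.laps_per_subject)

    intercepts = {name: rng.normal(0.0, spec.intercept_sd)
                  for name, spec in config.outcomes.items()}
    slopes = {name: rng.normal(0.0, spec.slope_sd)
              for name, spec in config.outcomes.items()}
    t_subj = rng.normal(0.0, gait.stride_time_subject_sd_s)

    dense = config.course
    total_len = dense.total_length_m

    laps: list[LapTruth] = []
    for lap_idx, cond in enumerate(order):
        wrap = 1.0 if cond == "Wrap" else 0.0
        slow_factor = 1.0
        if (config.qc_outlier_subject == subject_id and lap_idx == 1):
            # nominal duration at the section-mean speeds
            spd = config.outcomes["speed"]
            mean_v = np.average(
                [spd.means[s][int(1 - wrap)] for s in dense.labels],
                weights=dense.lengths_m)
            nominal = total_len / mean_v
            slow_factor = nominal / (nominal + config.qc_outlier_extra_s)

        rows = []
        arc = 0.0
        t_contact = 0.0
        while arc < total_len:
            sec = dense.labels[int(dense.section_at(arc))]
            vals = {}
            for name in STRIDE_OUTCOMES + STEP_OUTCOMES:
                spec = config.outcomes[name]
                w, l = spec.means[sec]
                mean = (w if wrap else l) + intercepts[name] + wrap * slopes[name]
                vals[name] = mean + rng.normal(0.0, spec.residual_sd)
            v = max(0.5, vals["speed"]) * slow_factor
            T = max(0.55, min(1.3, gait.stride_time_mean_s + t_subj
                              + rng.normal(0.0, gait.stride_time_sd_s)))
            L = v * T
            vals.update({
                "speed": v,
                "stride_time": T,
                "stride_length": L,
                "t_contact": t_contact,
                "arc_m": arc,
                "section": sec,
                "peak_eversion_velocity": max(50.0,
                                              vals["peak_eversion_velocity"]),
                "peak_acc": max(40.0, vals["peak_acc"]),
                "ml_range": max(10.0, vals["ml_range"]),
                "heel_contact_area": float(np.clip(vals["heel_contact_area"],
                                                   2.0, 100.0)),
                "toe_contact_area": float(np.clip(vals["toe_contact_area"],
                                                  2.0, 100.0)),
                "peak_heel_pressure": max(20.0, vals["peak_heel_pressure"]),
                "peak_toe_pressure": max(20.0, vals["peak_toe_pressure"]),
            })
            rows.append(vals)
            arc += L
            t_contact += T
        strides = pd.DataFrame(rows)
        if len(strides) == 0:
            raise ValueError("empty lap: section geometry too small for one stride")

        hr_spec = config.outcomes["heart_rate"]
        hr_mean = {}
        for sec in dense.labels:
            w, l = hr_spec.means[sec]
            hr_mean[sec] = ((w if wrap else l) + intercepts["heart_rate"]
                            + wrap * slopes["heart_rate"]
                            + rng.normal(0.0, hr_spec.residual_sd * 0.25))

        hp = config.hops
        run_start = (hp.pre_quiet_s + (hp.n_hops - 1) * hp.interval_s
                     + hp.width_s)
        t0 = 1.7e9 + subject_id * 1e5 + lap_idx * 2e4
        laps.append(LapTruth(
            subject=subject_id, lap=lap_idx, config=cond, strides=strides,
            hr_section_mean=hr_mean,
            duration_s=float(t_contact),
            t0_unix=t0,
            run_start_s=run_start,
            first_contact_s=run_start + hp.post_quiet_s,
        ))

    qrows = []
    for item, (wm, lm, sd) in config.questionnaire.items():
        subj_off = rng.normal(0.0, 0.6 * sd)
        for cond in CONFIGS:
            latent = (wm if cond == "Wrap" else lm) + subj_off \
                + rng.normal(0.0, 0.8 * sd)
            qrows.append({"item": item, "config": cond,
                          "rating": int(np.clip(round(latent), 0, 10))})
    questionnaire = pd.DataFrame(qrows)

    return GroundTruth(subject=subject_id, condition_order=order, laps=laps,
                       questionnaire=questionnaire,
                       subject_effects={"intercepts": intercepts,
                                        "slopes": slopes})
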