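"""Lap- and study-level orchestration: fuse, segment, measure, label.

``process_lap`` turns one lap's raw recordings into tidy per-stride and
per-step observation rows; ``run_study`` generates and processes a whole
synthetic study in memory (no disk round-trip); ``process_study`` does the
same from an on-disk bundle written by ``trailgait.synthetic.study``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .course import (TrailCourse, align_streams, assign_sections, lap_qc,
                     section_heart_rate)
from .gait_events import detect_hops, segment_strides
from .imu_metrics import filter_for_metrics, stride_metrics
from .pressure_metrics import lap_step_metrics
from .sensor_io import (GpsHrRecording, ImuRecording, PressureRecording,
                        fuse_accelerometers, read_lap, read_manifest)
from .speed import stride_speeds


@dataclass
class LapResult:
    """Tidy observation tables for one processed lap."""

    strides: pd.DataFrame
    steps: pd.DataFrame
    hr: pd.DataFrame
    duration_s: float
    run_start_time: float
    section_lengths: dict[str, float]
    events: pd.DataFrame | None = None
    status: str = "ok"
    warnings: list[str] = field(default_factory=list)


def process_lap(imu: ImuRecording, pressure: PressureRecording,
                gps: GpsHrRecording, course: TrailCourse,
                meta: dict | None = None) -> LapResult:
    """Run the full single-lap pipeline.

    Fusion -> hop gate -> stride segmentation -> ZUPT speeds -> filtered
    stride metrics -> stance detection and step metrics -> GPS section
    assignment and labeling of every stride/step by its contact-time GPS
    sample -> per-section heart rate.
    """
    meta = meta or {}
    fused = fuse_accelerometers(imu)
    run_start = detect_hops(fused)
    run_start_time = float(imu.t[run_start])
    strides = segment_strides(fused, run_start=run_start)
    fs = fused.rate
    f50, g30 = filter_for_metrics(fused.accel, imu.gyro, fs)
    speeds = stride_speeds(fused, imu.gyro, strides)

    labels, section_lengths = assign_sections(gps, course)
    contact_times = np.array([imu.t[s.contact] for s in strides])
    stride_sections = align_streams(run_start_time, gps, contact_times, labels)

    srows = []
    for s, sp, sec in zip(strides, speeds, stride_sections):
        if not s.qc_pass:
            continue
        m = stride_metrics(s, f50, g30, fs, imu.axis_map)
        srows.append({
            "section": sec,
            "stride_time": s.stride_time,
            "speed": sp.speed if sp.valid else np.nan,
            "stride_length": sp.stride_length if sp.valid else np.nan,
            "peak_acc": m.peak_acc,
            "peak_jerk": m.peak_jerk,
            "ml_range": m.ml_range,
            "peak_eversion_velocity": m.peak_eversion_velocity,
            "t_contact": imu.t[s.contact],
        })
    stride_df = pd.DataFrame(srows)

    step_list = lap_step_metrics(pressure, run_start_time=run_start_time)
    step_times = np.array([pressure.t[st.contact] for st in step_list])
    step_sections = align_streams(run_start_time, gps, step_times, labels) \
        if len(step_list) else np.array([], dtype=object)
    prow = []
    for st, sec in zip(step_list, step_sections):
        prow.append({
            "section": sec,
            "heel_contact_area": st.heel_contact_area,
            "toe_contact_area": st.toe_contact_area,
            "peak_heel_pressure": st.peak_heel_pressure,
            "peak_toe_pressure": st.peak_toe_pressure,
            "t_contact": pressure.t[st.contact],
        })
    step_df = pd.DataFrame(prow)

    hr_rows = [{"section": sec, "heart_rate": val}
               for sec, val in section_heart_rate(gps, labels).items()
               if np.isfinite(val)]
    hr_df = pd.DataFrame(hr_rows)

    for df in (stride_df, step_df, hr_df):
        for key, val in meta.items():
            df[key] = val
    duration = float(gps.t[-1] - gps.t[0]) if len(gps.t) else float("nan")
    from .gait_events import events_table
    return LapResult(strides=stride_df, steps=step_df, hr=hr_df,
                     duration_s=duration, run_start_time=run_start_time,
                     section_lengths=section_lengths,
                     events=events_table(strides, imu.t))


@dataclass
class StudyData:
    """All observation tables of a processed study plus the QC decisions."""

    strides: pd.DataFrame
    steps: pd.DataFrame
    hr: pd.DataFrame
    questionnaire: pd.DataFrame
    lap_meta: pd.DataFrame
    retained_subjects: list
    excluded_subjects: list

    def retained(self) -> "StudyData":
        keep = self.retained_subjects
        return StudyData(
            strides=self.strides[self.strides["subject"].isin(keep)],
            steps=self.steps[self.steps["subject"].isin(keep)],
            hr=self.hr[self.hr["subject"].isin(keep)],
            questionnaire=self.questionnaire[
                self.questionnaire["subject"].isin(keep)]
            if len(self.questionnaire) else self.questionnaire,
            lap_meta=self.lap_meta, retained_subjects=keep,
            excluded_subjects=self.excluded_subjects)


def _apply_qc(lap_meta: pd.DataFrame) -> tuple[list, list]:
    retained, excluded = [], []
    for subj, grp in lap_meta.groupby("subject"):
        ok = grp["status"] == "ok"
        durations = grp.loc[ok, "duration_s"].tolist()
        try:
            keep = lap_qc(durations)
        except ValueError:
            keep = False
        (retained if keep else excluded).append(subj)
    return retained, excluded


def run_study(config, progress: bool = False) -> StudyData:
    """Generate and process a full synthetic study in memory."""
    from .synthetic.truth import generate_subject_kinematics
    from .synthetic.waveforms import synthesize_sensor_streams
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    strides, steps, hr, quest, meta_rows = [], [], [], [], []
    for subj in range(config.n_subjects):
        truth = generate_subject_kinematics(config, subj, rng)
        for lap in truth.laps:
            imu, pressure, gps = synthesize_sensor_streams(lap, config, rng)
            meta = {"subject": subj, "lap": lap.lap, "config": lap.config}
            try:
                res = process_lap(imu, pressure, gps, config.course, meta)
                status, duration = "ok", res.duration_s
                strides.append(res.strides)
                steps.append(res.steps)
                hr.append(res.hr)
            except Exception as exc:  # isolate per-lap failures
                warnings.warn(f"lap failed: subject {subj} lap {lap.lap}: "
                              f"{exc}", stacklevel=2)
                status, duration = "failed", float("nan")
            meta_rows.append({**meta, "status": status,
                              "duration_s": duration})
        q = truth.questionnaire.copy()
        q["subject"] = subj
        quest.append(q)
        if progress:
            print(f"subject {subj + 1}/{config.n_subjects} done")
    lap_meta = pd.DataFrame(meta_rows)
    retained, excluded = _apply_qc(lap_meta)
    return StudyData(strides=pd.concat(strides, ignore_index=True),
                     steps=pd.concat(steps, ignore_index=True),
                     hr=pd.concat(hr, ignore_index=True),
                     questionnaire=pd.concat(quest, ignore_index=True),
                     lap_meta=lap_meta, retained_subjects=retained,
                     excluded_subjects=excluded)


def process_study(study_dir: Path | str,
                  course: TrailCourse | None = None,
                  events_dir: Path | str | None = None) -> StudyData:
    """Process an on-disk study bundle lap by lap, isolating failures.

    ``events_dir`` optionally receives one CSV of stride event indices per
    lap (a debugging aid).
    """
    study_dir = Path(study_dir)
    manifest = read_manifest(study_dir)
    if course is None:
        course = TrailCourse.from_yaml(study_dir / "course.yaml")
    strides, steps, hr, meta_rows = [], [], [], []
    for subj_entry in manifest["subjects"]:
        subj = subj_entry["id"]
        for lap_entry in subj_entry["laps"]:
            meta = {"subject": subj, "lap": lap_entry["lap"],
                    "config": lap_entry["condition"]}
            try:
                imu, pressure, gps = read_lap(study_dir / lap_entry["dir"],
                                              lap_entry)
                res = process_lap(imu, pressure, gps, course, meta)
                status, duration = "ok", res.duration_s
                strides.append(res.strides)
                steps.append(res.steps)
                hr.append(res.hr)
                if events_dir is not None and res.events is not None:
                    ev_out = Path(events_dir)
                    ev_out.mkdir(parents=True, exist_ok=True)
                    res.events.to_csv(
                        ev_out / f"events_sub{subj:02d}_lap"
                                 f"{lap_entry['lap']}.csv", index=False)
            except Exception as exc:
                warnings.warn(f"lap failed: {lap_entry['dir']}: {exc}",
                              stacklevel=2)
                status, duration = "failed", float("nan")
            meta_rows.append({**meta, "status": status,
                              "duration_s": duration})
    if not meta_rows:
        raise ValueError("empty study bundle")
    qpath = study_dir / "questionnaire.csv"
    quest = pd.read_csv(qpath) if qpath.exists() else pd.DataFrame()
    lap_meta = pd.DataFrame(meta_rows)
    retained, excluded = _apply_qc(lap_meta)
    empty = pd.DataFrame()
    return StudyData(
        strides=pd.concat(strides, ignore_index=True) if strides else empty,
        steps=pd.concat(steps, ignore_index=True) if steps else empty,
        hr=pd.concat(hr, ignore_index=True) if hr else empty,
        questionnaire=quest, lap_meta=lap_meta,
        retained_subjects=retained, excluded_subjects=excluded)
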