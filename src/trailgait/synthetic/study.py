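"""On-disk synthetic study bundles.

Layout written by :func:`generate_study`::

    out/
      manifest.json           # seed, design, per-lap condition + directory
      course.yaml             # the course geometry used
      truth.json              # ground-truth archive (per-lap stride tables)
      questionnaire.csv
      sub00/lap0/imu_main.csv      t_unix, ax..az (g), gx..gz (deg/s)
      sub00/lap0/imu_highg.csv     t_unix, ax..az (g)
      sub00/lap0/pressure.csv      t_unix, p_r{i}c{j} (kPa)
      sub00/lap0/track.gpx         GPX 1.1 with heart-rate extension
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..sensor_io import write_gpx, write_imu_csv, write_pressure_csv
from .config import StudyConfig
from .truth import generate_subject_kinematics
from .waveforms import synthesize_sensor_streams


def generate_study(config: StudyConfig, out_dir: Path | str,
                   progress: bool = False) -> dict:
    """Write a full study bundle; returns the manifest dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    config.course.to_yaml(out / "course.yaml")

    manifest = {"seed": int(config.rng_seed),
                "n_subjects": int(config.n_subjects),
                "laps_per_subject": int(config.laps_per_subject),
                "subjects": []}
    truth_doc: dict = {"subjects": []}
    quest_frames = []
    for subj in range(config.n_subjects):
        truth = generate_subject_kinematics(config, subj, rng)
        sub_entry = {"id": subj, "order": truth.condition_order, "laps": []}
        truth_subj = {"id": subj, "laps": []}
        for lap in truth.laps:
            lap_dir = out / f"sub{subj:02d}" / f"lap{lap.lap}"
            lap_dir.mkdir(parents=True, exist_ok=True)
            imu, pressure, gps = synthesize_sensor_streams(lap, config, rng)
            write_imu_csv(imu, lap_dir / "imu_main.csv",
                          lap_dir / "imu_highg.csv")
            write_pressure_csv(pressure, lap_dir / "pressure.csv")
            write_gpx(gps, lap_dir / "track.gpx")
            rel = str(lap_dir.relative_to(out))
            sub_entry["laps"].append({"lap": lap.lap,
                                      "condition": lap.config,
                                      "side": "right", "dir": rel})
            truth_subj["laps"].append(_lap_truth_doc(lap))
        q = truth.questionnaire.copy()
        q["subject"] = subj
        quest_frames.append(q)
        manifest["subjects"].append(sub_entry)
        truth_doc["subjects"].append(truth_subj)
        if progress:
            print(f"wrote subject {subj + 1}/{config.n_subjects}")
    pd.concat(quest_frames, ignore_index=True).to_csv(
        out / "questionnaire.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_doc, fh)
    return manifest


def _lap_truth_doc(lap) -> dict:
    return {"lap": int(lap.lap), "condition": lap.config,
            "duration_s": float(lap.duration_s),
            "run_start_s": float(lap.run_start_s),
            "first_contact_s": float(lap.first_contact_s),
            "t0_unix": float(lap.t0_unix),
            "hr_section_mean": {k: float(v)
                                for k, v in lap.hr_section_mean.items()},
            "strides": lap.strides.round(6).to_dict(orient="list")}


def load_truth(study_dir: Path | str) -> dict:
    with open(Path(study_dir) / "truth.json") as fh:
        return json.load(fh)
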