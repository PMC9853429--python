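"""Shared fixtures: one synthesized lap and its processed products."""
from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lap_config():
    from trailgait.synthetic.config import paper_config
    return paper_config(scale=0.12, n_subjects=2, seed=202, qc_outlier=False)


@pytest.fixture(scope="session")
def lap_bundle(lap_config):
    """One synthesized lap (truth + raw streams) of a non-outlier subject."""
    from trailgait.synthetic.truth import generate_subject_kinematics
    from trailgait.synthetic.waveforms import synthesize_sensor_streams
    rng = np.random.default_rng(lap_config.rng_seed)
    truth = generate_subject_kinematics(lap_config, 0, rng)
    lap = truth.laps[0]
    imu, pressure, gps = synthesize_sensor_streams(lap, lap_config, rng)
    return {"config": lap_config, "truth": truth, "lap": lap,
            "imu": imu, "pressure": pressure, "gps": gps}


@pytest.fixture(scope="session")
def processed_lap(lap_bundle):
    """The same lap run through fusion, hop gating and segmentation."""
    from trailgait.gait_events import detect_hops, segment_strides
    from trailgait.sensor_io import fuse_accelerometers
    fused = fuse_accelerometers(lap_bundle["imu"])
    run_start = detect_hops(fused)
    strides = segment_strides(fused, run_start=run_start)
    return {**lap_bundle, "fused": fused, "run_start": run_start,
            "strides": strides}


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A 2-subject on-disk study bundle (small loop, 2 laps each)."""
    from trailgait.synthetic.config import paper_config
    from trailgait.synthetic.study import generate_study
    cfg = paper_config(scale=0.05, n_subjects=2, seed=11, qc_outlier=False)
    cfg.laps_per_subject = 2
    out = tmp_path_factory.mktemp("study")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = generate_study(cfg, out)
    return {"config": cfg, "dir": out, "manifest": manifest}
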