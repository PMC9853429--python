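"""Per-stride IMU metrics: peak acceleration, peak jerk, M/L range, eversion.

Peak acceleration and jerk are surrogates for vertical loading rate; the
mediolateral acceleration range reflects terrain-induced frontal-plane
motion; peak eversion velocity near foot contact indexes how well the shoe
couples the foot to the midsole.  Acceleration metrics are computed from
the 50 Hz zero-phase-filtered fused signal; eversion from the raw gyroscope
filtered at 30 Hz (kinematic band, transient contact spikes suppressed).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gait_events import Stride, zero_phase_lowpass
from .sensor_io import AxisMap


@dataclass
class StrideMetrics:
    peak_acc: float               # m/s^2, max 3-axis norm over the stride
    peak_jerk: float              # m/s^3, max norm of d/dt filtered accel
    ml_range: float               # m/s^2, max-min of the mediolateral axis
    peak_eversion_velocity: float  # deg/s, signed toward eversion


def peak_acc_jerk(stride: Stride, fused_50hz: np.ndarray,
                  fs: float) -> tuple[float, float]:
    """Peak acceleration-norm and peak jerk-norm over one stride.

    The jerk is the central-difference time derivative of the filtered
    acceleration.  Strides shorter than 3 samples cannot support the
    derivative and raise.
    """
    seg = fused_50hz[stride.start:stride.end]
    if len(seg) < 3:
        raise ValueError("stride shorter than 3 samples")
    peak_acc = float(np.linalg.norm(seg, axis=1).max())
    jerk = np.gradient(seg, 1.0 / fs, axis=0)
    peak_jerk = float(np.linalg.norm(jerk, axis=1).max())
    return peak_acc, peak_jerk


def ml_acceleration_range(stride: Stride, fused_50hz: np.ndarray,
                          axis_map: AxisMap) -> float:
    """Max minus min of the mediolateral filtered acceleration."""
    ml = fused_50hz[stride.start:stride.end, axis_map.mediolateral]
    if ml.size == 0:
        raise ValueError("empty stride")
    return float(ml.max() - ml.min())


def peak_eversion_velocity(stride: Stride, gyro_30hz: np.ndarray,
                           axis_map: AxisMap,
                           window_frac: float = 0.20) -> float:
    """Signed peak eversion rate in the first ``window_frac`` of the stride.

    The window is anchored at foot contact; the frontal-plane channel is
    mirrored by foot side so that eversion is positive regardless of which
    foot carries the sensor.
    """
    n = stride.end - stride.start
    if n < 10:
        raise ValueError("stride too short for the eversion window")
    stop = stride.contact + max(1, int(round(window_frac * n)))
    seg = gyro_30hz[stride.contact:stop, axis_map.frontal]
    return float(np.max(axis_map.eversion_sign * seg))


def stride_metrics(stride: Stride, fused_50hz: np.ndarray,
                   gyro_30hz: np.ndarray, fs: float,
                   axis_map: AxisMap) -> StrideMetrics:
    pa, pj = peak_acc_jerk(stride, fused_50hz, fs)
    return StrideMetrics(
        peak_acc=pa,
        peak_jerk=pj,
        ml_range=ml_acceleration_range(stride, fused_50hz, axis_map),
        peak_eversion_velocity=peak_eversion_velocity(stride, gyro_30hz,
                                                      axis_map),
    )


def filter_for_metrics(fused_accel: np.ndarray, gyro_raw: np.ndarray,
                       fs: float) -> tuple[np.ndarray, np.ndarray]:
    """The two filtered signals the metric extractors consume.

    Acceleration: 50 Hz second-order zero-phase Butterworth.
    Gyroscope: 30 Hz second-order zero-phase Butterworth applied to the
    *raw* gyro (not the 50 Hz product).
    """
    return (zero_phase_lowpass(fused_accel, 50.0, fs),
            zero_phase_lowpass(gyro_raw, 30.0, fs))
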