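"""Sensor-stream synthesis from stride-level ground truth.

Each stride is a smooth analytic template laid on the recording clock:

* forward (anterior) world acceleration is the derivative of a
  raised-cosine swing-velocity bump scaled so the time integral of velocity
  over the stride equals the true stride length exactly;
* the foot is motionless in a foot-flat window inside stance, which makes
  the midstance zero-velocity-update assumption true by construction;
* the true orientation trajectory is a frontal-plane (roll) rotation whose
  rate is the emitted gyro signal: an eversion burst just after contact
  (its peak is the true peak eversion velocity), an inversion return, and a
  mid-swing oscillation that keeps the gyro magnitude well above the
  foot-flat minimum.  Sensor-frame accelerations are the world-frame
  specific force rotated by exactly this trajectory, so the dead-reckoning
  pipeline can undo it;
* heel-strike transients are a short pulse plus a decaying ~42 Hz
  oscillation added on the sensor vertical axis.  Their amplitude is
  pre-compensated for the known measurement chain (1600 Hz sampling,
  linear interpolation to 1125 Hz, 50 Hz zero-phase filtering) so that the
  *measured* peak acceleration matches the drawn truth; transients above
  +-16 g rail the low-g channel, which is clipped and quantized exactly as
  the hardware would.

Pressure frames load a known number of heel/toe sensels through stance so
regional contact areas and peak pressures equal the truth; the GPS track
follows the course loop at the true speeds with slowly drifting (AR(1))
position error; heart rate is the per-section mean plus AR(1) noise.
"""
from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from ..course import TrailCourse
from ..gait_events import zero_phase_lowpass
from ..pressure_metrics import region_masks
from ..sensor_io import (G, HIGH_G_LSB, LOW_G_LSB, AxisMap, GpsHrRecording,
                         ImuRecording, PressureRecording)
from .config import StudyConfig
from .truth import LapTruth


class GeneratorSelfCheckError(RuntimeError):
    """Raised when an emitted template violates its own integral constraint."""


# ---------------------------------------------------------------------------
# measurement-chain calibration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _impact_calibration(fs_low: float, fs_high: float, width_s: float,
                        ring_ratio: float, ring_freq: float,
                        ring_tau: float) -> tuple[float, float]:
    """Peak and jerk of the unit impact template after the measurement chain.

    Returns ``(peak_ratio, jerk_per_unit_amplitude)`` for the compound
    pulse+ringing shape sampled at the high-g rate, interpolated to the
    low-g rate and low-passed at 50 Hz — the exact path a real transient
    takes through the pipeline.  Averaged over crest phases.
    """
    rng = np.random.default_rng(12345)
    peaks, jerks = [], []
    t_hi = np.arange(0, 2.0, 1.0 / fs_high)
    t_lo = np.arange(0, 2.0, 1.0 / fs_low)
    for _ in range(16):
        t0 = 1.0 + rng.uniform(0, 1.0 / fs_low)
        x = _impact_shape(t_hi, t0, width_s, ring_ratio, ring_freq, ring_tau)
        y = zero_phase_lowpass(np.interp(t_lo, t_hi, x), 50.0, fs_low)
        peaks.append(np.max(np.abs(y)))
        jerks.append(np.max(np.abs(np.gradient(y, 1.0 / fs_low))))
    return float(np.mean(peaks)), float(np.mean(jerks))


@lru_cache(maxsize=8)
def _eversion_retention_curve(fs: float) -> tuple[tuple[float, ...],
                                                  tuple[float, ...]]:
    """Peak retention of a sin^2 burst through the 30 Hz zero-phase filter."""
    widths = np.linspace(0.03, 0.14, 12)
    t = np.arange(0, 2.0, 1.0 / fs)
    rets = []
    for w in widths:
        ph = (t - 1.0) / w
        x = np.where((ph >= 0) & (ph < 1),
                     np.sin(np.pi * np.clip(ph, 0, 1)) ** 2, 0.0)
        rets.append(float(zero_phase_lowpass(x, 30.0, fs).max()))
    return tuple(widths), tuple(rets)


def _impact_shape(t, t0, width, ring_ratio, ring_freq, ring_tau):
    ph = (t - t0) / width
    main = np.where((ph >= 0) & (ph < 1),
                    np.sin(np.pi * np.clip(ph, 0, 1)) ** 2, 0.0)
    tr = t - (t0 + width)
    ring = np.where((tr > 0) & (tr < 8 * ring_tau),
                    ring_ratio * np.sin(2 * np.pi * ring_freq * tr)
                    * np.exp(-np.clip(tr, 0, None) / ring_tau), 0.0)
    return main + ring


# unit mediolateral displacement shape f(s) = sin(alpha s) sin^2(pi s) and
# the max-min of its second derivative, used to scale the M/L range
_ML_CYCLES = 3
_ALPHA_ML = 2 * np.pi * _ML_CYCLES


def _ml_second_derivative(s: np.ndarray) -> np.ndarray:
    a = _ALPHA_ML
    return (-a * a * np.sin(a * s) * np.sin(np.pi * s) ** 2
            + 2 * a * np.pi * np.cos(a * s) * np.sin(2 * np.pi * s)
            + 2 * np.pi ** 2 * np.sin(a * s) * np.cos(2 * np.pi * s))


_S_GRID = np.linspace(0.0, 1.0, 2001)
_ML_UNIT_RANGE = float(_ml_second_derivative(_S_GRID).max()
                       - _ml_second_derivative(_S_GRID).min())


# ---------------------------------------------------------------------------
# continuous lap signal
# ---------------------------------------------------------------------------

def _lap_imu_signal(t_rel: np.ndarray, lap: LapTruth, cfg: StudyConfig,
                    eversion_scale: np.ndarray,
                    impact_amp: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the clean sensor-frame accel (m/s^2) and gyro (deg/s).

    ``t_rel`` is seconds from the recording start.  ``eversion_scale`` and
    ``impact_amp`` are per-stride raw amplitudes (already pre-compensated
    for the measurement chain).
    """
    g = cfg.gait
    n = len(t_rel)
    accel_w = np.zeros((n, 3))        # world: x forward, y ML, z up
    roll_rate = np.zeros(n)           # deg/s about the world/sensor x axis
    spike = np.zeros(n)               # sensor-frame vertical transient

    # synchronizing hops on the vertical axis
    hp = cfg.hops
    for k in range(hp.n_hops):
        s0 = hp.pre_quiet_s + k * hp.interval_s
        i0, i1 = np.searchsorted(t_rel, [s0, s0 + hp.width_s])
        ph = (t_rel[i0:i1] - s0) / hp.width_s
        accel_w[i0:i1, 2] += hp.amplitude_ms2 * np.sin(np.pi * ph) ** 2

    sw0, d = g.swing_start_frac, 1.0 - g.swing_start_frac
    strides = lap.strides
    contacts = lap.first_contact_s + strides["t_contact"].to_numpy()
    periods = strides["stride_time"].to_numpy()
    lengths = strides["stride_length"].to_numpy()
    ml_ranges = strides["ml_range"].to_numpy()

    e0, ew = g.eversion_start_frac, g.eversion_width_frac
    iw = g.inversion_width_frac
    for i in range(len(strides)):
        c, T, L = contacts[i], periods[i], lengths[i]
        i0, i1 = np.searchsorted(t_rel, [c, c + T])
        if i1 <= i0:
            continue
        u = (t_rel[i0:i1] - c) / T
        # swing: forward, vertical, mediolateral
        s = np.clip((u - sw0) / d, 0.0, 1.0)
        in_sw = (u >= sw0) & (u < 1.0)
        ax = np.where(in_sw,
                      2 * np.pi * L / (T * d) ** 2 * np.sin(2 * np.pi * s),
                      0.0)
        sin_s, cos_s = np.sin(np.pi * s), np.cos(np.pi * s)
        az = np.where(in_sw,
                      g.vertical_lift_m * 4 * np.pi ** 2 / (d * T) ** 2
                      * (3 * sin_s ** 2 * cos_s ** 2 - sin_s ** 4), 0.0)
        amp_ml = ml_ranges[i] * (d * T) ** 2 / _ML_UNIT_RANGE
        ay = np.where(in_sw, amp_ml / (d * T) ** 2
                      * _ml_second_derivative(s), 0.0)
        accel_w[i0:i1, 0] += ax
        accel_w[i0:i1, 1] += ay
        accel_w[i0:i1, 2] += az
        # frontal-plane rate: eversion burst, inversion return, swing wobble
        ev = np.zeros(len(u))
        ph_e = (u - e0) / ew
        m = (ph_e >= 0) & (ph_e < 1)
        ev[m] += eversion_scale[i] * np.sin(np.pi * ph_e[m]) ** 2
        ph_i = (u - (e0 + ew)) / iw
        m = (ph_i >= 0) & (ph_i < 1)
        ev[m] -= (eversion_scale[i] * ew / iw) * np.sin(np.pi * ph_i[m]) ** 2
        wob = np.where(in_sw, g.swing_wobble_dps
                       * np.sin(2 * np.pi * 2 * s) * sin_s ** 2, 0.0)
        roll_rate[i0:i1] += ev + wob
        # heel-strike transient on the sensor vertical axis
        i2 = min(n, np.searchsorted(t_rel, c + g.impact_width_s
                                    + 8 * g.impact_ring_tau_s))
        spike[i0:i2] += impact_amp[i] * _impact_shape(
            t_rel[i0:i2], c, g.impact_width_s, g.impact_ring_ratio,
            g.impact_ring_freq_hz, g.impact_ring_tau_s)

    # rotate the specific force into the sensor frame by the roll trajectory
    from scipy.integrate import cumulative_trapezoid
    phi = cumulative_trapezoid(np.deg2rad(roll_rate), t_rel, initial=0.0)
    f_x = accel_w[:, 0]
    f_y = accel_w[:, 1]
    f_z = accel_w[:, 2] + G
    cphi, sphi = np.cos(phi), np.sin(phi)
    sens_ml = cphi * f_y + sphi * f_z          # R_x(-phi) applied to (y, z)
    sens_vert = -sphi * f_y + cphi * f_z
    accel_s = np.column_stack([f_x, sens_vert + spike, sens_ml])
    gyro_s = np.column_stack([roll_rate, np.zeros(n), np.zeros(n)])
    return accel_s, gyro_s


def _quantize(x: np.ndarray, lsb: float) -> np.ndarray:
    return np.round(x / lsb) * lsb


def synthesize_sensor_streams(lap: LapTruth, cfg: StudyConfig,
                              rng: np.random.Generator,
                              self_check: bool = True,
                              ) -> tuple[ImuRecording, PressureRecording,
                                         GpsHrRecording]:
    """Emit the three raw sensor streams for one lap of one subject."""
    imu = cfg.imu
    g = cfg.gait
    duration = lap.first_contact_s + lap.duration_s + 1.0
    t_lo = np.arange(0.0, duration, 1.0 / imu.rate_low_hz)
    t_hi = np.arange(0.0, duration, 1.0 / imu.rate_high_hz)

    # pre-compensate per-stride amplitudes for the measurement chain
    peak_ratio, jerk_per_amp = _impact_calibration(
        imu.rate_low_hz, imu.rate_high_hz, g.impact_width_s,
        g.impact_ring_ratio, g.impact_ring_freq_hz, g.impact_ring_tau_s)
    widths, rets = _eversion_retention_curve(imu.rate_low_hz)
    strides = lap.strides
    ev_width_s = g.eversion_width_frac * strides["stride_time"].to_numpy()
    ev_ret = np.interp(ev_width_s, widths, rets)
    eversion_scale = strides["peak_eversion_velocity"].to_numpy() / ev_ret

    impact_amp = (strides["peak_acc"].to_numpy() - G) / peak_ratio
    low_rail = imu.range_low_g * G
    if cfg.clipping_fraction is not None:
        if cfg.clipping_fraction <= 0.0:
            impact_amp = np.minimum(impact_amp, 0.92 * low_rail - G)
        else:
            sat = rng.random(len(impact_amp)) < cfg.clipping_fraction
            impact_amp = np.where(sat, np.maximum(impact_amp, 1.05 * low_rail),
                                  np.minimum(impact_amp, 0.92 * low_rail - G))
        # realized truth replaces the drawn values
        strides = strides.assign(peak_acc=impact_amp * peak_ratio + G)
        lap.strides = strides
    lap.strides = lap.strides.assign(peak_jerk=impact_amp * jerk_per_amp)

    accel_lo, gyro_lo = _lap_imu_signal(t_lo, lap, cfg, eversion_scale,
                                        impact_amp)
    accel_hi, _ = _lap_imu_signal(t_hi, lap, cfg, eversion_scale, impact_amp)

    if self_check and len(strides):
        _template_self_check(lap, cfg, t_lo)

    bias = rng.normal(0.0, imu.accel_bias_sd, size=3)
    accel_lo = accel_lo + bias + rng.normal(0.0, imu.accel_noise_sd,
                                            accel_lo.shape)
    accel_hi = accel_hi + bias + rng.normal(0.0, imu.accel_noise_sd,
                                            accel_hi.shape)
    gyro_lo = gyro_lo + rng.normal(0.0, imu.gyro_noise_sd, gyro_lo.shape)

    accel_low = _quantize(np.clip(accel_lo, -low_rail, low_rail), LOW_G_LSB)
    hi_rail = imu.range_high_g * G
    accel_high = _quantize(np.clip(accel_hi, -hi_rail, hi_rail), HIGH_G_LSB)

    imu_rec = ImuRecording(
        t=lap.t0_unix + t_lo, accel_low=accel_low,
        t_high=lap.t0_unix + t_hi, accel_high=accel_high,
        gyro=gyro_lo, axis_map=AxisMap(side="right"),
        low_g_range_g=imu.range_low_g)

    pressure = _synthesize_pressure(lap, cfg, rng, duration)
    gps = _synthesize_gps(lap, cfg, rng)
    return imu_rec, pressure, gps


def _template_self_check(lap: LapTruth, cfg: StudyConfig,
                         t: np.ndarray, tol: float = 0.01) -> None:
    """Double-integrate the emitted forward template against the truth.

    Rebuilds the clean forward acceleration of the first stride exactly as
    emitted and checks that its trapezoidal double integral reproduces the
    true stride length within ``tol``.
    """
    g = cfg.gait
    from scipy.integrate import cumulative_trapezoid
    row = lap.strides.iloc[0]
    c = lap.first_contact_s + row["t_contact"]
    T, L = row["stride_time"], row["stride_length"]
    i0, i1 = np.searchsorted(t, [c, c + T])
    u = (t[i0:i1] - c) / T
    d = 1.0 - g.swing_start_frac
    s = np.clip((u - g.swing_start_frac) / d, 0.0, 1.0)
    ax = np.where((u >= g.swing_start_frac) & (u < 1.0),
                  2 * np.pi * L / (T * d) ** 2 * np.sin(2 * np.pi * s), 0.0)
    vx = cumulative_trapezoid(ax, t[i0:i1], initial=0.0)
    disp = np.trapezoid(vx, t[i0:i1])
    if abs(disp - L) > tol * L:
        raise GeneratorSelfCheckError(
            f"template displacement {disp:.3f} m != stride length {L:.3f} m")


# ---------------------------------------------------------------------------
# pressure
# ---------------------------------------------------------------------------

def _synthesize_pressure(lap: LapTruth, cfg: StudyConfig,
                         rng: np.random.Generator,
                         duration: float) -> PressureRecording:
    ps = cfg.pressure
    g = cfg.gait
    nt = int(duration * ps.rate_hz)
    t = np.arange(nt) / ps.rate_hz
    rows, cols = ps.rows, ps.cols
    frames = np.clip(rng.normal(0.0, ps.noise_sd_kpa, (nt, rows, cols)),
                     0.0, None)
    heel_mask, toe_mask = region_masks((rows, cols))
    heel_idx = np.flatnonzero(heel_mask.ravel())
    toe_idx = np.flatnonzero(toe_mask.ravel())
    mid_idx = np.flatnonzero(~(heel_mask | toe_mask).ravel())
    # fixed per-lap loading order within each region
    heel_order = rng.permutation(heel_idx)
    toe_order = rng.permutation(toe_idx)
    mid_loaded = rng.permutation(mid_idx)[:int(0.4 * len(mid_idx))]

    strides = lap.strides
    contacts = lap.first_contact_s + strides["t_contact"].to_numpy()
    stance = g.stance_frac * strides["stride_time"].to_numpy()
    flat = frames.reshape(nt, -1)

    realized_heel = np.empty(len(strides))
    realized_toe = np.empty(len(strides))
    for i in range(len(strides)):
        f0 = int(np.ceil(contacts[i] * ps.rate_hz))
        f1 = int(np.floor((contacts[i] + stance[i]) * ps.rate_hz))
        if f1 <= f0 or f1 > nt:
            realized_heel[i] = np.nan
            realized_toe[i] = np.nan
            continue
        tau = (np.arange(f0, f1) - f0) / max(1, (f1 - f0 - 1))
        profile = 0.3 + 0.7 * np.sin(np.pi * tau) ** 2
        plateau = np.clip(1.4 * np.sin(np.pi * tau) ** 2, 0.0, 1.0)
        for region, order, area_col, peak_col, realized in (
                ("heel", heel_order, "heel_contact_area",
                 "peak_heel_pressure", realized_heel),
                ("toe", toe_order, "toe_contact_area",
                 "peak_toe_pressure", realized_toe)):
            target = strides[area_col].iloc[i] / 100.0 * len(order)
            n_load = int(target) + int(rng.random() < (target - int(target)))
            n_load = max(1, min(len(order), n_load))
            realized[i] = 100.0 * n_load / len(order)
            sel = order[:n_load]
            peak = strides[peak_col].iloc[i]
            flat[f0:f1, sel[0]] = np.maximum(peak * plateau,
                                             0.3 * ps.load_level_kpa)
            if n_load > 1:
                flat[f0:f1, sel[1:]] = ps.load_level_kpa * profile[:, None]
        flat[f0:f1, mid_loaded] = 0.75 * ps.load_level_kpa * profile[:, None]
    lap.strides = strides.assign(heel_contact_area=realized_heel,
                                 toe_contact_area=realized_toe)
    return PressureRecording(t=lap.t0_unix + t,
                             frames=flat.reshape(nt, rows, cols),
                             sensel_area_cm2=ps.sensel_area_cm2)


# ---------------------------------------------------------------------------
# GPS + heart rate
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * math.sqrt(max(1.0 - rho * rho, 1e-12))
    eps = rng.normal(0.0, innov_sd, n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return x


def _synthesize_gps(lap: LapTruth, cfg: StudyConfig,
                    rng: np.random.Generator) -> GpsHrRecording:
    gs = cfg.gps
    course: TrailCourse = cfg.course
    strides = lap.strides
    contacts = lap.first_contact_s + strides["t_contact"].to_numpy()
    t_knots = np.concatenate(
        [contacts, [contacts[-1] + strides["stride_time"].iloc[-1]]])
    arc_knots = np.concatenate([strides["arc_m"].to_numpy(),
                                [strides["arc_m"].iloc[-1]
                                 + strides["stride_length"].iloc[-1]]])
    t_end = t_knots[-1]
    t = np.arange(lap.run_start_s, t_end, 1.0 / gs.rate_hz)
    arc = np.interp(t, t_knots, arc_knots, left=0.0)
    lat, lon, ele = course.point_at(np.minimum(arc, course.total_length_m - 1e-6))
    m_per_deg = np.pi * 6_371_000.0 / 180.0
    noise_n = _ar1(rng, len(t), gs.noise_sd_m, gs.noise_rho)
    noise_e = _ar1(rng, len(t), gs.noise_sd_m, gs.noise_rho)
    lat = lat + noise_n / m_per_deg
    lon = lon + noise_e / (m_per_deg * np.cos(np.radians(lat[0])))
    sec_idx = course.section_at(np.minimum(arc, course.total_length_m - 1e-6))
    hr_mean = np.array([lap.hr_section_mean[course.labels[i]]
                        for i in sec_idx])
    hr = np.clip(hr_mean + _ar1(rng, len(t), gs.hr_noise_sd, gs.hr_rho),
                 40.0, 220.0)
    return GpsHrRecording(t=lap.t0_unix + t, lat=lat, lon=lon,
                          elevation=ele, heart_rate=np.round(hr))
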