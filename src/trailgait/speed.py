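"""Per-stride running speed by ZUPT-anchored double integration.

Stride length is obtained by rotating the fused acceleration into a
gravity-aligned frame, removing gravity, integrating twice, and subtracting
a linear velocity ramp so the velocity is exactly zero at the bounding
midstance zero-velocity-update (ZUPT) instants.  Running speed is the
horizontal stride length divided by the contact-to-contact stride time.

Orientation is initialized at midstance from the accelerometer gravity
vector — the foot is quasi-static at foot-flat, so the specific force is
gravity alone — and propagated across the integration window by quaternion
integration of the gyroscope.  Integration windows therefore run midstance
to midstance (the ZUPT anchors), while stride metrics elsewhere use the
contact-to-contact span.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .gait_events import Stride
from .sensor_io import G, FusedAccel

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _propagate_quaternion(q0, gyro_rad, dt):
    """Integrate body rates into world-from-sensor quaternions (w,x,y,z).

    ``q0`` is the orientation at sample 0; sample ``i`` uses the rates
    between samples ``i-1`` and ``i`` (trapezoidal average).
    """
    n = gyro_rad.shape[0]
    out = np.empty((n, 4))
    out[0] = q0
    for i in range(1, n):
        wx = 0.5 * (gyro_rad[i - 1, 0] + gyro_rad[i, 0]) * dt
        wy = 0.5 * (gyro_rad[i - 1, 1] + gyro_rad[i, 1]) * dt
        wz = 0.5 * (gyro_rad[i - 1, 2] + gyro_rad[i, 2]) * dt
        ang = math.sqrt(wx * wx + wy * wy + wz * wz)
        if ang > 1e-14:
            s = math.sin(0.5 * ang) / ang
            dw, dx, dy, dz = math.cos(0.5 * ang), wx * s, wy * s, wz * s
        else:
            dw, dx, dy, dz = 1.0, 0.5 * wx, 0.5 * wy, 0.5 * wz
        aw, ax, ay, az = out[i - 1]
        # q_world_from_sensor(i) = q(i-1) * delta (body-frame increment)
        out[i, 0] = aw * dw - ax * dx - ay * dy - az * dz
        out[i, 1] = aw * dx + ax * dw + ay * dz - az * dy
        out[i, 2] = aw * dy - ax * dz + ay * dw + az * dx
        out[i, 3] = aw * dz + ax * dy - ay * dx + az * dw
        norm = math.sqrt(out[i, 0] ** 2 + out[i, 1] ** 2
                         + out[i, 2] ** 2 + out[i, 3] ** 2)
        for k in range(4):
            out[i, k] /= norm
    return out


def _rotate_by_quaternions(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply world-from-sensor quaternions (n,4 wxyz) to vectors (n,3)."""
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    # rotation matrix rows assembled column-wise; vectorized over samples
    vx, vy, vz = v[:, 0], v[:, 1], v[:, 2]
    rx = (1 - 2 * (y * y + z * z)) * vx + 2 * (x * y - w * z) * vy + 2 * (x * z + w * y) * vz
    ry = 2 * (x * y + w * z) * vx + (1 - 2 * (x * x + z * z)) * vy + 2 * (y * z - w * x) * vz
    rz = 2 * (x * z - w * y) * vx + 2 * (y * z + w * x) * vy + (1 - 2 * (x * x + y * y)) * vz
    return np.stack([rx, ry, rz], axis=1)


class QuasiStaticError(RuntimeError):
    """Raised when no quasi-static midstance window exists in a stride."""


def midstance_index(gyro: np.ndarray, start: int, end: int, fs: float,
                    window: tuple[float, float] = (0.25, 0.75),
                    smooth_s: float = 0.06) -> int:
    """Sample of minimum (smoothed) gyro magnitude within a stride fraction.

    Foot-flat is the rotational minimum of the gait cycle; the magnitude is
    smoothed with a short moving average so momentary zero crossings of the
    swing-phase signal do not masquerade as foot-flat.
    """
    lo = start + int(window[0] * (end - start))
    hi = start + int(window[1] * (end - start))
    if hi - lo < 3:
        raise QuasiStaticError("stride too short for a midstance search")
    mag = np.linalg.norm(gyro[lo:hi], axis=1)
    w = max(1, int(smooth_s * fs))
    kernel = np.ones(w) / w
    smooth = np.convolve(mag, kernel, mode="same")
    return lo + int(np.argmin(smooth))


def world_frame_acceleration(fused_accel: np.ndarray, gyro_deg: np.ndarray,
                             fs: float, anchor: int = 0,
                             gravity: float = G,
                             static_window_s: float = 0.03,
                             vertical_axis: int = 1) -> np.ndarray:
    """Gravity-corrected linear acceleration in a gravity-aligned frame.

    ``anchor`` is the quasi-static sample (midstance) used to initialize
    the orientation: the mean accelerometer vector around it is taken as
    the gravity direction.  The gyroscope propagates the attitude over the
    rest of the window.  Output axes: index 2 is the world vertical (up);
    0 and 1 span the horizontal plane (heading is unobservable without a
    magnetometer and is irrelevant for horizontal norms).
    """
    n = len(fused_accel)
    if not 0 <= anchor < n:
        raise QuasiStaticError("anchor outside window")
    half = max(1, int(static_window_s * fs / 2))
    seg = fused_accel[max(0, anchor - half):min(n, anchor + half + 1)]
    g_dir = seg.mean(axis=0)
    g_norm = np.linalg.norm(g_dir)
    if g_norm < 0.5 * gravity:
        raise QuasiStaticError("no gravity-magnitude specific force at anchor")
    g_dir = g_dir / g_norm
    # initial rotation: sensor gravity direction -> world +z
    zw = np.array([0.0, 0.0, 1.0])
    v = np.cross(g_dir, zw)
    c = float(np.dot(g_dir, zw))
    s = np.linalg.norm(v)
    if s < 1e-12:
        q0 = np.array([1.0, 0.0, 0.0, 0.0]) if c > 0 else \
            np.array([0.0, 1.0, 0.0, 0.0])
    else:
        axis = v / s
        half_ang = 0.5 * math.atan2(s, c)
        q0 = np.concatenate([[math.cos(half_ang)], math.sin(half_ang) * axis])
    gyro_rad = np.deg2rad(gyro_deg)
    dt = 1.0 / fs
    # propagate forward from the anchor and backward to the window start
    q = np.empty((n, 4))
    q[anchor:] = _propagate_quaternion(q0, gyro_rad[anchor:], dt)
    if anchor > 0:
        back = _propagate_quaternion(q0, gyro_rad[anchor::-1], -dt)
        q[:anchor + 1] = back[::-1]
    world = _rotate_by_quaternions(q, fused_accel)
    world[:, 2] -= gravity
    # reorder nothing: world axes are (h1, h2, vertical-up)
    return world


@dataclass
class StrideSpeed:
    """ZUPT-anchored stride length, time and speed for one stride."""

    stride_length: float          # m, horizontal
    stride_time: float            # s, contact to contact
    speed: float                  # m/s = stride_length / stride_time
    drift_correction_magnitude: float  # m/s removed at the closing ZUPT
    valid: bool = True


def stride_speed(world_accel: np.ndarray, fs: float, stride_time: float,
                 horizontal_only: bool = True) -> StrideSpeed:
    """Integrate one midstance-to-midstance window into a stride speed.

    Velocity is the cumulative trapezoidal integral of the world-frame
    acceleration; a linear ramp is subtracted so velocity is exactly zero
    at both window ends (the ZUPT anchors); displacement integrates the
    corrected velocity.  A constant accelerometer bias is absorbed exactly
    by the ramp.
    """
    n = len(world_accel)
    if n < 4:
        return StrideSpeed(math.nan, stride_time, math.nan, math.nan, False)
    dt = 1.0 / fs
    vel = cumulative_trapezoid(world_accel, dx=dt, axis=0, initial=0.0)
    drift = vel[-1].copy()
    ramp = np.linspace(0.0, 1.0, n)[:, None] * drift[None, :]
    vel -= ramp
    disp = np.trapezoid(vel, dx=dt, axis=0)
    if horizontal_only:
        length = float(math.hypot(disp[0], disp[1]))
    else:
        length = float(np.linalg.norm(disp))
    return StrideSpeed(stride_length=length, stride_time=stride_time,
                       speed=length / stride_time,
                       drift_correction_magnitude=float(np.linalg.norm(drift)))


def stride_speeds(fused: FusedAccel, gyro: np.ndarray, strides: list[Stride],
                  gravity: float = G,
                  horizontal_only: bool = True) -> list[StrideSpeed]:
    """Per-stride speeds for a lap.

    For stride *i* (contact *i* to contact *i+1*) the integration window
    runs from the midstance of stride *i* to the midstance of stride *i+1*
    so both ends are ZUPT anchors; the window contains exactly one swing.
    The final stride of a lap has no closing midstance and is marked
    invalid.
    """
    fs = fused.rate
    out: list[StrideSpeed] = []
    mids: list[int | None] = []
    for s in strides:
        try:
            mids.append(midstance_index(gyro, s.start, s.end, fs))
        except QuasiStaticError:
            mids.append(None)
    for i, s in enumerate(strides):
        m0 = mids[i]
        m1 = mids[i + 1] if i + 1 < len(strides) else None
        if m0 is None or m1 is None:
            out.append(StrideSpeed(math.nan, s.stride_time, math.nan,
                                   math.nan, False))
            continue
        try:
            world = world_frame_acceleration(
                fused.accel[m0:m1 + 1], gyro[m0:m1 + 1], fs, anchor=0,
                gravity=gravity)
        except QuasiStaticError:
            out.append(StrideSpeed(math.nan, s.stride_time, math.nan,
                                   math.nan, False))
            continue
        out.append(stride_speed(world, fs, s.stride_time,
                                horizontal_only=horizontal_only))
    return out
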