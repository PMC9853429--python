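"""Raw sensor containers, file dialects, and dual-range accelerometer fusion.

The foot-mounted IMU records a low-g accelerometer (±16 g, 1125 Hz, 16 bit)
together with the gyroscope (±2000 °/s, 1125 Hz) on one time base, and a
high-g accelerometer (±200 g, 1600 Hz, 13 bit) on its own time base.  Hard
heel strikes on technical terrain routinely rail the low-g channel, so the
two accelerometers are fused: the high-g stream is linearly interpolated
onto the low-g timestamps and substituted, per sample and per axis, wherever
the low-g channel sits at its rail.
"""
from __future__ import annotations

import json
import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: standard gravity used throughout (m/s^2 per g); configurable in the ops
#: that consume it.
G = 9.81

#: quantization step of the low-g accelerometer: 16-bit codes over +-16 g.
LOW_G_LSB = 32.0 * G / 2**16
#: quantization step of the high-g accelerometer: 13-bit codes over +-200 g.
HIGH_G_LSB = 400.0 * G / 2**13


class SensorLoadError(RuntimeError):
    """Raised when a raw sensor file fails validation."""


@dataclass(frozen=True)
class AxisMap:
    """Column convention of the IMU streams and the foot side.

    Accelerometer/gyroscope arrays are ``(n, 3)`` with columns
    ``(anterior, vertical, mediolateral)``; gyroscope column ``frontal``
    measures frontal-plane (roll about the anterior axis) angular rate.
    """

    anterior: int = 0
    vertical: int = 1
    mediolateral: int = 2
    frontal: int = 0
    side: str = "right"

    @property
    def eversion_sign(self) -> float:
        """Sign that maps the frontal gyro channel to 'eversion positive'.

        A right foot everts with positive roll about the anterior axis under
        this convention; the left foot mirrors.
        """
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown foot side {self.side!r}")
        return 1.0 if self.side == "right" else -1.0


@dataclass
class ImuRecording:
    """One lap of foot-mounted IMU data in SI units (m/s^2, deg/s)."""

    t: np.ndarray                 # unix seconds, low-g/gyro time base
    accel_low: np.ndarray         # (n, 3) m/s^2, clipped at +-16 g
    t_high: np.ndarray            # unix seconds, high-g time base
    accel_high: np.ndarray        # (m, 3) m/s^2
    gyro: np.ndarray              # (n, 3) deg/s
    axis_map: AxisMap = field(default_factory=AxisMap)
    low_g_range_g: float = 16.0

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def rate_high(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t_high)))

    def validate(self, nominal_rate: float = 1125.0,
                 nominal_rate_high: float = 1600.0,
                 rate_tol: float = 0.01) -> None:
        for name, tt in (("low-g", self.t), ("high-g", self.t_high)):
            if np.any(np.diff(tt) <= 0):
                raise SensorLoadError(f"non-monotone timestamps in {name} stream")
        if abs(self.rate - nominal_rate) > rate_tol * nominal_rate:
            raise SensorLoadError(
                f"low-g sample rate {self.rate:.1f} Hz outside "
                f"{rate_tol:.0%} of nominal {nominal_rate} Hz")
        if abs(self.rate_high - nominal_rate_high) > rate_tol * nominal_rate_high:
            raise SensorLoadError(
                f"high-g sample rate {self.rate_high:.1f} Hz outside "
                f"{rate_tol:.0%} of nominal {nominal_rate_high} Hz")
        limit = self.low_g_range_g * G + LOW_G_LSB
        if np.any(np.abs(self.accel_low) > limit):
            raise SensorLoadError("low-g samples exceed the +-16 g range")
        if self.accel_low.shape != self.gyro.shape:
            raise SensorLoadError("gyro and low-g accel must share a time base")


@dataclass
class FusedAccel:
    """Low-g acceleration with saturated samples replaced from the high-g unit."""

    t: np.ndarray
    accel: np.ndarray             # (n, 3) m/s^2
    substituted: np.ndarray       # (n, 3) bool

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class PressureRecording:
    """Plantar pressure frames on a fixed sensel grid at ~100 Hz.

    Grid row index 0 is the toe end of the insole; the heel occupies the
    last rows.
    """

    t: np.ndarray                 # unix seconds per frame
    frames: np.ndarray            # (n_frames, rows, cols) kPa
    sensel_area_cm2: float = 1.0

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def validate(self, nominal_rate: float = 100.0, rate_tol: float = 0.01) -> None:
        if np.any(self.frames < 0):
            raise SensorLoadError("negative pressures in recording")
        if abs(self.rate - nominal_rate) > rate_tol * nominal_rate:
            raise SensorLoadError(
                f"pressure frame rate {self.rate:.1f} Hz outside "
                f"{rate_tol:.0%} of nominal {nominal_rate} Hz")

    def total_force(self) -> np.ndarray:
        """Total insole force per frame in newtons (kPa * m^2 -> kN -> N)."""
        area_m2 = self.sensel_area_cm2 * 1e-4
        return self.frames.sum(axis=(1, 2)) * area_m2 * 1e3


@dataclass
class GpsHrRecording:
    """1 Hz GPS track with synchronously recorded heart rate."""

    t: np.ndarray                 # unix seconds
    lat: np.ndarray               # deg
    lon: np.ndarray               # deg
    elevation: np.ndarray         # m
    heart_rate: np.ndarray        # bpm

    def validate(self, nominal_rate: float = 1.0, rate_tol: float = 0.05) -> None:
        dt = np.median(np.diff(self.t))
        if abs(1.0 / dt - nominal_rate) > rate_tol * nominal_rate:
            raise SensorLoadError("GPS stream is not ~1 Hz")
        hr = self.heart_rate[np.isfinite(self.heart_rate)]
        if hr.size and (hr.min() < 30 or hr.max() > 230):
            raise SensorLoadError("heart rate outside the plausible 30-230 bpm band")


# ---------------------------------------------------------------------------
# accelerometer fusion
# ---------------------------------------------------------------------------

def fuse_accelerometers(rec: ImuRecording,
                        saturation_threshold_g: float = 16.0) -> FusedAccel:
    """Merge the dual-range accelerometers into one unsaturated stream.

    The high-g stream is linearly interpolated onto the low-g timestamps.
    Per sample and per axis the output takes the interpolated high-g value
    iff the low-g magnitude is at or above the saturation threshold (minus
    half a quantization step, to catch rail-limited codes); elsewhere the
    low-g sample passes through untouched.  Outside the high-g time span the
    nearest high-g sample is used, with a warning.
    """
    t, t_hi = rec.t, rec.t_high
    if t_hi[0] > t[-1] or t_hi[-1] < t[0]:
        raise SensorLoadError("high-g and low-g streams do not overlap in time")
    thresh = saturation_threshold_g * G - LOW_G_LSB / 2.0
    mask = np.abs(rec.accel_low) >= thresh
    hi = np.empty_like(rec.accel_low)
    for k in range(3):
        # np.interp holds edge values, i.e. nearest-sample fallback at gaps
        hi[:, k] = np.interp(t, t_hi, rec.accel_high[:, k])
    if mask.any() and (t[mask.any(axis=1)].min() < t_hi[0]
                       or t[mask.any(axis=1)].max() > t_hi[-1]):
        warnings.warn("saturated low-g sample outside high-g span; "
                      "nearest high-g sample substituted", stacklevel=2)
    fused = np.where(mask, hi, rec.accel_low)
    return FusedAccel(t=t, accel=fused, substituted=mask)


# ---------------------------------------------------------------------------
# CSV / GPX dialects (as written by trailgait.synthetic.study)
# ---------------------------------------------------------------------------

IMU_MAIN_COLUMNS = ["t_unix", "ax", "ay", "az", "gx", "gy", "gz"]
IMU_HIGH_COLUMNS = ["t_unix", "ax", "ay", "az"]


def _dedup_time(t: np.ndarray, *arrays: np.ndarray, label: str = "stream"):
    """Drop repeated timestamps (keep first); error on decreasing time."""
    d = np.diff(t)
    if np.any(d < 0):
        raise SensorLoadError(f"non-monotone timestamps in {label}")
    if np.any(d == 0):
        keep = np.concatenate([[True], d > 0])
        warnings.warn(f"{label}: dropped {int((~keep).sum())} duplicated "
                      "timestamp(s)", stacklevel=3)
        return (t[keep],) + tuple(a[keep] for a in arrays)
    return (t,) + tuple(arrays)


def read_imu_csv(main_path: Path | str, high_path: Path | str,
                 axis_map: AxisMap | None = None,
                 column_map: dict[str, str] | None = None) -> ImuRecording:
    """Read the low-g+gyro CSV and the high-g CSV.

    Accelerations are stored in g and converted to m/s^2 here; gyro columns
    are deg/s.  ``column_map`` renames columns of real exports onto the
    packaged dialect.
    """
    main = pd.read_csv(main_path)
    high = pd.read_csv(high_path)
    if column_map:
        main = main.rename(columns=column_map)
        high = high.rename(columns=column_map)
    for df, cols, path in ((main, IMU_MAIN_COLUMNS, main_path),
                           (high, IMU_HIGH_COLUMNS, high_path)):
        missing = set(cols) - set(df.columns)
        if missing:
            raise SensorLoadError(f"{path}: missing columns {sorted(missing)}")
    t, alow, gyro = _dedup_time(
        main["t_unix"].to_numpy(float),
        main[["ax", "ay", "az"]].to_numpy(float) * G,
        main[["gx", "gy", "gz"]].to_numpy(float),
        label="low-g IMU CSV")
    t_hi, ahigh = _dedup_time(
        high["t_unix"].to_numpy(float),
        high[["ax", "ay", "az"]].to_numpy(float) * G,
        label="high-g IMU CSV")
    return ImuRecording(t=t, accel_low=alow, t_high=t_hi, accel_high=ahigh,
                        gyro=gyro, axis_map=axis_map or AxisMap())


def write_imu_csv(rec: ImuRecording, main_path: Path | str,
                  high_path: Path | str) -> None:
    main = pd.DataFrame({"t_unix": rec.t,
                         "ax": rec.accel_low[:, 0] / G,
                         "ay": rec.accel_low[:, 1] / G,
                         "az": rec.accel_low[:, 2] / G,
                         "gx": rec.gyro[:, 0],
                         "gy": rec.gyro[:, 1],
                         "gz": rec.gyro[:, 2]})
    main.to_csv(main_path, index=False, float_format="%.6f")
    high = pd.DataFrame({"t_unix": rec.t_high,
                         "ax": rec.accel_high[:, 0] / G,
                         "ay": rec.accel_high[:, 1] / G,
                         "az": rec.accel_high[:, 2] / G})
    high.to_csv(high_path, index=False, float_format="%.6f")


def read_pressure_csv(path: Path | str) -> PressureRecording:
    """Frame-major pressure CSV: column ``t_unix`` then ``p_r{i}c{j}`` in kPa."""
    df = pd.read_csv(path)
    if "t_unix" not in df.columns:
        raise SensorLoadError(f"{path}: missing t_unix column")
    pcols = [c for c in df.columns if c.startswith("p_r")]
    if not pcols:
        raise SensorLoadError(f"{path}: no sensel columns (p_r*c*)")
    rows = max(int(c.split("c")[0][3:]) for c in pcols) + 1
    cols = max(int(c.split("c")[1]) for c in pcols) + 1
    order = [f"p_r{i}c{j}" for i in range(rows) for j in range(cols)]
    missing = set(order) - set(pcols)
    if missing:
        raise SensorLoadError(f"{path}: ragged sensel grid")
    t = df["t_unix"].to_numpy(float)
    frames = df[order].to_numpy(float).reshape(len(df), rows, cols)
    t, frames = _dedup_time(t, frames, label="pressure CSV")
    return PressureRecording(t=t, frames=frames)


def write_pressure_csv(rec: PressureRecording, path: Path | str) -> None:
    rows, cols = rec.grid_shape
    names = [f"p_r{i}c{j}" for i in range(rows) for j in range(cols)]
    df = pd.DataFrame(rec.frames.reshape(len(rec.t), -1), columns=names)
    df.insert(0, "t_unix", rec.t)
    df.to_csv(path, index=False, float_format="%.2f")


_GPX_NS = "http://www.topografix.com/GPX/1/1"
_TPX_NS = "http://www.garmin.com/xmlschemas/TrackPointExtension/v1"


def write_gpx(rec: GpsHrRecording, path: Path | str) -> None:
    """Write a GPX 1.1 track with the Garmin heart-rate extension."""
    ET.register_namespace("", _GPX_NS)
    ET.register_namespace("gpxtpx", _TPX_NS)
    gpx = ET.Element(f"{{{_GPX_NS}}}gpx", version="1.1", creator="trailgait")
    seg = ET.SubElement(ET.SubElement(gpx, f"{{{_GPX_NS}}}trk"),
                        f"{{{_GPX_NS}}}trkseg")
    for i in range(len(rec.t)):
        pt = ET.SubElement(seg, f"{{{_GPX_NS}}}trkpt",
                           lat=f"{rec.lat[i]:.7f}", lon=f"{rec.lon[i]:.7f}")
        ET.SubElement(pt, f"{{{_GPX_NS}}}ele").text = f"{rec.elevation[i]:.2f}"
        ET.SubElement(pt, f"{{{_GPX_NS}}}time").text = (
            pd.Timestamp(rec.t[i], unit="s", tz="UTC").isoformat())
        ext = ET.SubElement(pt, f"{{{_GPX_NS}}}extensions")
        tpx = ET.SubElement(ext, f"{{{_TPX_NS}}}TrackPointExtension")
        ET.SubElement(tpx, f"{{{_TPX_NS}}}hr").text = f"{rec.heart_rate[i]:.0f}"
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="utf-8")


def read_gpx(path: Path | str) -> GpsHrRecording:
    root = ET.parse(path).getroot()
    pts = root.findall(f".//{{{_GPX_NS}}}trkpt")
    if not pts:
        raise SensorLoadError(f"{path}: no track points")
    t, lat, lon, ele, hr = [], [], [], [], []
    for pt in pts:
        lat.append(float(pt.get("lat")))
        lon.append(float(pt.get("lon")))
        e = pt.find(f"{{{_GPX_NS}}}ele")
        ele.append(float(e.text) if e is not None else math.nan)
        tm = pt.find(f"{{{_GPX_NS}}}time")
        t.append(pd.Timestamp(tm.text).timestamp() if tm is not None else math.nan)
        h = pt.find(f".//{{{_TPX_NS}}}hr")
        hr.append(float(h.text) if h is not None else math.nan)
    return GpsHrRecording(t=np.asarray(t), lat=np.asarray(lat),
                          lon=np.asarray(lon), elevation=np.asarray(ele),
                          heart_rate=np.asarray(hr))


def read_lap(lap_dir: Path | str, manifest_entry: dict | None = None,
             axis_map: AxisMap | None = None,
             ) -> tuple[ImuRecording, PressureRecording, GpsHrRecording]:
    """Load and validate one lap directory written by the study generator."""
    lap_dir = Path(lap_dir)
    entry = manifest_entry or {}
    side = entry.get("side", "right")
    amap = axis_map or AxisMap(side=side)
    for name in ("imu_main.csv", "imu_highg.csv", "pressure.csv", "track.gpx"):
        if not (lap_dir / name).exists():
            raise SensorLoadError(f"{lap_dir}: missing {name}")
    imu = read_imu_csv(lap_dir / "imu_main.csv", lap_dir / "imu_highg.csv",
                       axis_map=amap)
    imu.validate()
    pressure = read_pressure_csv(lap_dir / "pressure.csv")
    pressure.validate()
    gps = read_gpx(lap_dir / "track.gpx")
    gps.validate()
    return imu, pressure, gps


def read_manifest(study_dir: Path | str) -> dict:
    with open(Path(study_dir) / "manifest.json") as fh:
        return json.load(fh)
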