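"""GPS course segmentation, per-section heart rate, and lap-time QC.

The trail loop has three sections — uphill, top (technical), downhill —
whose boundaries are fixed waypoints.  Every 1 Hz GPS sample is assigned to
the section of its nearest point on the course polyline; per-section path
lengths are haversine sums over consecutive samples.  Subjects whose
condition laps differ by more than one minute are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .sensor_io import GpsHrRecording

EARTH_RADIUS_M = 6_371_000.0
SECTION_LABELS = ("uphill", "top", "downhill")


def haversine_m(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_M):
    """Great-circle distance in metres on a spherical Earth (vectorized)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(a))


@dataclass
class TrailCourse:
    """Closed three-section loop defined by boundary waypoints.

    ``waypoints`` holds the four boundary coordinates (start of uphill, of
    top, of downhill, and back to start) as ``(lat, lon, elevation)``; the
    loop closes from the last waypoint back to the first.
    """

    waypoints: np.ndarray            # (4, 3): lat, lon, elevation
    labels: tuple[str, ...] = SECTION_LABELS
    lengths_m: tuple[float, ...] = (580.0, 520.0, 470.0)
    slopes_deg: tuple[float, ...] = (4.0, 2.0, -6.0)
    name: str = "synthetic-trail-loop"
    _dense: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.waypoints = np.asarray(self.waypoints, float)
        if self.waypoints.shape[0] != len(self.labels) + 1:
            raise ValueError("need one boundary waypoint per section plus closure")

    # -- construction -------------------------------------------------

    @classmethod
    def triangle(cls, origin: tuple[float, float] = (39.6530, -105.1920),
                 lengths_m: tuple[float, float, float] = (580.0, 520.0, 470.0),
                 slopes_deg: tuple[float, float, float] = (4.0, 2.0, -6.0),
                 origin_elevation: float = 1900.0,
                 scale: float = 1.0) -> "TrailCourse":
        """Closed triangular loop with the given leg lengths (scaled).

        The three legs are laid out counter-clockwise in a local tangent
        plane at ``origin`` and converted to latitude/longitude on the
        spherical Earth.  Elevation follows each leg's mean slope (the
        printed slopes do not close the loop exactly; the residual is a
        property of the published description, not of this construction).
        """
        a, b, c = (L * scale for L in lengths_m)
        # triangle with P0=(0,0), P1=(a,0), |P1P2|=b, |P2P0|=c
        x2 = (a * a + c * c - b * b) / (2 * a)
        y2 = float(np.sqrt(max(c * c - x2 * x2, 0.0)))
        xy = np.array([[0.0, 0.0], [a, 0.0], [x2, y2], [0.0, 0.0]])
        lat0, lon0 = origin
        m_per_deg = np.pi * EARTH_RADIUS_M / 180.0
        lat = lat0 + xy[:, 1] / m_per_deg
        lon = lon0 + xy[:, 0] / (m_per_deg * np.cos(np.radians(lat0)))
        ele = origin_elevation + np.concatenate(
            [[0.0], np.cumsum([L * np.tan(np.radians(s))
                               for L, s in zip((a, b, c), slopes_deg)])])
        wpts = np.column_stack([lat, lon, ele])
        return cls(waypoints=wpts,
                   lengths_m=tuple(float(L) for L in (a, b, c)),
                   slopes_deg=tuple(slopes_deg))

    @classmethod
    def packaged(cls) -> "TrailCourse":
        """The packaged synthetic stand-in for the study's trail loop.

        The published boundary coordinates are not available; this closed
        loop reproduces the printed section lengths and mean slopes near
        the study location.
        """
        from importlib.resources import files
        return cls.from_yaml(files("trailgait.data") / "course_synthetic.yaml")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "TrailCourse":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        wpts = np.array([[w["lat"], w["lon"], w.get("elevation", 0.0)]
                         for w in doc["waypoints"]])
        return cls(waypoints=wpts,
                   labels=tuple(doc.get("labels", SECTION_LABELS)),
                   lengths_m=tuple(doc.get("lengths_m", (580.0, 520.0, 470.0))),
                   slopes_deg=tuple(doc.get("slopes_deg", (4.0, 2.0, -6.0))),
                   name=doc.get("name", "course"))

    def to_yaml(self, path: Path | str) -> None:
        doc = {
            "name": self.name,
            "labels": list(self.labels),
            "lengths_m": [float(x) for x in self.lengths_m],
            "slopes_deg": [float(x) for x in self.slopes_deg],
            "waypoints": [{"lat": float(w[0]), "lon": float(w[1]),
                           "elevation": float(w[2])} for w in self.waypoints],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    # -- geometry helpers ---------------------------------------------

    @property
    def total_length_m(self) -> float:
        return float(sum(self.lengths_m))

    def _local_xy(self, lat, lon):
        """Equirectangular projection to metres around the course start."""
        lat0, lon0 = self.waypoints[0, 0], self.waypoints[0, 1]
        m_per_deg = np.pi * EARTH_RADIUS_M / 180.0
        x = (np.asarray(lon) - lon0) * m_per_deg * np.cos(np.radians(lat0))
        y = (np.asarray(lat) - lat0) * m_per_deg
        return x, y

    def densify(self, step_m: float = 2.0):
        """Points every ~step_m along the loop with arc position and label."""
        key = round(step_m, 3)
        if key not in self._dense:
            xw, yw = self._local_xy(self.waypoints[:, 0], self.waypoints[:, 1])
            pts, arcs, labs = [], [], []
            s0 = 0.0
            for i in range(len(self.labels)):
                p0 = np.array([xw[i], yw[i]])
                p1 = np.array([xw[i + 1], yw[i + 1]])
                seg_len = float(np.linalg.norm(p1 - p0))
                n = max(2, int(np.ceil(seg_len / step_m)))
                frac = np.linspace(0.0, 1.0, n, endpoint=False)
                pts.append(p0[None, :] + frac[:, None] * (p1 - p0)[None, :])
                arcs.append(s0 + frac * seg_len)
                labs.append(np.full(n, i, dtype=int))
                s0 += seg_len
            self._dense[key] = (np.vstack(pts), np.concatenate(arcs),
                                np.concatenate(labs), s0)
        return self._dense[key]

    def point_at(self, arc_m: np.ndarray):
        """(lat, lon, elevation) at arc positions along the loop (wraps)."""
        xw, yw = self._local_xy(self.waypoints[:, 0], self.waypoints[:, 1])
        seg_lens = np.hypot(np.diff(xw), np.diff(yw))
        bounds = np.concatenate([[0.0], np.cumsum(seg_lens)])
        s = np.mod(np.asarray(arc_m, float), bounds[-1])
        idx = np.clip(np.searchsorted(bounds, s, side="right") - 1, 0,
                      len(seg_lens) - 1)
        frac = (s - bounds[idx]) / seg_lens[idx]
        x = xw[idx] + frac * (xw[idx + 1] - xw[idx])
        y = yw[idx] + frac * (yw[idx + 1] - yw[idx])
        lat0, lon0 = self.waypoints[0, 0], self.waypoints[0, 1]
        m_per_deg = np.pi * EARTH_RADIUS_M / 180.0
        lat = lat0 + y / m_per_deg
        lon = lon0 + x / (m_per_deg * np.cos(np.radians(lat0)))
        ele = (self.waypoints[idx, 2]
               + frac * (self.waypoints[idx + 1, 2] - self.waypoints[idx, 2]))
        return lat, lon, ele

    def section_at(self, arc_m) -> np.ndarray:
        """Section index at arc positions (by nominal leg lengths)."""
        _, _, _, total = self.densify()
        xw, yw = self._local_xy(self.waypoints[:, 0], self.waypoints[:, 1])
        bounds = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(xw),
                                                           np.diff(yw)))])
        s = np.mod(np.asarray(arc_m, float), total)
        return np.clip(np.searchsorted(bounds, s, side="right") - 1, 0,
                       len(self.labels) - 1)


class CourseAlignmentError(RuntimeError):
    """Raised when a GPS track cannot be matched to the course."""


def assign_sections(track: GpsHrRecording, course: TrailCourse,
                    max_offset_m: float = 50.0,
                    ) -> tuple[np.ndarray, dict[str, float]]:
    """Label every GPS sample with its trail section.

    Each sample takes the section of its nearest densified course point
    (equivalently, of the pair of boundary waypoints it lies between).
    Because the loop closes on itself, the start and the finish are the
    same place: raw nearest-point arc positions are unwrapped by time
    continuity so that position noise at the start/finish boundary cannot
    flip a sample onto the wrong end of the lap.  Also returns each
    section's path length: the haversine sum over consecutive samples
    sharing the label.
    """
    dense_pts, dense_arc, dense_lab, total = course.densify()
    x, y = course._local_xy(track.lat, track.lon)
    from scipy.spatial import cKDTree
    tree = cKDTree(dense_pts)
    dist, idx = tree.query(np.column_stack([x, y]))
    if dist.min() > max_offset_m:
        raise CourseAlignmentError(
            f"track never approaches the course (min offset {dist.min():.0f} m)")
    raw = dense_arc[idx]
    # circular unwrap: each step takes the arc increment of smallest
    # magnitude modulo the loop length, anchored near the start waypoint
    start = raw[0] if raw[0] < total / 2 else raw[0] - total
    steps = np.mod(np.diff(raw) + total / 2, total) - total / 2
    arc = start + np.concatenate([[0.0], np.cumsum(steps)])
    sec_idx = course.section_at(np.clip(arc, 0.0, None))
    labels = np.array([course.labels[i] for i in sec_idx])
    step = haversine_m(track.lat[:-1], track.lon[:-1],
                       track.lat[1:], track.lon[1:])
    lengths: dict[str, float] = {}
    for i, lab in enumerate(course.labels):
        same = (sec_idx[:-1] == i) & (sec_idx[1:] == i)
        lengths[lab] = float(step[same].sum())
    empty = [lab for lab in course.labels if (labels == lab).sum() == 0]
    if empty:
        import warnings
        warnings.warn(f"sections with no GPS samples: {empty}", stacklevel=2)
    return labels, lengths


def section_heart_rate(track: GpsHrRecording,
                       labels: np.ndarray) -> dict[str, float]:
    """Arithmetic mean heart rate per section (NaN for empty sections)."""
    out = {}
    for lab in SECTION_LABELS:
        sel = labels == lab
        out[lab] = float(np.nanmean(track.heart_rate[sel])) if sel.any() \
            else float("nan")
    return out


def lap_qc(lap_durations_s: dict | list, max_range_s: float = 60.0) -> bool:
    """Include a subject iff their condition-lap times span <= one minute.

    The rule is strict: a range of exactly ``max_range_s`` is retained
    ("greater than one minute" excludes).
    """
    vals = list(lap_durations_s.values()) if isinstance(lap_durations_s, dict) \
        else list(lap_durations_s)
    if len(vals) < 2 or any(v is None or not np.isfinite(v) for v in vals):
        raise ValueError("need at least two finite condition-lap durations")
    return (max(vals) - min(vals)) <= max_range_s


def align_streams(run_start_time: float, track: GpsHrRecording,
                  event_times: np.ndarray,
                  labels: np.ndarray) -> np.ndarray:
    """Label strides/steps with the section of their contact-time GPS sample.

    The GPS watch was started right after the three hops, so GPS t=0 maps
    to the IMU run-start instant.  Events outside the GPS span are labeled
    ``"unlabeled"`` and skipped by the statistics.
    """
    if len(track.t) == 0:
        return np.full(len(event_times), "unlabeled", dtype=object)
    rel = np.asarray(event_times, float) - run_start_time
    gps_rel = track.t - track.t[0]
    if rel.size and rel.max() < 0:
        raise CourseAlignmentError("events end before the GPS track starts")
    idx = np.searchsorted(gps_rel, rel)
    idx = np.clip(idx, 0, len(gps_rel) - 1)
    out = np.asarray(labels, dtype=object)[idx].copy()
    out[(rel < gps_rel[0] - 1.0) | (rel > gps_rel[-1] + 1.0)] = "unlabeled"
    return out
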