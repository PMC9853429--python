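"""Stance detection and regional plantar-pressure metrics.

Stance phases are found on the total insole force: candidate events come
from threshold crossings and each is refined by descending the force curve
from the adjacent steepest-gradient sample down to the local baseline, so
contact lands at the onset of the loading ramp and toe-off at the end of
the unloading ramp.  The heel region is the rear 20% of the sensel grid
rows, the toe region the front 20%; contact area is the percentage of a
region's sensels above the load threshold, averaged over stance frames.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .sensor_io import PressureRecording


def detect_stance(total_force: np.ndarray, fs: float = 100.0,
                  threshold_frac: float = 0.05,
                  min_step_separation_s: float = 0.35,
                  ) -> list[tuple[int, int]]:
    """Detect ``[contact, toe_off)`` frame intervals from total force.

    ``threshold_frac`` scales the per-lap median of the per-step peak
    forces into the crossing threshold.  Returned intervals are ordered and
    non-overlapping.  An all-zero force series yields no steps.
    """
    f = np.asarray(total_force, float)
    if f.size == 0 or not np.any(f > 0):
        return []
    peaks, _ = find_peaks(f, distance=max(1, int(min_step_separation_s * fs)),
                          height=f.max() * 0.3)
    if peaks.size == 0:
        return []
    thresh = threshold_frac * float(np.median(f[peaks]))
    above = f > thresh
    rises = np.nonzero(~above[:-1] & above[1:])[0] + 1
    falls = np.nonzero(above[:-1] & ~above[1:])[0] + 1
    grad = np.gradient(f)
    # stop descending once the decrease is immaterial (sensor noise flat)
    eps = 0.002 * float(np.median(f[peaks]))
    intervals: list[tuple[int, int]] = []
    for r in rises:
        # matching fall: first fall after this rise
        after = falls[falls > r]
        if after.size == 0:
            continue
        fall = int(after[0])
        contact = _descend_to_baseline(f, grad, r, fall, eps, mode="contact")
        toe_off = _descend_to_baseline(f, grad, r, fall, eps, mode="toe_off")
        if toe_off > contact:
            if intervals and contact < intervals[-1][1]:
                contact = intervals[-1][1]
            intervals.append((contact, toe_off))
    return intervals


def _descend_to_baseline(f: np.ndarray, grad: np.ndarray, rise: int,
                         fall: int, eps: float, mode: str) -> int:
    """Walk downhill on the force curve from the steepest ramp sample.

    For a contact the walk runs backward from the steepest loading
    gradient to the local baseline and the event is the first loaded frame
    after it; for a toe-off it runs forward to the first baseline frame
    (the exclusive end of stance).  Descent stops when the next decrease
    is below ``eps``, i.e. once the curve is flat at the noise floor.
    """
    n = len(f)
    if mode == "contact":
        lo = max(0, rise - 10)
        hi = min(n, rise + 10)
        start = lo + int(np.argmax(grad[lo:hi]))
        i = start
        while i > 0 and f[i - 1] < f[i] - eps:
            i -= 1
        # i is the local-baseline frame; contact is the first loaded frame
        return min(i + 1, start)
    lo = max(0, fall - 10)
    hi = min(n, fall + 10)
    start = lo + int(np.argmin(grad[lo:hi]))
    i = start
    while i < n - 1 and f[i + 1] < f[i] - eps:
        i += 1
    return i


def region_masks(grid_shape: tuple[int, int], heel_frac: float = 0.20,
                 toe_frac: float = 0.20) -> tuple[np.ndarray, np.ndarray]:
    """Boolean heel/toe sensel masks from row bands of the grid.

    Row 0 is the toe end.  The toe region is the first ``ceil(toe_frac *
    rows)`` rows and the heel region the last ``ceil(heel_frac * rows)``
    rows; the two must not overlap.
    """
    rows, cols = grid_shape
    if rows < 5:
        raise ValueError("grid must have at least 5 rows")
    if heel_frac + toe_frac > 1.0:
        raise ValueError("heel and toe fractions sum to more than 1")
    n_heel = math.ceil(heel_frac * rows)
    n_toe = math.ceil(toe_frac * rows)
    if n_heel + n_toe > rows:
        raise ValueError("heel and toe row bands overlap on this grid")
    heel = np.zeros((rows, cols), dtype=bool)
    toe = np.zeros((rows, cols), dtype=bool)
    heel[rows - n_heel:, :] = True
    toe[:n_toe, :] = True
    return heel, toe


@dataclass
class StepMetrics:
    """Stance-phase regional contact areas (%) and peak pressures (kPa)."""

    contact: int
    toe_off: int
    heel_contact_area: float
    toe_contact_area: float
    peak_heel_pressure: float
    peak_toe_pressure: float


def step_metrics(rec: PressureRecording, interval: tuple[int, int],
                 masks: tuple[np.ndarray, np.ndarray],
                 load_threshold_kpa: float = 2.5) -> StepMetrics:
    """Regional metrics for one stance interval.

    Per frame, a region's contact area is 100 x (loaded sensels in region)
    / (region sensels), with loaded meaning pressure above the threshold;
    the reported area is the mean over stance frames.  Peak pressure is the
    max over stance frames of the max sensel pressure in the region.
    """
    contact, toe_off = interval
    if toe_off <= contact:
        raise ValueError("empty stance interval")
    if contact < 0 or toe_off > len(rec.t):
        raise ValueError("stance interval outside the recording")
    heel_mask, toe_mask = masks
    stance = rec.frames[contact:toe_off]
    loaded = stance > load_threshold_kpa
    heel_area = 100.0 * loaded[:, heel_mask].mean(axis=1).mean()
    toe_area = 100.0 * loaded[:, toe_mask].mean(axis=1).mean()
    return StepMetrics(
        contact=contact, toe_off=toe_off,
        heel_contact_area=float(heel_area),
        toe_contact_area=float(toe_area),
        peak_heel_pressure=float(stance[:, heel_mask].max()),
        peak_toe_pressure=float(stance[:, toe_mask].max()),
    )


def lap_step_metrics(rec: PressureRecording, run_start_time: float | None = None,
                     heel_frac: float = 0.20, toe_frac: float = 0.20,
                     load_threshold_kpa: float = 2.5) -> list[StepMetrics]:
    """Detect all stances of a lap and compute their regional metrics.

    Steps whose contact precedes ``run_start_time`` (the shared three-hop
    gate on the common clock) are discarded.
    """
    force = rec.total_force()
    intervals = detect_stance(force, fs=rec.rate)
    if run_start_time is not None:
        intervals = [iv for iv in intervals if rec.t[iv[0]] >= run_start_time]
    masks = region_masks(rec.grid_shape, heel_frac, toe_frac)
    return [step_metrics(rec, iv, masks, load_threshold_kpa)
            for iv in intervals]
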