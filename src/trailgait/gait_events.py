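"""Hop detection, stride segmentation and zero-phase filtering.

Every lap starts with three synchronizing hops; all metrics are computed
from samples after the third hop's landing.  Strides are segmented from the
squared jerk magnitude of the fused acceleration: heel strikes on trail are
jerk-rich transients that stand far above the between-impact baseline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

from .sensor_io import G, FusedAccel


class HopDetectionError(RuntimeError):
    """Raised when the three synchronizing hops cannot be located."""


def zero_phase_lowpass(signal: np.ndarray, cutoff_hz: float, fs: float,
                       order: int = 2, axis: int = 0) -> np.ndarray:
    """Forward-backward Butterworth low-pass of the stated order.

    The filter is applied once forward and once backward, so the net phase
    response is zero and the amplitude response is squared: a second-order
    design passes each direction at 1/sqrt(2) gain at the cutoff, 0.5 after
    both passes.
    """
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    if np.asarray(signal).shape[axis] <= 3 * order:
        raise ValueError("signal too short for the requested filter order")
    sos = butter(order, cutoff_hz / nyq, output="sos")
    return sosfiltfilt(sos, signal, axis=axis)


def jerk_squared(accel: np.ndarray, fs: float) -> np.ndarray:
    """Squared jerk magnitude: first difference of acceleration times rate.

    Returned with the same length as the input (last value repeated).
    """
    j = np.diff(accel, axis=0) * fs
    j2 = np.einsum("ij,ij->i", j, j)
    return np.concatenate([j2, j2[-1:]])


def detect_hops(fused: FusedAccel, n_hops: int = 3,
                search_window_s: float = 60.0,
                min_separation_s: float = 0.4,
                burst_threshold_ms2: float = 30.0,
                quiet_threshold_ms2: float = 5.0) -> int:
    """Locate the synchronizing hops; return the run-start sample index.

    Hops appear as the first ``n_hops`` bursts of the gravity-removed
    acceleration magnitude.  The returned index is the first sample after
    the third hop's landing, i.e. where the signal first settles back below
    the quiet threshold.
    """
    a = np.abs(np.linalg.norm(fused.accel, axis=1) - G)
    fs = fused.rate
    n_search = min(len(a), int(search_window_s * fs))
    peaks, _ = find_peaks(a[:n_search], height=burst_threshold_ms2,
                          distance=max(1, int(min_separation_s * fs)))
    if len(peaks) < n_hops:
        raise HopDetectionError(
            f"found {len(peaks)} acceleration burst(s) in the first "
            f"{search_window_s:.0f} s; expected at least {n_hops} hops")
    third = peaks[n_hops - 1]
    after = np.nonzero(a[third:n_search] < quiet_threshold_ms2)[0]
    if after.size == 0:
        raise HopDetectionError("no quiet period after the third hop")
    return int(third + after[0])


@dataclass
class Stride:
    """One gait cycle of the instrumented foot on the low-g time base.

    The span is half-open ``[start, end)``; ``contact`` is the detected
    impact sample (equal to ``start`` under contact-to-contact
    segmentation).
    """

    start: int
    end: int
    contact: int
    stride_time: float
    qc_pass: bool = True
    is_first: bool = False
    is_last: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("stride end must exceed start")


def segment_strides(fused: FusedAccel, gyro: np.ndarray | None = None,
                    run_start: int = 0,
                    k: float = 10.0,
                    refractory_s: float = 0.4,
                    median_window_s: float = 2.0,
                    onset_frac: float = 0.02,
                    onset_search_s: float = 0.04,
                    peak_floor_frac: float = 0.01,
                    qc_bounds: tuple[float, float] = (0.4, 2.0)) -> list[Stride]:
    """Segment running strides from the squared-jerk impact detector.

    Impacts are peaks of the squared jerk magnitude that exceed ``k`` times
    a rolling median of the same series, separated by at least the
    refractory period; candidates weaker than ``peak_floor_frac`` of the
    median accepted peak are discarded (they are swing-phase motion, not
    impacts).  Each contact is then refined from the peak back to the
    transient onset, where the squared jerk first drops below
    ``onset_frac`` of the peak, so the whole impact lies inside its own
    stride window.  A stride spans contact to the next contact of the same
    foot.  Stride times outside ``qc_bounds`` are flagged as QC failures
    but still returned.
    """
    fs = fused.rate
    j2 = jerk_squared(fused.accel, fs)
    win = max(3, int(median_window_s * fs))
    baseline = (pd.Series(j2).rolling(win, center=True, min_periods=1)
                .median().to_numpy())
    peaks, _ = find_peaks(j2, distance=max(1, int(refractory_s * fs)))
    peaks = peaks[(j2[peaks] > k * baseline[peaks]) & (peaks >= run_start)]
    if len(peaks) >= 2:
        floor = peak_floor_frac * float(np.median(j2[peaks]))
        peaks = peaks[j2[peaks] > floor]
    if len(peaks) < 2:
        return []
    back = max(1, int(onset_search_s * fs))
    refined = []
    for p in peaks:
        thresh = onset_frac * j2[p]
        i = p
        while i > max(run_start, p - back) and j2[i - 1] > thresh:
            i -= 1
        refined.append(i)
    peaks = np.asarray(refined)
    strides: list[Stride] = []
    lo, hi = qc_bounds
    for i, (c0, c1) in enumerate(zip(peaks[:-1], peaks[1:])):
        st = (c1 - c0) / fs
        ok = lo <= st <= hi
        strides.append(Stride(start=int(c0), end=int(c1), contact=int(c0),
                              stride_time=st, qc_pass=ok,
                              is_first=(i == 0), is_last=(i == len(peaks) - 2),
                              flags=[] if ok else ["stride_time_out_of_range"]))
    return strides


def events_table(strides: list[Stride], t: np.ndarray) -> pd.DataFrame:
    """Tidy per-stride event table (used for the CLI debug dump)."""
    return pd.DataFrame({
        "start": [s.start for s in strides],
        "end": [s.end for s in strides],
        "contact": [s.contact for s in strides],
        "t_contact": [t[s.contact] for s in strides],
        "stride_time": [s.stride_time for s in strides],
        "qc_pass": [s.qc_pass for s in strides],
    })
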