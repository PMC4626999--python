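"""Systolic peak detection and RMSSD, the comparator heat-stress index.

The detector is the classic event-detection scheme for PPG: square the
band-passed signal (negative lobes clipped first), compare a short moving
average (~111 ms, one systolic peak wide) against a long moving average
(~667 ms, one beat wide) plus a small offset, and take the argmax of each
suprathreshold block wider than the peak window, with a 250 ms refractory
period between accepted peaks.

RMSSD is the root mean square of successive differences between inter-beat
intervals, in milliseconds -- the standard parasympathetic HRV index,
suppressed under heat stress. Inter-beat intervals outside (0.25, 2.0) s
are discarded before RMSSD: on a 20-s window a single missed beat would
otherwise dominate the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDataset, PPGRecording
from .preprocess import FilterSpec, bandpass

__all__ = [
    "HRVResult", "detect_peaks", "rmssd", "rms_intervals",
    "analyze_recording", "compute_hrv_table", "InsufficientDataError",
]

#: Physiologic inter-beat-interval gate in seconds (240--30 bpm).
IBI_GATE = (0.25, 2.0)


class InsufficientDataError(ValueError):
    """Too few beats to compute the requested statistic."""


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    w = max(1, w)
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def detect_peaks(signal_or_recording, fs: float | None = None, *,
                 peak_window: float = 0.111,
                 beat_window: float = 0.667,
                 offset_beta: float = 0.02,
                 refractory: float = 0.25) -> np.ndarray:
    """Detect systolic peak times (s) on a band-passed PPG signal.

    Parameters
    ----------
    signal_or_recording : ndarray or PPGRecording
        Band-passed PPG samples.
    fs : float
        Sampling rate in Hz (taken from the recording if one is given).
    peak_window, beat_window : float
        Short and long moving-average windows in seconds.
    offset_beta : float
        Threshold offset as a fraction of the mean squared signal.
    refractory : float
        Minimum separation between accepted peaks in seconds.

    Returns
    -------
    ndarray
        Peak times in seconds (possibly empty).
    """
    if isinstance(signal_or_recording, PPGRecording):
        x = signal_or_recording.samples
        fs = signal_or_recording.fs
    else:
        x = np.asarray(signal_or_recording, dtype=float)
    if fs is None or fs <= 0:
        raise ValueError("fs must be positive")

    z = np.square(np.clip(x, 0.0, None))
    if not np.any(z > 0):
        return np.asarray([])
    w1 = int(round(peak_window * fs))
    w2 = int(round(beat_window * fs))
    ma_peak = _moving_average(z, w1)
    ma_beat = _moving_average(z, w2)
    thr = ma_beat + offset_beta * float(z.mean())
    above = ma_peak > thr

    # contiguous suprathreshold blocks at least one peak-window wide
    padded = np.concatenate(([0], above.astype(int), [0]))
    d = np.diff(padded)
    block_starts = np.flatnonzero(d == 1)
    block_ends = np.flatnonzero(d == -1)  # exclusive

    candidates = []
    for s, e in zip(block_starts, block_ends):
        if e - s >= w1:
            k = s + int(np.argmax(x[s:e]))
            candidates.append((k, x[k]))

    peaks: list[tuple[int, float]] = []
    min_gap = refractory * fs
    for k, amp in candidates:
        if peaks and k - peaks[-1][0] < min_gap:
            if amp > peaks[-1][1]:
                peaks[-1] = (k, amp)
        else:
            peaks.append((k, amp))
    return np.asarray([k for k, _ in peaks], dtype=float) / fs


def rmssd(peak_times: np.ndarray, *, gate: tuple[float, float] = IBI_GATE,
          literal_rms_of_intervals: bool = False) -> float:
    """RMSSD in milliseconds from systolic peak times.

    Successive differences are only taken between inter-beat intervals that
    are adjacent in the original beat sequence and both inside the
    physiologic gate. ``literal_rms_of_intervals`` computes the RMS of the
    intervals themselves instead of their successive differences (a debug
    variant; not the standard index).
    """
    pt = np.asarray(peak_times, dtype=float)
    if pt.size < 3:
        raise InsufficientDataError(
            f"need >= 3 peaks for RMSSD, got {pt.size}")
    if np.any(np.diff(pt) <= 0):
        raise ValueError("peak times must be strictly increasing")
    ibis = np.diff(pt)
    valid = (ibis > gate[0]) & (ibis < gate[1])
    if literal_rms_of_intervals:
        kept = ibis[valid]
        if kept.size == 0:
            raise InsufficientDataError("no intervals inside the gate")
        return float(np.sqrt(np.mean(kept ** 2)) * 1000.0)
    pair = valid[:-1] & valid[1:]
    if not np.any(pair):
        raise InsufficientDataError("no adjacent interval pair inside the gate")
    diffs = (ibis[1:] - ibis[:-1])[pair]
    return float(np.sqrt(np.mean(diffs ** 2)) * 1000.0)


def rms_intervals(peak_times: np.ndarray, **kw) -> float:
    """RMS of the inter-beat intervals themselves (debug variant), ms."""
    return rmssd(peak_times, literal_rms_of_intervals=True, **kw)


@dataclass
class HRVResult:
    """Peak times, gated intervals and summary indices for one recording."""

    peak_times: np.ndarray
    ibis: np.ndarray
    mean_hr: float   # bpm
    rmssd: float     # ms

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)


def analyze_recording(recording: PPGRecording, *,
                      filter_spec: FilterSpec | None = None,
                      gate: tuple[float, float] = IBI_GATE) -> HRVResult:
    """Band-pass (if needed), detect peaks and compute HR / RMSSD.

    Unfiltered input is band-passed zero-phase by default: the forward-
    backward filter has no group delay, so detected peak times line up
    with the waveform's true systolic maxima.
    """
    if filter_spec is None:
        filter_spec = FilterSpec(mode="zero_phase")
    rec = recording if recording.filtered else bandpass(recording, filter_spec)
    peaks = detect_peaks(rec)
    ibis = np.diff(peaks) if peaks.size > 1 else np.asarray([])
    valid = ibis[(ibis > gate[0]) & (ibis < gate[1])] if ibis.size else ibis
    mean_hr = float(60.0 / valid.mean()) if valid.size else float("nan")
    value = rmssd(peaks, gate=gate)  # raises InsufficientDataError if < 3 peaks
    return HRVResult(peak_times=peaks, ibis=valid, mean_hr=mean_hr, rmssd=value)


def compute_hrv_table(dataset: CohortDataset, *,
                      filter_spec: FilterSpec | None = None) -> pd.DataFrame:
    """Per-recording HRV summary for a cohort.

    Columns: ``subject_id``, ``condition``, ``n_peaks``, ``mean_hr_bpm``,
    ``rmssd_ms``. Recordings with too few beats get NaN indices rather than
    failing the whole cohort.
    """
    rows = []
    for rec in dataset:
        try:
            res = analyze_recording(rec, filter_spec=filter_spec)
            rows.append((rec.subject_id, rec.condition, res.n_peaks,
                         res.mean_hr, res.rmssd))
        except InsufficientDataError:
            rows.append((rec.subject_id, rec.condition, 0,
                         float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "n_peaks",
                                       "mean_hr_bpm", "rmssd_ms"])
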