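"""R-peak detection, heart-rate metrics and heartbeat-counting-task scoring.

The detector follows the classic Pan-Tompkins recipe: band-pass around the
QRS energy band, differentiate, square, moving-window integrate, then apply
an adaptive threshold with a physiological refractory period, and finally
re-align each detection to the local R maximum of the (polarity-corrected)
raw trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["RPeakSeries", "detect_r_peaks", "heart_rate", "hct_score", "hr_exclusion"]


@dataclass
class RPeakSeries:
    """Detected R-peak sample indices at a given sampling rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=int)
        if self.samples.size > 1 and np.any(np.diff(self.samples) <= 0):
            raise ValueError("R-peak samples must be strictly increasing")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times_s(self) -> np.ndarray:
        return self.samples / self.fs


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    refractory_s: float = 0.25,
    qrs_band_hz: tuple[float, float] = (5.0, 18.0),
) -> RPeakSeries:
    """Pan-Tompkins-style QRS detection.

    Works on either polarity (the dominant deflection sign is detected and
    the trace flipped if needed).  A flat or near-flat signal yields an
    empty series with a warning rather than an exception.
    """
    ecg = np.asarray(ecg, dtype=float).ravel()
    if ecg.size < 2 * fs:
        raise ValueError("need at least 2 s of ECG signal")
    if np.ptp(ecg) == 0.0:
        warnings.warn("flat ECG signal: no R peaks detected", stacklevel=2)
        return RPeakSeries(np.array([], dtype=int), fs)

    sos = sps.butter(3, qrs_band_hz, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, ecg)
    # polarity: make the dominant QRS deflection positive
    if abs(filt.min()) > abs(filt.max()):
        filt = -filt
        raw = -ecg
    else:
        raw = ecg

    deriv = np.gradient(filt)
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    threshold = 0.25 * np.percentile(integrated, 99)
    if threshold <= 0:
        warnings.warn("degenerate ECG signal: no R peaks detected", stacklevel=2)
        return RPeakSeries(np.array([], dtype=int), fs)
    distance = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(integrated, height=threshold, distance=distance)
    if cand.size == 0:
        warnings.warn("no QRS-like activity found", stacklevel=2)
        return RPeakSeries(np.array([], dtype=int), fs)

    # re-align each candidate to the raw R maximum within +-50 ms
    half = int(round(0.05 * fs))
    peaks = []
    for c in cand:
        a, b = max(0, c - half), min(len(raw), c + half + 1)
        peaks.append(a + int(np.argmax(raw[a:b])))
    peaks = np.unique(peaks)
    # enforce the refractory period after re-alignment, keeping larger peaks
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < distance:
            if raw[p] > raw[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return RPeakSeries(np.array(kept, dtype=int), fs)


def heart_rate(rp: RPeakSeries, span_s: tuple[float, float] | None = None) -> float:
    """Mean heart rate in bpm: 60 * n_intervals / total interval duration.

    ``span_s`` optionally restricts to peaks within a time window.
    Fewer than two peaks is undefined and raises.
    """
    t = rp.times_s
    if span_s is not None:
        t = t[(t >= span_s[0]) & (t <= span_s[1])]
    if t.size < 2:
        raise ValueError("heart rate undefined with fewer than 2 R peaks")
    return 60.0 * (t.size - 1) / (t[-1] - t[0])


def hct_score(reports: list[tuple[float, float]]) -> float:
    """Heartbeat-counting (Schandry) accuracy score.

    ``reports`` are (recorded, counted) pairs, one per timed interval; the
    score is the mean over intervals of ``1 - |recorded - counted| /
    recorded``.  The absolute value keeps over-counting from scoring above a
    perfect 1.0; the value is otherwise not clamped.
    """
    if len(reports) == 0:
        raise ValueError("need at least one (recorded, counted) report")
    terms = []
    for recorded, counted in reports:
        if recorded <= 0:
            raise ValueError("recorded heartbeat count must be positive")
        terms.append(1.0 - abs(recorded - counted) / recorded)
    return float(np.mean(terms))


def hr_exclusion(rp: RPeakSeries, threshold_bpm: float = 86.0) -> bool:
    """True (drop) iff the mean task heart rate is strictly above the
    threshold; exactly at threshold keeps the subject."""
    return bool(heart_rate(rp) > threshold_bpm)
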