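"""Filtering, re-referencing and channel selection.

Defaults mirror a conventional ERP acquisition chain: zero-phase 0.3-30 Hz
band-pass on scalp channels (the ECG channel gets its own wider band so the
QRS complex survives), common average reference over scalp channels only.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from heplpp.io import Recording

__all__ = ["bandpass_filter", "common_average_reference", "select_channels"]


def _butter_sos(low_hz: float, high_hz: float, fs: float, order: int):
    nyq = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist ({nyq})"
        )
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    rec: Recording,
    low_hz: float = 0.3,
    high_hz: float = 30.0,
    ecg_band: tuple[float, float] = (0.5, 40.0),
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass.

    EEG channels are filtered at ``(low_hz, high_hz)``; the ECG channel is
    filtered at ``ecg_band`` to preserve QRS morphology for peak detection.
    Forward-backward application (``sosfiltfilt``) keeps component latencies
    intact.
    """
    sos_eeg = _butter_sos(low_hz, high_hz, rec.fs, order)
    out = rec.data.copy()
    eeg = rec.eeg_indices
    if eeg.size:
        out[eeg] = sps.sosfiltfilt(sos_eeg, rec.data[eeg], axis=1)
    ecg_rows = [i for i, r in enumerate(rec.channel_roles) if r == "ecg"]
    if ecg_rows:
        sos_ecg = _butter_sos(ecg_band[0], ecg_band[1], rec.fs, order)
        out[ecg_rows] = sps.sosfiltfilt(sos_ecg, rec.data[ecg_rows], axis=1)
    return rec.copy_with(out)


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean over scalp channels from each scalp
    channel; the ECG channel is untouched.  Idempotent."""
    eeg = rec.eeg_indices
    if eeg.size < 2:
        raise ValueError("common average reference requires at least 2 EEG channels")
    out = rec.data.copy()
    out[eeg] = rec.data[eeg] - rec.data[eeg].mean(axis=0, keepdims=True)
    return rec.copy_with(out)


def select_channels(rec: Recording, keep: list[str]) -> Recording:
    """Keep only the named channels, in the given order, preserving roles."""
    unknown = [lab for lab in keep if lab not in rec.channel_labels]
    if unknown:
        raise KeyError(f"unknown channel labels: {unknown}")
    idx = [rec.channel_labels.index(lab) for lab in keep]
    return Recording(
        rec.data[idx],
        rec.fs,
        [rec.channel_labels[i] for i in idx],
        [rec.channel_roles[i] for i in idx],
    )
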