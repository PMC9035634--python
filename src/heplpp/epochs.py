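"""Stimulus-locked (LPP) and heartbeat-locked (HEP) epoch extraction.

Epoch windows are half-open sample intervals; the sample index of a time
point is ``round(t_s * fs)``.  LPP epochs run -200..1000 ms around face
onset with a -200..0 ms baseline; HEP epochs run -100..600 ms around the
R peak with no baseline by default (the pre-R interval belongs to the
preceding cardiac cycle, so between-group contrasts at matched latencies
are preferred over baseline subtraction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from heplpp.io import EventTable, Recording
from heplpp.cardiac import RPeakSeries

__all__ = [
    "EpochSet",
    "extract_stimulus_epochs",
    "extract_heartbeat_epochs",
    "reject_artifacts",
    "retention_report",
    "mean_amplitude",
    "ecg_confound_amplitude",
]

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Channels x times x trials array cut around a lock event."""

    data: np.ndarray  # (n_channels, n_times, n_trials), microvolts
    fs: float
    channel_labels: list[str]
    channel_roles: list[str]
    lock: str  # "face" or "rpeak"
    window_ms: tuple[float, float]
    conditions: np.ndarray  # per-trial label (str)
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    baseline_ms: tuple[float, float] | None = None
    trial_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n_trials = self.data.shape[2]
        if self.rejected is None:
            self.rejected = np.zeros(n_trials, dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        self.conditions = np.asarray(self.conditions)
        if self.trial_ids is None:
            self.trial_ids = np.arange(n_trials)
        if len(self.conditions) != n_trials or len(self.rejected) != n_trials:
            raise ValueError("condition/rejection mask length must equal n_trials")
        expected = int(round((self.window_ms[1] - self.window_ms[0]) / 1000.0 * self.fs))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"window {self.window_ms} at fs={self.fs} implies {expected} samples, "
                f"data has {self.data.shape[1]}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def kept(self) -> np.ndarray:
        return ~self.rejected

    def kept_per_condition(self) -> dict:
        return {
            str(c): int(np.sum(self.kept & (self.conditions == c)))
            for c in np.unique(self.conditions)
        }

    @property
    def eeg_rows(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == "eeg"], dtype=int)

    def _sample_range(self, window_ms: tuple[float, float]) -> tuple[int, int]:
        if window_ms[0] < self.window_ms[0] or window_ms[1] > self.window_ms[1]:
            raise ValueError(f"window {window_ms} outside epoch window {self.window_ms}")
        a = int(round((window_ms[0] - self.window_ms[0]) / 1000.0 * self.fs))
        b = int(round((window_ms[1] - self.window_ms[0]) / 1000.0 * self.fs))
        return a, b


def _cut(
    rec: Recording, centers_s: np.ndarray, window_ms: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Cut half-open epochs [onset+w0, onset+w1); returns (data, kept_idx)."""
    fs = rec.fs
    n_times = int(round((window_ms[1] - window_ms[0]) / 1000.0 * fs))
    starts = np.round((centers_s + window_ms[0] / 1000.0) * fs).astype(int)
    ok = (starts >= 0) & (starts + n_times <= rec.n_samples)
    for i in np.flatnonzero(~ok):
        logger.info("epoch %d at %.3f s exceeds recording bounds; dropped", i, centers_s[i])
    kept = np.flatnonzero(ok)
    data = np.empty((rec.n_channels, n_times, kept.size))
    for j, i in enumerate(kept):
        data[:, :, j] = rec.data[:, starts[i] : starts[i] + n_times]
    return data, kept


def extract_stimulus_epochs(
    rec: Recording,
    events: EventTable,
    window_ms: tuple[float, float] = (-200.0, 1000.0),
    baseline_ms: tuple[float, float] | None = (-200.0, 0.0),
) -> EpochSet:
    """One epoch per non-capture face event, baseline-corrected per channel
    and trial.  Epochs that would run outside the recording are dropped
    with a logged reason."""
    faces = events.face_events()
    if len(faces) == 0:
        raise ValueError("no face events in the event table")
    capture = events.capture_trial_indices()
    faces = faces[~faces["trial_index"].isin(capture)].reset_index(drop=True)
    onsets = faces["onset"].to_numpy(float)
    conds = faces["trial_type"].str.replace("face_", "", regex=False).to_numpy()
    trial_ids = faces["trial_index"].to_numpy(int)

    data, kept = _cut(rec, onsets, window_ms)
    conds, trial_ids = conds[kept], trial_ids[kept]
    epochs = EpochSet(
        data,
        rec.fs,
        list(rec.channel_labels),
        list(rec.channel_roles),
        lock="face",
        window_ms=window_ms,
        conditions=conds,
        baseline_ms=baseline_ms,
        trial_ids=trial_ids,
    )
    if baseline_ms is not None:
        a, b = epochs._sample_range(baseline_ms)
        epochs.data -= epochs.data[:, a:b, :].mean(axis=1, keepdims=True)
    return epochs


def extract_heartbeat_epochs(
    rec: Recording,
    rpeaks: RPeakSeries,
    events: EventTable,
    window_ms: tuple[float, float] = (-100.0, 600.0),
    guard_after_face_s: float = 1.0,
    baseline_ms: tuple[float, float] | None = None,
) -> EpochSet:
    """Epochs locked to R peaks that fall inside pre-stimulus cue periods.

    A heartbeat qualifies when its full epoch (i) lies within a cue period
    preceding a face stimulus and (ii) starts at least
    ``guard_after_face_s`` after the most recent face onset — suppressing
    overlap with the visual evoked response to the previous face.  Each
    epoch carries the upcoming face's condition label; the primary HEP
    average pools all cue-period beats.
    """
    if len(rpeaks) == 0:
        raise ValueError("R-peak series is empty")
    cues = events.cue_events()
    faces = events.face_events().set_index("trial_index")
    face_onsets_sorted = np.sort(faces["onset"].to_numpy(float))
    r_times = rpeaks.times_s
    w0, w1 = window_ms[0] / 1000.0, window_ms[1] / 1000.0

    centers, conds, trial_ids = [], [], []
    for _, cue in cues.iterrows():
        ti = int(cue["trial_index"])
        if ti not in faces.index:
            continue
        face = faces.loc[ti]
        cue_on, face_on = float(cue["onset"]), float(face["onset"])
        cand = r_times[(r_times + w0 >= cue_on) & (r_times + w1 <= face_on)]
        for t_r in cand:
            k = np.searchsorted(face_onsets_sorted, t_r) - 1
            prev_face = face_onsets_sorted[k] if k >= 0 else -np.inf
            if t_r + w0 < prev_face + guard_after_face_s:
                continue
            centers.append(t_r)
            conds.append(str(face["trial_type"]).replace("face_", ""))
            trial_ids.append(ti)

    centers = np.array(centers, dtype=float)
    data, kept = _cut(rec, centers, window_ms) if centers.size else (
        np.empty((rec.n_channels, int(round((w1 - w0) * rec.fs)), 0)),
        np.array([], dtype=int),
    )
    conds = np.array(conds, dtype=object)[kept] if centers.size else np.array([], dtype=object)
    trial_ids = np.array(trial_ids, dtype=int)[kept] if centers.size else np.array([], dtype=int)
    epochs = EpochSet(
        data,
        rec.fs,
        list(rec.channel_labels),
        list(rec.channel_roles),
        lock="rpeak",
        window_ms=window_ms,
        conditions=conds,
        baseline_ms=baseline_ms,
        trial_ids=trial_ids,
    )
    if baseline_ms is not None and epochs.n_trials:
        a, b = epochs._sample_range(baseline_ms)
        epochs.data -= epochs.data[:, a:b, :].mean(axis=1, keepdims=True)
    return epochs


def reject_artifacts(epochs: EpochSet, peak_to_peak_uv: float = 100.0) -> EpochSet:
    """Mark any trial whose any scalp channel exceeds the peak-to-peak
    bound; rejection combines with any pre-existing mask.  Order-independent
    by construction (a per-trial criterion)."""
    if peak_to_peak_uv <= 0:
        raise ValueError("peak-to-peak threshold must be positive")
    eeg = epochs.eeg_rows
    if eeg.size == 0 or epochs.n_trials == 0:
        return replace(epochs, rejected=epochs.rejected.copy())
    ptp = np.ptp(epochs.data[eeg], axis=1)  # (n_eeg, n_trials)
    bad = np.any(ptp > peak_to_peak_uv, axis=0)
    return replace(epochs, rejected=epochs.rejected | bad)


def retention_report(epochs: EpochSet, floor: int = 70) -> dict:
    """Per-condition retained-trial counts and a flag when any condition
    drops below the floor (subjects so flagged are excluded upstream)."""
    counts = epochs.kept_per_condition()
    return {
        "retained_per_condition": counts,
        "floor": floor,
        "flagged": any(v < floor for v in counts.values()),
    }


def mean_amplitude(
    epochs: EpochSet,
    window_ms: tuple[float, float],
    channels: list[str],
    condition: str | None = None,
    per_trial: bool = False,
):
    """Mean voltage over ``[start, end)`` ms and the named channels.

    By default unrejected trials are averaged first (the ERP average) and
    the window/channel mean of that average is returned; ``per_trial``
    returns one value per unrejected trial instead.
    """
    unknown = [c for c in channels if c not in epochs.channel_labels]
    if unknown:
        raise KeyError(f"unknown channels: {unknown}")
    rows = [epochs.channel_labels.index(c) for c in channels]
    a, b = epochs._sample_range(window_ms)
    keep = epochs.kept.copy()
    if condition is not None:
        keep &= epochs.conditions == condition
    if not np.any(keep):
        raise ValueError("no unrejected trials to average")
    sub = epochs.data[np.ix_(rows, range(a, b), np.flatnonzero(keep))]
    if per_trial:
        return sub.mean(axis=(0, 1))
    return float(sub.mean(axis=2).mean())


def ecg_confound_amplitude(
    epochs: EpochSet, window_ms: tuple[float, float] = (455.0, 595.0)
) -> float:
    """Mean ECG amplitude in the HEP analysis window for R-locked epochs —
    the per-subject cardiac confound check."""
    ecg_labels = [
        lab for lab, role in zip(epochs.channel_labels, epochs.channel_roles) if role == "ecg"
    ]
    if len(ecg_labels) != 1:
        raise ValueError(f"expected exactly one ecg channel, found {len(ecg_labels)}")
    return mean_amplitude(epochs, window_ms, ecg_labels)
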