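"""Data model and file I/O: recordings (EDF), event tables (TSV), montages.

Conventions
-----------
* All signal data are stored in microvolts, EEG and ECG alike, as a
  ``channels x samples`` float array with a uniform sampling rate.
* Event onsets are in seconds from recording start; the sample index of an
  onset is ``round(onset_s * fs)`` and epochs are half-open sample
  intervals ``[start, end)``.
* Channel roles are ``eeg``, ``ecg`` or ``excluded``; the pipeline expects
  exactly one ``ecg`` channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventTable",
    "Montage",
    "SubjectRecord",
    "DEFAULT_47_CHANNELS",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_montage",
    "write_montage",
]

#: Scalp channel set retained for analysis: a 64-channel 10-10 cap minus the
#: rows nearest the orbital cavity (Fp/AF) and the lowest temporal sites,
#: leaving 47 channels.  The exact retained set is a configuration choice.
DEFAULT_47_CHANNELS: tuple[str, ...] = (
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

VALID_ROLES = ("eeg", "ecg", "excluded")


class FormatError(ValueError):
    """A file failed to parse under the named standard."""


class StructuralIntegrityError(ValueError):
    """A table violates a structural invariant (e.g. face without cue)."""


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names, one per row of ``data``.
    channel_roles : list of str
        One of ``eeg``, ``ecg``, ``excluded`` per channel.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_roles: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = self.data.shape[0]
        if len(self.channel_labels) != n or len(self.channel_roles) != n:
            raise ValueError("labels/roles length must match number of channels")
        if len(set(self.channel_labels)) != n:
            raise ValueError("channel labels must be unique")
        for r in self.channel_roles:
            if r not in VALID_ROLES:
                raise ValueError(f"unknown channel role {r!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == "eeg"], dtype=int)

    @property
    def ecg_index(self) -> int:
        """Index of the single ecg-role channel; raises if not exactly one."""
        idx = [i for i, r in enumerate(self.channel_roles) if r == "ecg"]
        if len(idx) != 1:
            raise ValueError(f"expected exactly one ecg channel, found {len(idx)}")
        return idx[0]

    def index_of(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(data, self.fs, list(self.channel_labels), list(self.channel_roles))


def infer_roles(labels: list[str], ecg_labels: tuple[str, ...] = ("ECG",)) -> list[str]:
    """Default role inference: a label named (or prefixed) ``ECG`` is the
    cardiac channel, everything else is scalp EEG."""
    roles = []
    for lab in labels:
        if lab.upper() in ecg_labels or lab.upper().startswith("ECG"):
            roles.append("ecg")
        else:
            roles.append("eeg")
    return roles


# ---------------------------------------------------------------------------
# EDF writer (16-bit European Data Format, one-second records)
# ---------------------------------------------------------------------------


def _ascii(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _fmt_number(x: float) -> str:
    s = f"{x:.8g}"
    return s[:8]


def _write_edf(rec: Recording, path: Path) -> None:
    """Write a minimal EDF file: physical dimension uV, 1 s data records.

    The signal is padded with zeros to a whole number of one-second
    records; amplitudes are quantized to the 16-bit digital range.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs)) if rec.n_samples else 0
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : rec.n_samples] = rec.data

    phys_min, phys_max = [], []
    for ch in range(n_ch):
        amp = float(np.max(np.abs(padded[ch]))) if padded.shape[1] else 0.0
        if amp == 0.0:
            amp = 1.0
        lo, hi = _fmt_number(-amp), _fmt_number(amp)
        # re-parse the formatted strings so writer and reader agree exactly
        phys_min.append(float(lo))
        phys_max.append(float(hi))

    dig_min, dig_max = -32768, 32767
    with open(path, "wb") as f:
        f.write(_ascii("0", 8))
        f.write(_ascii("X X X X", 80))
        f.write(_ascii("Startdate 01-JAN-2020 X X X", 80))
        f.write(_ascii("01.01.20", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(str(256 * (n_ch + 1)), 8))
        f.write(_ascii("", 44))
        f.write(_ascii(str(n_records), 8))
        f.write(_ascii("1", 8))
        f.write(_ascii(str(n_ch), 4))
        for lab in rec.channel_labels:
            f.write(_ascii(lab, 16))
        for _ in range(n_ch):
            f.write(_ascii("", 80))
        for _ in range(n_ch):
            f.write(_ascii("uV", 8))
        for v in phys_min:
            f.write(_ascii(_fmt_number(v), 8))
        for v in phys_max:
            f.write(_ascii(_fmt_number(v), 8))
        for _ in range(n_ch):
            f.write(_ascii(str(dig_min), 8))
        for _ in range(n_ch):
            f.write(_ascii(str(dig_max), 8))
        for _ in range(n_ch):
            f.write(_ascii("", 80))
        for _ in range(n_ch):
            f.write(_ascii(str(fs), 8))
        for _ in range(n_ch):
            f.write(_ascii("", 32))

        scale = np.array(
            [(phys_max[c] - phys_min[c]) / (dig_max - dig_min) for c in range(n_ch)]
        )
        offset = np.array([phys_max[c] / scale[c] - dig_max for c in range(n_ch)])
        for r in range(n_records):
            block = padded[:, r * fs : (r + 1) * fs]
            digital = np.round(block / scale[:, None] - offset[:, None])
            digital = np.clip(digital, dig_min, dig_max).astype("<i2")
            f.write(digital.tobytes())


def _check_uniform_fs(path: Path) -> None:
    """Parse the EDF header's samples-per-record fields; the pipeline
    requires one sampling rate for all channels."""
    with open(path, "rb") as f:
        header = f.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header (need 256 bytes)")
        try:
            n_ch = int(header[252:256].decode("ascii").strip())
        except ValueError:
            raise FormatError(f"{path}: unreadable channel-count field") from None
        sig_header = f.read(256 * n_ch)
    off = n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    rates = set()
    for c in range(n_ch):
        fld = sig_header[off + 8 * c : off + 8 * (c + 1)].decode("ascii", "replace").strip()
        try:
            rates.add(int(fld))
        except ValueError:
            raise FormatError(f"{path}: bad samples-per-record field {fld!r}") from None
    if len(rates) > 1:
        raise FormatError(
            f"{path}: channels declare different sampling rates {sorted(rates)}; "
            "the pipeline requires a uniform rate"
        )


def _read_edf(path: Path, ecg_labels: tuple[str, ...]) -> Recording:
    import mne

    _check_uniform_fs(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted exceptions on bad headers
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise FormatError(f"EDF file {path} contains zero channels")
    fs_per_ch = {raw.info["sfreq"]}
    if len(fs_per_ch) != 1:
        raise FormatError("EDF channels have non-uniform sampling rates")
    labels = list(raw.ch_names)
    roles = infer_roles(labels, ecg_labels)
    types = {lab: ("ecg" if role == "ecg" else "eeg") for lab, role in zip(labels, roles)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw.set_channel_types(types, verbose="error")
    present_types = set(raw.get_channel_types())
    data_uv = raw.get_data(units={t: "uV" for t in present_types})
    return Recording(data_uv, float(raw.info["sfreq"]), labels, roles)


# ---------------------------------------------------------------------------
# Internal columnar container (npz) — convenient for tests and scratch runs
# ---------------------------------------------------------------------------


def _write_internal(rec: Recording, path: Path) -> None:
    np.savez(
        path,
        data=rec.data,
        fs=np.array([rec.fs]),
        labels=np.array(rec.channel_labels),
        roles=np.array(rec.channel_roles),
    )


def _read_internal(path: Path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        return Recording(
            z["data"],
            float(z["fs"][0]),
            [str(x) for x in z["labels"]],
            [str(x) for x in z["roles"]],
        )


def write_recording(rec: Recording, path: str | Path, format: str = "edf") -> None:
    """Write a :class:`Recording` to disk as EDF (default) or the internal
    npz container."""
    path = Path(path)
    if format == "edf":
        _write_edf(rec, path)
    elif format == "internal":
        _write_internal(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_recording(
    path: str | Path,
    format: str = "edf",
    ecg_labels: tuple[str, ...] = ("ECG",),
) -> Recording:
    """Read a continuous recording.

    Channel roles are inferred from labels (``ECG`` prefix -> ecg), which can
    be overridden through ``ecg_labels``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        return _read_edf(path, ecg_labels)
    if format == "internal":
        rec = _read_internal(path)
        rec.channel_roles = infer_roles(rec.channel_labels, ecg_labels)
        return rec
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# EventTable
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ("onset", "duration", "trial_type", "trial_index")
FACE_TYPES = ("face_sad", "face_happy", "face_neutral")


@dataclass
class EventTable:
    """Task event markers: a thin wrapper over a tidy DataFrame.

    Columns: ``onset`` (s), ``duration`` (s), ``trial_type`` (one of cue,
    face_sad, face_happy, face_neutral, capture, response), ``trial_index``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise StructuralIntegrityError(f"event table missing columns {missing}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def sorted(self) -> "EventTable":
        return EventTable(self.frame.sort_values("onset", kind="stable").reset_index(drop=True))

    def validate(self) -> None:
        """Check structural invariants; raise listing offending trials."""
        f = self.frame
        if len(f) == 0:
            return
        onsets = f["onset"].to_numpy(float)
        if np.any(np.diff(onsets) < 0):
            raise StructuralIntegrityError("event onsets are not sorted")
        cue_idx = set(f.loc[f["trial_type"] == "cue", "trial_index"])
        faces = f[f["trial_type"].isin(FACE_TYPES)]
        orphans = sorted(set(faces["trial_index"]) - cue_idx)
        if orphans:
            raise StructuralIntegrityError(
                f"face events without a matching cue for trial_index {orphans}"
            )

    def of_type(self, *types: str) -> pd.DataFrame:
        return self.frame[self.frame["trial_type"].isin(types)].reset_index(drop=True)

    def face_events(self) -> pd.DataFrame:
        return self.of_type(*FACE_TYPES)

    def cue_events(self) -> pd.DataFrame:
        return self.of_type("cue")

    def capture_trial_indices(self) -> set[int]:
        return set(self.of_type("capture")["trial_index"].astype(int))


def write_events(events: EventTable, path: str | Path) -> None:
    events.frame.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> EventTable:
    """Read a BIDS-style events TSV; rows are sorted by onset and the table
    is validated (a face with no matching cue is an error, not repaired)."""
    frame = pd.read_csv(path, sep="\t")
    if len(frame) == 0:
        return EventTable(frame)
    ev = EventTable(frame).sorted()
    ev.validate()
    return ev


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------


@dataclass
class Montage:
    """Electrode labels with 3-D head-coordinate positions.

    2-D positions for adjacency construction come from an azimuthal
    equidistant projection about the head centre.
    """

    labels: list[str]
    positions: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("montage positions must be finite")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def projected_2d(self) -> np.ndarray:
        """Azimuthal-equidistant projection of unit-sphere electrode
        directions onto the plane tangent at the vertex."""
        pos = self.positions - self.positions.mean(axis=0)
        # push the centre below the cap so all electrodes are on the upper
        # hemisphere of the fitted sphere
        pos = pos - np.array([0.0, 0.0, pos[:, 2].min() * 1.5])
        norm = np.linalg.norm(pos, axis=1)
        norm[norm == 0] = 1.0
        unit = pos / norm[:, None]
        theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
        phi = np.arctan2(unit[:, 1], unit[:, 0])
        return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])

    def subset(self, labels: list[str]) -> "Montage":
        idx = [self.labels.index(lab) for lab in labels]
        return Montage(list(labels), self.positions[idx])

    @classmethod
    def standard(cls, labels: tuple[str, ...] = DEFAULT_47_CHANNELS) -> "Montage":
        """Standard 10-10 positions for the requested labels (via MNE)."""
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                std = mne.channels.make_standard_montage("colin27_1020")
            except ValueError:
                std = mne.channels.make_standard_montage("standard_1020")
        ch_pos = std.get_positions()["ch_pos"]
        missing = [lab for lab in labels if lab not in ch_pos]
        if missing:
            raise KeyError(f"labels not in standard montage: {missing}")
        pos = np.array([ch_pos[lab] for lab in labels])
        return cls(list(labels), pos)


def write_montage(montage: Montage, path: str | Path) -> None:
    with open(path, "w") as f:
        for lab, (x, y, z) in zip(montage.labels, montage.positions):
            f.write(f"{lab} {x:.17g} {y:.17g} {z:.17g}\n")


def read_montage(path: str | Path) -> Montage:
    """Read a whitespace-delimited ``label x y z`` montage file."""
    labels, pos = [], []
    with open(path) as f:
        for ln, line in enumerate(f, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{path}:{ln}: expected 'label x y z', got {line!r}")
            labels.append(parts[0])
            try:
                pos.append([float(v) for v in parts[1:]])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-numeric coordinate in {line!r}") from None
    return Montage(labels, np.array(pos).reshape(len(labels), 3))


# ---------------------------------------------------------------------------
# SubjectRecord
# ---------------------------------------------------------------------------

HCT_INTERVALS_S = (25, 35, 45, 55, 60)


@dataclass
class SubjectRecord:
    """Per-subject demographics, questionnaires and heartbeat-counting data."""

    subject_id: str
    group: str  # "MDD" or "HC"
    sex: str  # "M" or "F"
    age: float
    bmi: float
    education_years: float
    parent_education_years: float
    duration_months: float
    episodes: float
    bdi_total: float
    bdi_item20: float
    bdi_cognitive_factor: float
    sai: float
    tai: float
    hct_reports: list[tuple[float, int, int]] = field(default_factory=list)
    hit_rate: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in ("MDD", "HC"):
            raise ValueError(f"group must be MDD or HC, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        for interval, rec, cnt in self.hct_reports:
            if rec < 0 or cnt < 0:
                raise ValueError("heartbeat counts must be non-negative")

    def to_row(self) -> dict:
        row = {
            k: getattr(self, k)
            for k in (
                "subject_id", "group", "sex", "age", "bmi", "education_years",
                "parent_education_years", "duration_months", "episodes",
                "bdi_total", "bdi_item20", "bdi_cognitive_factor", "sai", "tai",
                "hit_rate",
            )
        }
        for i, (interval, rec, cnt) in enumerate(self.hct_reports, 1):
            row[f"hct{i}_interval_s"] = interval
            row[f"hct{i}_recorded"] = rec
            row[f"hct{i}_counted"] = cnt
        return row


def subjects_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])
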