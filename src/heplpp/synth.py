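"""Synthetic two-group EEG/ECG cohort generator with known ground truth.

The generator emulates an emotional-faces EEG experiment in a depressed
(MDD-like) and a healthy-control (HC-like) group:

* trials of cue (1.5-2.5 s, uniform) -> emotional face (2.5 s, sad / happy /
  neutral in equal numbers) -> inter-trial interval (2.5-3.5 s), with 20 %
  attention-capture trials;
* a synthetic ECG channel carrying a sum-of-Gaussians PQRST train at a
  group-specific heart rate, volume-conducted into every scalp channel as a
  cardiac field artifact (instantaneous linear mixing, per-channel gain);
* a heartbeat-evoked potential (HEP) injected as a raised-cosine bump in the
  455-595 ms post-R window on a frontocentral channel set, attenuated in the
  MDD-like group;
* a late positive potential (LPP) injected 300-1000 ms post-face with
  group x condition amplitudes (centroparietal attenuation, frontocentral
  sad/neutral enhancement in the MDD-like group);
* subject-level coupling between HEP amplitude and sad-LPP amplitude in the
  MDD-like group only;
* 1/f (pink) background noise, mains line noise and occasional high-amplitude
  transients, plus a behavioral table (questionnaires, heartbeat-counting
  reports, capture-trial hit rate) drawn from group-specific distributions.

Everything is a deterministic function of ``(SimConfig, seed)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from heplpp.io import (
    DEFAULT_47_CHANNELS,
    EventTable,
    Recording,
    SubjectRecord,
    HCT_INTERVALS_S,
    subjects_to_frame,
    write_events,
    write_recording,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SubjectData",
    "simulate_subject",
    "simulate_cohort",
    "simulate_behavior",
    "simulate_measured_effects",
    "iter_cohort",
]

GROUPS = ("MDD", "HC")
CONDITIONS = ("sad", "happy", "neutral")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic cohort.

    Amplitudes are microvolts; durations are seconds unless the name says
    otherwise.  Component amplitudes are defined as the *mean* of the
    injected waveform over its analysis window, so the pipeline's
    mean-amplitude index estimates them directly.
    """

    # cohort size and task structure
    n_per_group: int = 27
    n_trials: int = 300
    fs: float = 1000.0
    channels: tuple[str, ...] = DEFAULT_47_CHANNELS
    ecg_label: str = "ECG"
    cue_duration_range_s: tuple[float, float] = (1.5, 2.5)
    face_duration_s: float = 2.5
    iti_range_s: tuple[float, float] = (2.5, 3.5)
    capture_fraction: float = 0.2
    lead_in_s: float = 5.0
    tail_s: float = 2.0

    # cardiac model
    heart_rate_bpm: dict = field(default_factory=lambda: {"MDD": 70.4, "HC": 69.9})
    heart_rate_between_sd: dict = field(default_factory=lambda: {"MDD": 8.8, "HC": 7.6})
    ibi_jitter_sd_s: float = 0.04
    enforce_hr_cap: bool = True
    hr_cap_bpm: float = 86.0
    ecg_r_amplitude_uv: float = 800.0

    # noise and artifacts
    noise_sd_uv: float = 12.0
    line_noise_uv: float = 2.0
    line_freq_hz: float = 50.0
    cfa_gain_mean: float = 0.02
    cfa_gain_sd: float = 0.01
    artifact_rate: float = 0.1
    artifact_amp_uv: float = 500.0

    # evoked components
    hep_channels: tuple[str, ...] = ("F2", "F4", "F6", "FC2", "FC4", "FC6")
    hep_window_ms: tuple[float, float] = (455.0, 595.0)
    hep_amp_uv: dict = field(default_factory=lambda: {"HC": 2.0, "MDD": 0.8})
    hep_between_sd_uv: float = 0.6
    lpp_window_ms: tuple[float, float] = (300.0, 1000.0)
    lpp_centroparietal: tuple[str, ...] = ("C4", "CP4", "CP6")
    lpp_frontocentral: tuple[str, ...] = ("F5", "F3", "FC5", "FC3", "FC1")
    lpp_amp_uv: dict = field(
        default_factory=lambda: {
            "HC": {
                "centroparietal": {"sad": 6.0, "happy": 5.0, "neutral": 4.0},
                "frontocentral": {"sad": 1.0, "happy": 1.0, "neutral": 1.0},
            },
            "MDD": {
                "centroparietal": {"sad": 4.0, "happy": 3.0, "neutral": 2.0},
                "frontocentral": {"sad": 3.0, "happy": 1.0, "neutral": 2.5},
            },
        }
    )
    lpp_between_sd_uv: float = 0.8
    # near-deterministic within-patient coupling: the generated condition is
    # that HEP->sad-LPP linkage is reliably detectable in the patient group,
    # so group specificity (not power) is what recovery experiments probe
    coupling_slope: dict = field(default_factory=lambda: {"MDD": 1.0, "HC": 0.0})
    coupling_resid_sd_uv: float = 0.05

    # behavior
    hct_accuracy_mean: dict = field(default_factory=lambda: {"MDD": 0.3, "HC": 0.5})
    hct_accuracy_sd: dict = field(default_factory=lambda: {"MDD": 0.2, "HC": 0.2})
    hct_interval_jitter_sd: float = 0.03
    hit_rate_mean: dict = field(default_factory=lambda: {"MDD": 0.993, "HC": 0.994})
    hit_rate_sd: dict = field(default_factory=lambda: {"MDD": 0.023, "HC": 0.016})
    n_males: dict = field(default_factory=lambda: {"MDD": 16, "HC": 15})
    behavior_dists: dict = field(
        default_factory=lambda: {
            # variable: {group: (mean, sd)}, bounds applied after drawing
            "age": {"MDD": (27.0, 6.7), "HC": (25.3, 3.8)},
            "bmi": {"MDD": (21.6, 2.8), "HC": (21.6, 2.9)},
            "education_years": {"MDD": (13.6, 3.9), "HC": (14.0, 3.2)},
            "parent_education_years": {"MDD": (14.7, 1.8), "HC": (15.3, 1.8)},
            "duration_months": {"MDD": (54.2, 57.8), "HC": (0.0, 0.0)},
            "episodes": {"MDD": (5.1, 3.2), "HC": (0.0, 0.0)},
            "bdi_total": {"MDD": (27.9, 9.3), "HC": (2.7, 3.3)},
            "sai": {"MDD": (54.7, 11.2), "HC": (30.3, 5.5)},
            "tai": {"MDD": (57.7, 9.3), "HC": (30.7, 7.2)},
            "bdi_item20": {"MDD": (1.5, 0.8), "HC": (0.2, 0.4)},
            "bdi_cognitive_factor": {"MDD": (10.0, 4.0), "HC": (1.0, 1.5)},
        }
    )

    def validate(self) -> None:
        if self.n_per_group < 1 or self.n_trials < 1:
            raise ConfigError("cohort and trial counts must be positive")
        for name in ("cue_duration_range_s", "iti_range_s"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must be a positive (lo, hi) range")
        if self.face_duration_s <= 0 or self.fs <= 0:
            raise ConfigError("face duration and sampling rate must be positive")
        if not 0.0 <= self.capture_fraction <= 1.0:
            raise ConfigError("capture_fraction must lie in [0, 1]")
        if self.face_duration_s * 1000.0 < self.lpp_window_ms[1]:
            raise ConfigError(
                "face duration shorter than the LPP analysis window "
                f"({self.face_duration_s * 1000:.0f} < {self.lpp_window_ms[1]:.0f} ms)"
            )
        for g in GROUPS:
            for d in (self.heart_rate_bpm, self.hep_amp_uv, self.coupling_slope):
                if g not in d:
                    raise ConfigError(f"missing group {g!r} in config dictionaries")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

        def detuple(v):
            # JSON has no tuples; restore them recursively on load
            if isinstance(v, list):
                return tuple(detuple(x) for x in v)
            if isinstance(v, dict):
                return {k: detuple(x) for k, x in v.items()}
            return v

        cfg = cls(**{k: detuple(v) for k, v in d.items()})
        cfg.validate()
        return cfg

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class GroundTruth:
    """Per-subject latent state: the oracle for recovery tests."""

    subject_id: str
    group: str
    hr_mean_bpm: float
    r_peak_samples: np.ndarray
    artifact_trials: list[int]
    hep_amp_uv: float
    lpp_amps_uv: dict  # {site_set: {condition: amplitude}}
    coupling_slope: float
    hit_rate: float
    hct_accuracy: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["r_peak_samples"] = [int(v) for v in self.r_peak_samples]
        return d


class SubjectData(NamedTuple):
    subject_id: str
    group: str
    recording: Recording
    events: EventTable
    truth: GroundTruth


# ---------------------------------------------------------------------------
# subject-level latent traits (shared by signal and behavior simulators)
# ---------------------------------------------------------------------------


def _trunc_normal(rng, mean, sd, lo=-np.inf, hi=np.inf, max_tries=1000):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


_BOUNDS = {
    "age": (18.0, 65.0),
    "bmi": (15.0, 35.0),
    "education_years": (6.0, 22.0),
    "parent_education_years": (6.0, 22.0),
    "duration_months": (0.0, 360.0),
    "episodes": (0.0, 30.0),
    "bdi_total": (0.0, 63.0),
    "sai": (20.0, 80.0),
    "tai": (20.0, 80.0),
    "bdi_item20": (0.0, 3.0),
    "bdi_cognitive_factor": (0.0, 30.0),
}


def _draw_subject_traits(config: SimConfig, group: str, rng: np.random.Generator) -> dict:
    """Draw every subject-level latent variable in a fixed order so that the
    signal and behavior simulators agree when seeded identically."""
    t: dict = {"group": group}
    lo_hr = 45.0
    hi_hr = config.hr_cap_bpm if config.enforce_hr_cap else 130.0
    t["hr_mean_bpm"] = _trunc_normal(
        rng, config.heart_rate_bpm[group], config.heart_rate_between_sd[group], lo_hr, hi_hr
    )
    t["hep_amp_uv"] = rng.normal(config.hep_amp_uv[group], config.hep_between_sd_uv)

    lpp: dict = {}
    for site_set in ("centroparietal", "frontocentral"):
        lpp[site_set] = {}
        for cond in CONDITIONS:
            base = config.lpp_amp_uv[group][site_set][cond]
            lpp[site_set][cond] = rng.normal(base, config.lpp_between_sd_uv)
    # coupling: the subject's sad frontocentral LPP tracks their HEP deviation
    hep_dev = t["hep_amp_uv"] - config.hep_amp_uv[group]
    slope = config.coupling_slope[group]
    lpp["frontocentral"]["sad"] = (
        config.lpp_amp_uv[group]["frontocentral"]["sad"]
        + slope * hep_dev
        + rng.normal(0.0, config.coupling_resid_sd_uv)
    )
    t["lpp_amps_uv"] = lpp
    t["coupling_slope"] = float(slope)
    t["hit_rate"] = float(
        np.clip(rng.normal(config.hit_rate_mean[group], config.hit_rate_sd[group]), 0.0, 1.0)
    )
    t["hct_accuracy"] = _trunc_normal(
        rng, config.hct_accuracy_mean[group], config.hct_accuracy_sd[group], 0.0, 1.0
    )
    for var, per_group in config.behavior_dists.items():
        mean, sd = per_group[group]
        lo, hi = _BOUNDS.get(var, (-np.inf, np.inf))
        t[var] = _trunc_normal(rng, mean, sd, lo, hi)
    return t


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------


def _draw_schedule(config: SimConfig, rng: np.random.Generator, hit_rate: float) -> pd.DataFrame:
    n = config.n_trials
    per_cond = n // len(CONDITIONS)
    conds = [c for c in CONDITIONS for _ in range(per_cond)]
    conds += [CONDITIONS[i] for i in range(n - len(conds))]
    conds = [conds[i] for i in rng.permutation(n)]

    # distribute capture trials evenly across conditions
    capture = np.zeros(n, dtype=bool)
    for cond in CONDITIONS:
        idx = np.flatnonzero(np.array(conds) == cond)
        k = int(round(config.capture_fraction * len(idx)))
        capture[rng.choice(idx, size=k, replace=False)] = True

    rows = []
    t = config.lead_in_s
    for i in range(n):
        cue_dur = rng.uniform(*config.cue_duration_range_s)
        face_on = t + cue_dur
        rows.append((t, cue_dur, "cue", i))
        rows.append((face_on, config.face_duration_s, f"face_{conds[i]}", i))
        if capture[i]:
            rows.append((face_on, config.face_duration_s, "capture", i))
            if rng.uniform() < hit_rate:
                rt = rng.uniform(0.3, 0.9)
                rows.append((face_on + rt, 0.0, "response", i))
        t = face_on + config.face_duration_s + rng.uniform(*config.iti_range_s)
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "trial_index"])


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

# PQRST as Gaussians (offset_s, relative amplitude, width_s); the template is
# near-zero beyond ~0.45 s after R, leaving the 455-595 ms HEP window free of
# cardiac field artifact by construction.
_PQRST = (
    (-0.180, 0.12, 0.025),
    (-0.025, -0.12, 0.008),
    (0.000, 1.00, 0.011),
    (0.025, -0.22, 0.009),
    (0.220, 0.30, 0.055),
)


def ecg_template(fs: float, r_amplitude_uv: float) -> tuple[np.ndarray, int]:
    """PQRST waveform sampled at ``fs``; returns (template, index of R)."""
    t = np.arange(round(-0.30 * fs), round(0.45 * fs)) / fs
    wave = np.zeros_like(t)
    for off, amp, width in _PQRST:
        wave += amp * np.exp(-0.5 * ((t - off) / width) ** 2)
    return wave * r_amplitude_uv, int(round(0.30 * fs))


def _place(signal: np.ndarray, template: np.ndarray, centers: np.ndarray, center_offset: int):
    n = signal.shape[-1]
    m = len(template)
    for c in centers:
        a = int(c) - center_offset
        b = a + m
        ta, tb = max(0, -a), m - max(0, b - n)
        a, b = max(0, a), min(n, b)
        if a < b:
            signal[..., a:b] += template[ta:tb]


def _raised_cosine(fs: float, start_ms: float, end_ms: float) -> np.ndarray:
    """Smooth bump spanning [start, end) ms with unit mean over the window."""
    n = int(round((end_ms - start_ms) / 1000.0 * fs))
    u = (np.arange(n) + 0.5) / n
    return 2.0 * np.sin(np.pi * u) ** 2


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-power background noise with the requested standard deviation."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** -0.5
    out = np.fft.irfft(spec, n)
    out *= sd / out.std()
    return out


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------


def simulate_subject(
    config: SimConfig, group: str, seed: int, subject_id: str | None = None
) -> tuple[Recording, EventTable, GroundTruth]:
    """Simulate one subject's EEG+ECG session.

    Deterministic given ``(config, group, seed)``.  The scalp signal is
    pink noise + line noise + CFA-mixed ECG + the injected HEP and LPP
    components; ground truth records the latent amplitudes and R-peak train.
    """
    config.validate()
    if group not in GROUPS:
        raise ConfigError(f"group must be one of {GROUPS}, got {group!r}")
    rng = np.random.default_rng(seed)
    traits = _draw_subject_traits(config, group, rng)
    sched = _draw_schedule(config, rng, traits["hit_rate"])

    fs = config.fs
    faces = sched[sched["trial_type"].str.startswith("face_")]
    t_end = float(faces["onset"].max()) + config.face_duration_s + config.tail_s
    n_samples = int(math.ceil(t_end * fs))

    # --- ECG: R-peak train + PQRST template ---
    ibi_mean = 60.0 / traits["hr_mean_bpm"]
    r_times = []
    t = 0.5
    while t < t_end - 0.5:
        r_times.append(t)
        t += max(0.25, ibi_mean + rng.normal(0.0, config.ibi_jitter_sd_s))
    r_samples = np.array([int(round(v * fs)) for v in r_times], dtype=int)
    template, r_off = ecg_template(fs, config.ecg_r_amplitude_uv)
    ecg = np.zeros(n_samples)
    _place(ecg, template, r_samples, r_off)

    labels = list(config.channels) + [config.ecg_label]
    roles = ["eeg"] * len(config.channels) + ["ecg"]
    n_eeg = len(config.channels)
    data = np.empty((n_eeg + 1, n_samples))
    data[-1] = ecg

    cfa_gains = rng.normal(config.cfa_gain_mean, config.cfa_gain_sd, size=n_eeg)
    line_phases = rng.uniform(0, 2 * np.pi, size=n_eeg)
    tt = np.arange(n_samples) / fs

    hep_bump = _raised_cosine(fs, *config.hep_window_ms) * traits["hep_amp_uv"]
    hep_start = int(round(config.hep_window_ms[0] / 1000.0 * fs))
    lpp_bump_unit = _raised_cosine(fs, *config.lpp_window_ms)
    lpp_start = int(round(config.lpp_window_ms[0] / 1000.0 * fs))

    face_samples = {
        cond: faces.loc[faces["trial_type"] == f"face_{cond}", "onset"]
        .apply(lambda v: int(round(v * fs)))
        .to_numpy()
        for cond in CONDITIONS
    }
    site_sets = {
        "centroparietal": config.lpp_centroparietal,
        "frontocentral": config.lpp_frontocentral,
    }

    for ch in range(n_eeg):
        sig = _pink_noise(rng, n_samples, config.noise_sd_uv)
        if config.line_noise_uv:
            sig = sig + config.line_noise_uv * np.sin(
                2 * np.pi * config.line_freq_hz * tt + line_phases[ch]
            )
        sig = sig + cfa_gains[ch] * ecg
        lab = labels[ch]
        if lab in config.hep_channels:
            _place(sig, hep_bump, r_samples + hep_start, -0)
        for site_set, chans in site_sets.items():
            if lab in chans:
                for cond in CONDITIONS:
                    bump = lpp_bump_unit * traits["lpp_amps_uv"][site_set][cond]
                    _place(sig, bump, face_samples[cond] + lpp_start, 0)
        data[ch] = sig

    # --- high-amplitude transients on a fraction of trials ---
    artifact_trials = []
    if config.artifact_rate > 0 and n_eeg > 0:
        spike_t = np.arange(round(-0.05 * fs), round(0.05 * fs)) / fs
        for i, row in faces.iterrows():
            if rng.uniform() < config.artifact_rate:
                artifact_trials.append(int(row["trial_index"]))
                ch = rng.integers(0, n_eeg)
                when = row["onset"] + rng.uniform(0.1, 0.9)
                sign = rng.choice([-1.0, 1.0])
                spike = sign * config.artifact_amp_uv * np.exp(-0.5 * (spike_t / 0.012) ** 2)
                _place(data[ch], spike, np.array([int(round(when * fs))]), len(spike) // 2)

    sid = subject_id or f"{group}{seed:04d}"
    rec = Recording(data, fs, labels, roles)
    events = EventTable(sched)
    truth = GroundTruth(
        subject_id=sid,
        group=group,
        hr_mean_bpm=traits["hr_mean_bpm"],
        r_peak_samples=r_samples,
        artifact_trials=artifact_trials,
        hep_amp_uv=traits["hep_amp_uv"],
        lpp_amps_uv=traits["lpp_amps_uv"],
        coupling_slope=traits["coupling_slope"],
        hit_rate=traits["hit_rate"],
        hct_accuracy=traits["hct_accuracy"],
    )
    return rec, events, truth


def _subject_plan(config: SimConfig, seed: int) -> list[tuple[str, str, int]]:
    """(subject_id, group, subject_seed) for the whole cohort, deterministic."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * config.n_per_group)
    plan = []
    k = 0
    for group in GROUPS:
        for i in range(config.n_per_group):
            sub_seed = int(children[k].generate_state(1)[0] % (2**31 - 1))
            plan.append((f"sub-{group}{i + 1:02d}", group, sub_seed))
            k += 1
    return plan


def iter_cohort(config: SimConfig, seed: int) -> Iterator[SubjectData]:
    """Yield simulated subjects one at a time (memory-friendly)."""
    config.validate()
    for sid, group, sub_seed in _subject_plan(config, seed):
        rec, events, truth = simulate_subject(config, group, sub_seed, subject_id=sid)
        yield SubjectData(sid, group, rec, events, truth)


def simulate_cohort(
    config: SimConfig,
    seed: int,
    outdir: str | Path,
    overwrite: bool = False,
    format: str = "edf",
) -> Path:
    """Write a full cohort to ``outdir``: per-subject recording + events +
    ground-truth JSON, plus a manifest recording the config hash and seeds.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  Identical ``(config, seed)`` produce
    byte-identical manifests.
    """
    config.validate()
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty (use overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    ext = "edf" if format == "edf" else "npz"
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": seed,
        "format": format,
        "subjects": [],
    }
    for sid, group, sub_seed in _subject_plan(config, seed):
        rec, events, truth = simulate_subject(config, group, sub_seed, subject_id=sid)
        write_recording(rec, outdir / f"{sid}.{ext}", format=format)
        write_events(events, outdir / f"{sid}_events.tsv")
        with open(outdir / f"{sid}_truth.json", "w") as f:
            json.dump(truth.to_dict(), f, indent=0, sort_keys=True)
        manifest["subjects"].append(
            {"subject_id": sid, "group": group, "seed": sub_seed,
             "recording": f"{sid}.{ext}", "events": f"{sid}_events.tsv",
             "truth": f"{sid}_truth.json"}
        )
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return outdir / "manifest.json"


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def _hct_reports(config: SimConfig, hr_bpm: float, accuracy: float, rng) -> list[tuple[float, int, int]]:
    reports = []
    for interval in HCT_INTERVALS_S:
        recorded = int(round(hr_bpm * interval / 60.0))
        eff = accuracy + rng.normal(0.0, config.hct_interval_jitter_sd)
        counted = max(0, int(round(recorded * eff)))
        reports.append((float(interval), recorded, counted))
    return reports


def simulate_behavior(config: SimConfig, seed: int) -> pd.DataFrame:
    """Behavioral table for the cohort: demographics, questionnaires,
    heartbeat-counting reports and capture hit rate.

    Uses the same per-subject seed chain as :func:`iter_cohort`, so rows are
    consistent with the simulated recordings of the same ``(config, seed)``.
    """
    config.validate()
    records = []
    for sid, group, sub_seed in _subject_plan(config, seed):
        rng = np.random.default_rng(sub_seed)
        traits = _draw_subject_traits(config, group, rng)
        records.append((sid, group, traits, np.random.default_rng(sub_seed + 1)))

    rows = []
    for gi, group in enumerate(GROUPS):
        group_recs = [r for r in records if r[1] == group]
        n_m = min(config.n_males[group], len(group_recs))
        sex_order = ["M"] * n_m + ["F"] * (len(group_recs) - n_m)
        for (sid, _, traits, rng2), sex in zip(group_recs, sex_order):
            reports = _hct_reports(config, traits["hr_mean_bpm"], traits["hct_accuracy"], rng2)
            rows.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    sex=sex,
                    age=traits["age"],
                    bmi=traits["bmi"],
                    education_years=traits["education_years"],
                    parent_education_years=traits["parent_education_years"],
                    duration_months=traits["duration_months"],
                    episodes=traits["episodes"],
                    bdi_total=traits["bdi_total"],
                    bdi_item20=traits["bdi_item20"],
                    bdi_cognitive_factor=traits["bdi_cognitive_factor"],
                    sai=traits["sai"],
                    tai=traits["tai"],
                    hct_reports=reports,
                    hit_rate=traits["hit_rate"],
                )
            )
    return subjects_to_frame(rows)


def simulate_measured_effects(
    config: SimConfig, seed: int, measurement_noise_uv: float = 0.2
) -> pd.DataFrame:
    """Subject-level table of *measured* HEP/LPP cluster means plus behavior.

    Emulates what the EEG pipeline estimates after trial averaging: each
    subject's latent component amplitude plus independent measurement noise
    (default 0.3 uV, the residual of averaging ~10 uV single-epoch noise
    over a few hundred epochs and a handful of channels).  The
    ``hep_frontocentral`` column is the coupled cluster; ``hep_left_frontal``
    and ``hep_centroparietal`` are uncoupled decoys drawn from the same
    group distribution.  The default 0.2 uV measurement noise is the
    residual of averaging ~10 uV single-epoch noise over the study's
    hundreds of epochs and a multi-channel cluster.  Intended for fast
    statistics-level recovery experiments; the full signal path is
    exercised by :func:`iter_cohort`.
    """
    config.validate()
    behavior = simulate_behavior(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]).generate_state(1)[0])
    rows = []
    for sid, group, sub_seed in _subject_plan(config, seed):
        traits = _draw_subject_traits(config, group, np.random.default_rng(sub_seed))
        m = lambda v: v + rng.normal(0.0, measurement_noise_uv)
        rows.append(
            {
                "subject_id": sid,
                "hep_frontocentral": m(traits["hep_amp_uv"]),
                "hep_left_frontal": m(rng.normal(config.hep_amp_uv[group], config.hep_between_sd_uv)),
                "hep_centroparietal": m(rng.normal(config.hep_amp_uv[group], config.hep_between_sd_uv)),
                "lpp_frontocentral_sad": m(traits["lpp_amps_uv"]["frontocentral"]["sad"]),
                "lpp_frontocentral_happy": m(traits["lpp_amps_uv"]["frontocentral"]["happy"]),
                "lpp_frontocentral_neutral": m(traits["lpp_amps_uv"]["frontocentral"]["neutral"]),
                "lpp_centroparietal_sad": m(traits["lpp_amps_uv"]["centroparietal"]["sad"]),
                "lpp_centroparietal_happy": m(traits["lpp_amps_uv"]["centroparietal"]["happy"]),
                "lpp_centroparietal_neutral": m(traits["lpp_amps_uv"]["centroparietal"]["neutral"]),
                "true_hep_amp": traits["hep_amp_uv"],
            }
        )
    return behavior.merge(pd.DataFrame(rows), on="subject_id")
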