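"""End-to-end orchestration: simulate -> preprocess -> cardiac -> epoch ->
cluster tests -> association, as one reproducible, fully seeded run.

The run is configured by a single serializable :class:`RunConfig`; the
report embeds the resolved configuration, every subject exclusion with its
rule, per-subject QC, group-level cluster statistics, the ECG confound
check, and the linkage analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from heplpp import cardiac, cluster, epochs as ep, preprocess, stats, synth
from heplpp.io import Montage, read_events, read_recording

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All parameters of a full analysis run."""

    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    seed: int = 0
    input_dir: str | None = None  # load a written cohort instead of simulating

    # preprocessing
    band_hz: tuple[float, float] = (0.3, 30.0)
    ecg_band_hz: tuple[float, float] = (0.5, 40.0)
    apply_car: bool = True

    # epoching / rejection
    lpp_epoch_ms: tuple[float, float] = (-200.0, 1000.0)
    lpp_baseline_ms: tuple[float, float] = (-200.0, 0.0)
    lpp_index_ms: tuple[float, float] = (300.0, 1000.0)
    hep_epoch_ms: tuple[float, float] = (-100.0, 600.0)
    hep_index_ms: tuple[float, float] = (455.0, 595.0)
    peak_to_peak_uv: float = 100.0
    trial_floor: int = 70
    hit_rate_floor: float = 0.5

    # exclusions / statistics
    hr_cap_bpm: float = 86.0
    forming_alpha: float = 0.05
    cluster_alpha: float = 0.05
    n_perm: int = 1000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = synth.SimConfig.from_dict(d["sim"])
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(json.load(f))


def _iter_subjects(config: RunConfig):
    if config.input_dir is None:
        yield from synth.iter_cohort(config.sim, config.seed)
        return
    indir = Path(config.input_dir)
    with open(indir / "manifest.json") as f:
        manifest = json.load(f)
    for entry in manifest["subjects"]:
        fmt = manifest.get("format", "edf")
        rec = read_recording(indir / entry["recording"], format=fmt)
        events = read_events(indir / entry["events"])
        with open(indir / entry["truth"]) as tf:
            td = json.load(tf)
        truth = synth.GroundTruth(
            subject_id=td["subject_id"], group=td["group"],
            hr_mean_bpm=td["hr_mean_bpm"],
            r_peak_samples=np.asarray(td["r_peak_samples"], dtype=int),
            artifact_trials=td["artifact_trials"], hep_amp_uv=td["hep_amp_uv"],
            lpp_amps_uv=td["lpp_amps_uv"], coupling_slope=td["coupling_slope"],
            hit_rate=td["hit_rate"], hct_accuracy=td["hct_accuracy"],
        )
        yield synth.SubjectData(entry["subject_id"], entry["group"], rec, events, truth)


def _process_subject(config: RunConfig, sub: synth.SubjectData, eeg_labels: list[str]):
    """Single-subject chain; returns (qc_row, exclusion_reason_or_None,
    lpp_matrix {cond: electrode-vector}, hep_vector, ecg_confound)."""
    rec = preprocess.bandpass_filter(
        sub.recording, *config.band_hz, ecg_band=config.ecg_band_hz
    )
    if config.apply_car:
        rec = preprocess.common_average_reference(rec)

    ecg_sig = rec.data[rec.ecg_index]
    rpeaks = cardiac.detect_r_peaks(ecg_sig, rec.fs)
    qc: dict = {"subject_id": sub.subject_id, "group": sub.group, "n_r_peaks": len(rpeaks)}
    if len(rpeaks) < 2:
        return qc, "no detectable heartbeats", None, None, None
    hr = cardiac.heart_rate(rpeaks)
    qc["heart_rate_bpm"] = hr
    if cardiac.hr_exclusion(rpeaks, config.hr_cap_bpm):
        return qc, f"heart rate > {config.hr_cap_bpm:g} bpm", None, None, None
    if sub.truth is not None and sub.truth.hit_rate < config.hit_rate_floor:
        return qc, "failed capture-trial responses", None, None, None

    lpp = ep.extract_stimulus_epochs(
        rec,
        sub.events,
        window_ms=config.lpp_epoch_ms,
        baseline_ms=config.lpp_baseline_ms,
    )
    lpp = ep.reject_artifacts(lpp, config.peak_to_peak_uv)
    ret = ep.retention_report(lpp, config.trial_floor)
    qc["lpp_retained"] = ret["retained_per_condition"]
    if ret["flagged"]:
        return qc, f"retained trials below floor {config.trial_floor}", None, None, None

    hep = ep.extract_heartbeat_epochs(rec, rpeaks, sub.events, window_ms=config.hep_epoch_ms)
    if hep.n_trials == 0:
        return qc, "no qualifying cue-period heartbeats", None, None, None
    hep = ep.reject_artifacts(hep, config.peak_to_peak_uv)
    if not np.any(hep.kept):
        return qc, "all heartbeat epochs rejected", None, None, None
    qc["hep_epochs"] = int(np.sum(hep.kept))

    conds = sorted(set(lpp.conditions))
    lpp_mat = {
        cond: np.array(
            [ep.mean_amplitude(lpp, config.lpp_index_ms, [lab], condition=cond)
             for lab in eeg_labels]
        )
        for cond in conds
    }
    hep_vec = np.array(
        [ep.mean_amplitude(hep, config.hep_index_ms, [lab]) for lab in eeg_labels]
    )
    ecg_conf = ep.ecg_confound_amplitude(hep, config.hep_index_ms)
    return qc, None, lpp_mat, hep_vec, ecg_conf


def _cluster_to_dict(res: cluster.ClusterResult) -> dict:
    return {
        "forming_threshold": res.forming_threshold,
        "n_perm": res.n_perm,
        "exact": res.exact,
        "clusters": [
            {"electrodes": c.electrodes, "mass": c.mass, "sign": c.sign, "p": c.p_value}
            for c in res.clusters
        ],
    }


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and return the report dictionary.

    Deterministic given the embedded seeds.  Any stage failure raises with
    the stage name and subject id attached.
    """
    sim = config.sim
    eeg_labels = list(sim.channels)
    montage = Montage.standard(tuple(eeg_labels))
    adjacency = cluster.build_adjacency(montage)

    qc_rows, exclusions = [], []
    lpp_by_group: dict = {}
    hep_by_group: dict = {}
    ecg_by_group: dict = {}
    kept_ids: dict = {"MDD": [], "HC": []}

    for sub in _iter_subjects(config):
        try:
            qc, reason, lpp_mat, hep_vec, ecg_conf = _process_subject(config, sub, eeg_labels)
        except Exception as exc:
            raise RuntimeError(
                f"stage failure for subject {sub.subject_id}: {exc}"
            ) from exc
        qc_rows.append(qc)
        if reason is not None:
            exclusions.append({"subject_id": sub.subject_id, "rule": reason})
            continue
        kept_ids[sub.group].append(sub.subject_id)
        for cond, vec in lpp_mat.items():
            lpp_by_group.setdefault(sub.group, {}).setdefault(cond, []).append(vec)
        hep_by_group.setdefault(sub.group, []).append(hep_vec)
        ecg_by_group.setdefault(sub.group, []).append(ecg_conf)

    report: dict = {
        "config": config.to_dict(),
        "subjects": qc_rows,
        "exclusions": exclusions,
        "n_analyzed": {g: len(v) for g, v in kept_ids.items()},
    }
    if any(len(v) < 2 for v in kept_ids.values()):
        report["error"] = "fewer than 2 analyzable subjects in a group"
        return report

    hep_a = np.vstack(hep_by_group["MDD"])
    hep_b = np.vstack(hep_by_group["HC"])
    hep_res = cluster.cluster_permutation_test(
        hep_a, hep_b, adjacency, config.forming_alpha, config.n_perm, seed=config.seed
    )
    report["hep_cluster_test"] = _cluster_to_dict(hep_res)
    hep_cols = [i for i, lab in enumerate(eeg_labels) if lab in sim.hep_channels]
    if hep_cols:
        report["hep_mean_on_target_channels"] = {
            "MDD": float(hep_a[:, hep_cols].mean()),
            "HC": float(hep_b[:, hep_cols].mean()),
        }

    lpp_results = {}
    conds = sorted(lpp_by_group["MDD"].keys())
    for cond in conds:
        res = cluster.cluster_permutation_test(
            np.vstack(lpp_by_group["MDD"][cond]),
            np.vstack(lpp_by_group["HC"][cond]),
            adjacency,
            config.forming_alpha,
            config.n_perm,
            seed=config.seed + 1,
        )
        lpp_results[cond] = res
        report.setdefault("lpp_cluster_tests", {})[cond] = _cluster_to_dict(res)

    ecg_t = stats.two_sample_t(np.array(ecg_by_group["MDD"]), np.array(ecg_by_group["HC"]))
    report["ecg_confound_t"] = {"t": ecg_t.statistic, "df": ecg_t.df, "p": ecg_t.p_value}

    # --- association: subject table with cluster means ---
    behavior = synth.simulate_behavior(sim, config.seed) if config.input_dir is None else None
    if behavior is not None:
        analyzed = kept_ids["MDD"] + kept_ids["HC"]
        table = behavior[behavior["subject_id"].isin(analyzed)].reset_index(drop=True)

        def cluster_channels(res: cluster.ClusterResult, fallback: tuple[str, ...]) -> list[str]:
            sig = res.significant(config.cluster_alpha)
            chans = [lab for c in sig for lab in c.electrodes]
            usable = [c for c in (chans or list(fallback)) if c in eeg_labels]
            return usable or list(eeg_labels)

        hep_chans = cluster_channels(hep_res, sim.hep_channels)
        sad_res = lpp_results.get("sad")
        lpp_fc = [c for c in sim.lpp_frontocentral if c in eeg_labels] or eeg_labels
        lpp_cp = [c for c in sim.lpp_centroparietal if c in eeg_labels] or eeg_labels
        if sad_res is not None and sad_res.significant(config.cluster_alpha):
            pos = [lab for c in sad_res.significant(config.cluster_alpha) if c.sign > 0
                   for lab in c.electrodes]
            neg = [lab for c in sad_res.significant(config.cluster_alpha) if c.sign < 0
                   for lab in c.electrodes]
            lpp_fc = pos or lpp_fc  # MDD-enhanced frontocentral cluster
            lpp_cp = neg or lpp_cp  # MDD-attenuated centroparietal cluster

        idx = {lab: i for i, lab in enumerate(eeg_labels)}

        def set_mean(vecs, chans):
            sel = [idx[c] for c in chans]
            return [float(v[sel].mean()) for v in vecs]

        col_data = {"subject_id": analyzed}
        col_data["hep_cluster"] = set_mean(hep_by_group["MDD"], hep_chans) + set_mean(
            hep_by_group["HC"], hep_chans
        )
        for name, chans in (("lpp_frontocentral_sad", lpp_fc), ("lpp_centroparietal_sad", lpp_cp)):
            vals = []
            for g in ("MDD", "HC"):
                sad_vecs = lpp_by_group[g]["sad"] if "sad" in lpp_by_group[g] else None
                vals += set_mean(sad_vecs, chans) if sad_vecs else [np.nan] * len(kept_ids[g])
            col_data[name] = vals
        table = table.merge(pd.DataFrame(col_data), on="subject_id")

        # partial correlation needs n > n_controls + 2 per group; at the
        # study scale (27/group) the full covariate set fits, scaled-down
        # runs keep a leading subset
        n_min = min(len(v) for v in kept_ids.values())
        covariates = tuple(stats.DEFAULT_COVARIATES[: max(0, n_min - 3)])
        try:
            linkage = stats.linkage_analysis(
            table,
            hep_cols=["hep_cluster"],
            lpp_cols=["lpp_frontocentral_sad", "lpp_centroparietal_sad"],
            covariates=covariates,
                stepwise_targets={
                    "lpp_frontocentral_sad": [],
                    "lpp_centroparietal_sad": ["bdi_cognitive_factor"],
                },
            )
        except ValueError as exc:
            report["linkage"] = {"error": str(exc)}
            return report
        report["linkage"] = {
            "partial_correlations": {
                g: {f"{h}~{l}": v for (h, l), v in cells.items()}
                for g, cells in linkage["partial_correlations"].items()
            },
            "stepwise_models": {
                t: dataclasses.asdict(m) for t, m in linkage["stepwise_models"].items()
            },
            "hep_cluster_channels": hep_chans,
            "lpp_frontocentral_channels": lpp_fc,
            "lpp_centroparietal_channels": lpp_cp,
        }
    return report
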