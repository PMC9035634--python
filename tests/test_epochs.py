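"""Epoch extraction, artifact rejection, mean-amplitude indices."""

import numpy as np
import pandas as pd
import pytest

from heplpp.cardiac import RPeakSeries, detect_r_peaks
from heplpp.epochs import (
    ecg_confound_amplitude,
    extract_heartbeat_epochs,
    extract_stimulus_epochs,
    mean_amplitude,
    reject_artifacts,
    retention_report,
)
from heplpp.io import EventTable, Recording, infer_roles
from heplpp.preprocess import bandpass_filter
from heplpp.synth import SimConfig, simulate_subject


def events_frame(rows):
    return EventTable(pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "trial_index"]))


def flat_recording(value=0.0, n_ch=3, dur_s=20.0, fs=1000.0):
    labels = [f"E{i}" for i in range(n_ch - 1)] + ["ECG"]
    data = np.full((n_ch, int(dur_s * fs)), float(value))
    return Recording(data, fs, labels, infer_roles(labels))


SIMPLE_EVENTS = events_frame(
    [
        (2.0, 2.0, "cue", 0),
        (4.0, 2.5, "face_sad", 0),
        (8.0, 2.0, "cue", 1),
        (10.0, 2.5, "face_happy", 1),
        (14.0, 2.0, "cue", 2),
        (16.0, 2.5, "face_neutral", 2),
    ]
)


class TestStimulusEpochs:
    def test_constant_channel_baselined_to_zero(self):
        rec = flat_recording(value=7.5)
        ep = extract_stimulus_epochs(rec, SIMPLE_EVENTS)
        assert ep.n_trials == 3
        assert np.all(ep.data[:2] == 0.0)

    def test_counts_with_capture_trials(self, small_config, sim_subject):
        rec, events, _ = sim_subject
        ep = extract_stimulus_epochs(rec, events)
        n = small_config.n_trials
        n_capture = round(small_config.capture_fraction * n)
        assert ep.n_trials == n - n_capture
        per_cond = ep.kept_per_condition()
        assert sum(per_cond.values()) == n - n_capture

    def test_boundary_epoch_dropped(self):
        rec = flat_recording(dur_s=12.0)
        ev = events_frame(
            [
                (2.0, 2.0, "cue", 0),
                (4.0, 2.5, "face_sad", 0),
                (9.0, 2.0, "cue", 1),
                (11.5, 2.5, "face_sad", 1),  # 11.5 + 1.0 s > 12 s recording
            ]
        )
        ep = extract_stimulus_epochs(rec, ev)
        assert ep.n_trials == 1
        assert list(ep.trial_ids) == [0]

    def test_window_sample_count(self):
        rec = flat_recording()
        ep = extract_stimulus_epochs(rec, SIMPLE_EVENTS, window_ms=(-200, 1000))
        assert ep.data.shape[1] == 1200


class TestHeartbeatEpochs:
    def test_guard_excludes_beats_near_previous_face(self):
        rec = flat_recording(dur_s=10.0)
        ev = events_frame(
            [
                (0.5, 1.0, "cue", 0),
                (1.5, 1.0, "face_sad", 0),
                (2.0, 2.6, "cue", 1),  # cue begins 0.5 s after previous face onset
                (4.6, 2.5, "face_happy", 1),
            ]
        )
        # beat at 2.4 s: epoch [2.3, 3.0] inside the cue but starts before
        # 1.5 + 1.0 s guard -> excluded; beat at 3.6 s: [3.5, 4.2] -> kept
        rp = RPeakSeries(np.array([2400, 3600]), 1000.0)
        ep = extract_heartbeat_epochs(rec, rp, ev)
        assert ep.n_trials == 1
        assert list(ep.conditions) == ["happy"]

    def test_epoch_must_fit_inside_cue_period(self):
        rec = flat_recording(dur_s=10.0)
        ev = events_frame([(3.0, 2.0, "cue", 0), (5.0, 2.5, "face_sad", 0)])
        # epoch [-100, 600] around 3.05 s starts before the cue
        rp = RPeakSeries(np.array([3050, 4000, 4600]), 1000.0)
        ep = extract_heartbeat_epochs(rec, rp, ev)
        # 4.0 s fits ([3.9, 4.6] in [3, 5]); 4.6 s does not (ends 5.2 > 5.0)
        assert ep.n_trials == 1

    def test_expected_beats_per_trial_near_analytic(self):
        """~(cue span - epoch span) / IBI qualifying beats per 2 s cue at 60 bpm."""
        cfg = SimConfig(
            n_per_group=1, n_trials=40, channels=("Cz",),
            heart_rate_bpm={"MDD": 60.0, "HC": 60.0},
            heart_rate_between_sd={"MDD": 0.0, "HC": 0.0},
            ibi_jitter_sd_s=0.0, artifact_rate=0.0,
            cue_duration_range_s=(2.0, 2.0),
        )
        rec, events, truth = simulate_subject(cfg, "HC", seed=2)
        rp = RPeakSeries(truth.r_peak_samples, cfg.fs)
        ep = extract_heartbeat_epochs(rec, rp, events)
        per_trial = ep.n_trials / cfg.n_trials
        assert 0.8 <= per_trial <= 1.8  # uniform-phase expectation ~1.3

    def test_hep_amplitude_recovery_without_cfa(self):
        """Injected HEP window mean is recovered on the target channel,
        unbiased across seeds (no filtering, zero CFA)."""
        cfg = SimConfig(
            n_per_group=1, n_trials=15, channels=("FCz", "FC2", "Cz", "Pz"),
            hep_channels=("FCz", "FC2"), cfa_gain_mean=0.0, cfa_gain_sd=0.0,
            artifact_rate=0.0, noise_sd_uv=6.0, line_noise_uv=0.0,
        )
        errs = []
        for s in range(20):
            rec, events, truth = simulate_subject(cfg, "HC", seed=300 + s)
            rp = RPeakSeries(truth.r_peak_samples, cfg.fs)
            ep = extract_heartbeat_epochs(rec, rp, events)
            errs.append(mean_amplitude(ep, (455, 595), ["FCz"]) - truth.hep_amp_uv)
        errs = np.array(errs)
        se = errs.std(ddof=1) / np.sqrt(errs.size)
        assert abs(errs.mean()) < 2 * se + 1e-12


class TestRejection:
    def _epochs(self, data, conds=None):
        n_tr = data.shape[2]
        from heplpp.epochs import EpochSet

        return EpochSet(
            data, 1000.0, ["E0", "E1"], ["eeg", "eeg"], "face", (0.0, data.shape[1]),
            conditions=np.array(conds if conds is not None else ["sad"] * n_tr),
        )

    def test_all_zero_nothing_rejected(self):
        ep = self._epochs(np.zeros((2, 100, 8)))
        out = reject_artifacts(ep)
        assert not out.rejected.any()

    def test_single_spiked_trial_rejected(self, rng):
        data = rng.normal(0, 5, size=(2, 100, 10))
        data[1, 50, 4] += 500.0
        out = reject_artifacts(self._epochs(data), peak_to_peak_uv=100.0)
        assert list(np.flatnonzero(out.rejected)) == [4]

    def test_order_independence(self, rng):
        data = rng.normal(0, 40, size=(2, 100, 30))
        ep = self._epochs(data)
        perm = rng.permutation(30)
        ep_perm = self._epochs(data[:, :, perm])
        m1 = reject_artifacts(ep).rejected
        m2 = reject_artifacts(ep_perm).rejected
        np.testing.assert_array_equal(m2, m1[perm])

    def test_retention_report_flags_low_condition(self):
        data = np.zeros((2, 100, 6))
        ep = self._epochs(data, conds=["sad"] * 3 + ["happy"] * 3)
        rep = retention_report(reject_artifacts(ep), floor=4)
        assert rep["flagged"]
        assert rep["retained_per_condition"] == {"sad": 3, "happy": 3}

    def test_injected_artifacts_detected_in_generator_output(self, small_config):
        rec, events, truth = simulate_subject(small_config, "HC", seed=77)
        rec = bandpass_filter(rec)
        ep = reject_artifacts(extract_stimulus_epochs(rec, events))
        capture = events.capture_trial_indices()
        expected_bad = {t for t in truth.artifact_trials if t not in capture}
        flagged = set(ep.trial_ids[ep.rejected])
        assert expected_bad <= flagged


class TestMeanAmplitude:
    def _const_epochs(self, value, n_times=700):
        from heplpp.epochs import EpochSet

        data = np.full((1, n_times, 4), float(value))
        return EpochSet(
            data, 1000.0, ["Cz"], ["eeg"], "face", (0.0, float(n_times)),
            conditions=np.array(["sad"] * 4),
        )

    def test_constant_epoch(self):
        assert mean_amplitude(self._const_epochs(3.0), (100, 600), ["Cz"]) == 3.0

    def test_linear_ramp(self):
        from heplpp.epochs import EpochSet

        n = 1000
        ramp = np.linspace(0, 1, n, endpoint=False)
        data = np.tile(ramp, (1, 1, 1)).reshape(1, n, 1)
        ep = EpochSet(
            data, 1000.0, ["Cz"], ["eeg"], "face", (0.0, 1000.0),
            conditions=np.array(["sad"]),
        )
        assert mean_amplitude(ep, (0, 1000), ["Cz"]) == pytest.approx(0.5, abs=1e-3)

    def test_matches_bruteforce_loop(self, rng):
        from heplpp.epochs import EpochSet

        data = rng.normal(size=(3, 500, 7))
        rejected = np.array([False, True, False, False, False, True, False])
        ep = EpochSet(
            data, 1000.0, ["A", "B", "C"], ["eeg"] * 3, "face", (-100.0, 400.0),
            conditions=np.array(["sad"] * 7), rejected=rejected,
        )
        # naive re-computation: average kept trials, then loop over samples
        a, b = 150, 400  # 50..300 ms relative to -100 ms epoch start
        acc = n = 0
        for ch in (0, 2):
            for s in range(a, b):
                vals = [data[ch, s, t] for t in range(7) if not rejected[t]]
                acc += np.mean(vals)
                n += 1
        expected = acc / n
        got = mean_amplitude(ep, (50, 300), ["A", "C"])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            mean_amplitude(self._const_epochs(1.0), (600, 900), ["Cz"])

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError, match="Oz"):
            mean_amplitude(self._const_epochs(1.0), (100, 200), ["Oz"])


class TestEcgConfound:
    def test_constant_ecg_value(self):
        from heplpp.epochs import EpochSet

        data = np.zeros((2, 700, 5))
        data[1] = 4.0
        ep = EpochSet(
            data, 1000.0, ["Cz", "ECG"], ["eeg", "ecg"], "rpeak", (-100.0, 600.0),
            conditions=np.array(["sad"] * 5),
        )
        assert ecg_confound_amplitude(ep) == 4.0

    def test_requires_single_ecg_channel(self):
        from heplpp.epochs import EpochSet

        ep = EpochSet(
            np.zeros((1, 700, 2)), 1000.0, ["Cz"], ["eeg"], "rpeak", (-100.0, 600.0),
            conditions=np.array(["sad"] * 2),
        )
        with pytest.raises(ValueError, match="ecg"):
            ecg_confound_amplitude(ep)
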