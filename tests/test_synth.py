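"""Synthetic-data generator: signal composition, schedules, artifacts, sweeps."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import signal as sps

from thetagamma import synth
from thetagamma.core import HFS_TRAIN_DURATION_S, Recording, StimEvent


class TestGenCoupledEEG:
    def test_uncoupled_noise_free_is_sum_of_two_sinusoids(self, clean_config):
        rec = synth.gen_coupled_eeg(clean_config)
        t = np.arange(rec.n_samples) / clean_config.fs_hz
        expected = (clean_config.theta_amp_uv * np.cos(2 * np.pi * 8.0 * t)
                    + clean_config.gamma_amp_uv * np.cos(2 * np.pi * 78.0 * t))
        np.testing.assert_allclose(rec.samples, expected, atol=1e-9)

    def test_psd_peaks_at_configured_frequencies(self):
        cfg = synth.SynthConfig(duration_s=4.1, theta_freq_hz=8.0, gamma_freq_hz=78.0,
                                coupling_depth=0.8, seed=1)
        rec = synth.gen_coupled_eeg(cfg)
        freqs, pxx = sps.welch(rec.samples, fs=cfg.fs_hz, nperseg=2048)
        for f0 in (8.0, 78.0):
            k = int(np.argmin(np.abs(freqs - f0)))
            lo, hi = max(0, k - 3), k + 4
            assert np.argmax(pxx[lo:hi]) + lo in (k - 1, k, k + 1)

    def test_seeded_determinism(self):
        cfg = synth.SynthConfig(duration_s=2.0, seed=7)
        a = synth.gen_coupled_eeg(cfg).samples
        b = synth.gen_coupled_eeg(cfg).samples
        np.testing.assert_array_equal(a, b)
        c = synth.gen_coupled_eeg(dataclasses.replace(cfg, seed=8)).samples
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("depth", [0.0, 0.25, 0.5, 0.8, 1.0])
    def test_modulation_depth_fidelity(self, depth):
        """Hilbert envelope of the noise-free gamma component has exactly the
        configured modulation depth (within 1%)."""
        cfg = synth.SynthConfig(duration_s=8.0, coupling_depth=depth, theta_amp_uv=0.0,
                                noise_amp_uv=0.0, line_amp_uv=0.0,
                                theta_phase_drift=0.0, seed=3)
        rec = synth.gen_coupled_eeg(cfg)
        env = np.abs(sps.hilbert(rec.samples))[2000:-2000]
        measured = (env.max() - env.min()) / (env.max() + env.min())
        assert measured == pytest.approx(depth, abs=0.01)

    @pytest.mark.parametrize("bad", [
        {"coupling_depth": 1.5},
        {"coupling_depth": -0.1},
        {"fs_hz": 100.0},            # below 2 * gamma
        {"duration_s": 0.0},
        {"noise_exponent": -1.0},
        {"theta_phase_drift": -2.0},
    ])
    def test_invalid_config_rejected(self, bad):
        cfg = dataclasses.replace(synth.SynthConfig(), **bad)
        with pytest.raises(ValueError):
            synth.gen_coupled_eeg(cfg)


class TestStimSchedule:
    def test_ten_trains_at_ten_second_intervals(self):
        events = synth.gen_stim_schedule(10, 10.0, 0.0, 100.0)
        trains = [ev for ev in events if ev.kind == "hfs_train"]
        assert [ev.time_s for ev in trains] == [float(10 * i) for i in range(10)]
        assert all(ev.duration_s == pytest.approx(0.075) for ev in trains)

    def test_zero_trains_gives_only_test_pulses(self):
        events = synth.gen_stim_schedule(0, 10.0, 0.025, 100.0)
        assert events and all(ev.kind == "test_pulse" for ev in events)
        assert events[0].time_s == pytest.approx(40.0)

    def test_single_train_duration_is_15_pulses_at_200hz(self):
        (ev,) = synth.gen_stim_schedule(1, 10.0, 0.0, 10.0)
        assert ev.duration_s == pytest.approx(15 / 200.0)
        assert ev.duration_s == pytest.approx(HFS_TRAIN_DURATION_S)

    def test_overlapping_trains_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synth.gen_stim_schedule(5, 0.05, 0.0, 100.0)

    def test_train_beyond_duration_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_stim_schedule(10, 10.0, 0.0, 50.0)


class TestInjectArtifacts:
    def _recording(self, seed=0):
        cfg = synth.SynthConfig(duration_s=30.0, seed=seed)
        return synth.gen_coupled_eeg(cfg)

    def test_empty_event_list_leaves_recording_unchanged(self):
        rec = self._recording()
        out = synth.inject_artifacts(rec, [])
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_train_dominates_amplitude_inside_its_window(self):
        rec = self._recording()
        ev = StimEvent(time_s=10.0, kind="hfs_train", duration_s=0.075)
        out = synth.inject_artifacts(rec, [ev])
        fs = rec.fs_hz
        i0, i1 = int(10.0 * fs), int(10.08 * fs)
        assert np.max(np.abs(out.samples[i0:i1])) > np.max(np.abs(rec.samples))

    def test_samples_outside_event_windows_unchanged(self):
        rec = self._recording()
        ev = StimEvent(time_s=10.0, kind="hfs_train", duration_s=0.075)
        out = synth.inject_artifacts(rec, [ev])
        fs = rec.fs_hz
        changed = np.nonzero(out.samples != rec.samples)[0]
        assert changed.min() >= int(10.0 * fs) - 1
        assert changed.max() <= int(10.08 * fs) + 1

    def test_ten_trains_give_at_least_ten_disjoint_suprathreshold_intervals(self):
        rec = self._recording()
        events = [StimEvent(time_s=1.0 + 2.5 * i, kind="hfs_train", duration_s=0.075)
                  for i in range(10)]
        out = synth.inject_artifacts(rec, events)
        thresh = 5.0 * np.sqrt(np.mean(rec.samples ** 2))
        above = np.abs(out.samples) > thresh
        n_intervals = int(np.sum(np.diff(above.astype(int)) == 1))
        assert n_intervals >= 10

    def test_event_outside_recording_rejected(self):
        rec = self._recording()
        ev = StimEvent(time_s=40.0, kind="hfs_train", duration_s=0.075)
        with pytest.raises(ValueError):
            synth.inject_artifacts(rec, [ev])


class TestEvokedSweepGeneration:
    def test_pre_hfs_noise_free_measures_equal_baselines(self):
        from thetagamma.evoked import fepsp_slope, ps_amplitude

        m = synth.PlasticityModel(sweep_noise_frac=0.0)
        sw = synth.gen_evoked_sweep(m, -5.0)
        assert fepsp_slope(sw) == pytest.approx(m.baseline_slope_mv_ms, rel=1e-6)
        assert ps_amplitude(sw) == pytest.approx(m.baseline_ps_mv, rel=1e-6)

    def test_post_hfs_scaling_by_potentiation_factor(self):
        from thetagamma.evoked import fepsp_slope

        m = synth.PlasticityModel(potentiation_factor=1.5, sweep_noise_frac=0.0)
        sw = synth.gen_evoked_sweep(m, 0.0)
        assert fepsp_slope(sw) == pytest.approx(1.5 * m.baseline_slope_mv_ms, rel=1e-6)

    def test_decay_returns_to_baseline_after_24h(self):
        m = synth.PlasticityModel(potentiation_factor=1.5, decay_tau_min=240.0)
        assert m.factor(1440.0) == pytest.approx(1.0, abs=0.01)
        assert m.factor(-1.0) == 1.0
        persistent = synth.PlasticityModel(decay_tau_min=math.inf)
        assert persistent.factor(1440.0) == persistent.potentiation_factor

    def test_sweep_determinism_and_noise(self):
        m = synth.PlasticityModel(sweep_noise_frac=0.05)
        a = synth.gen_evoked_sweep(m, 5.0, seed=11).samples
        b = synth.gen_evoked_sweep(m, 5.0, seed=11).samples
        np.testing.assert_array_equal(a, b)
        c = synth.gen_evoked_sweep(m, 5.0, seed=12).samples
        assert not np.array_equal(a, c)

    def test_invalid_plasticity_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_evoked_sweep(synth.PlasticityModel(potentiation_factor=0.5), 0.0)
        with pytest.raises(ValueError):
            synth.gen_evoked_sweep(synth.PlasticityModel(decay_tau_min=-1.0), 0.0)


class TestExperimentPresets:
    def test_control_truth_has_persistent_ltp(self):
        exp = synth.gen_experiment("control", seed=0)
        assert math.isinf(exp.truth.plasticity.decay_tau_min)
        depths = exp.truth.coupling_depth_during
        assert len(set(depths)) == 1

    def test_mk801_truth_halves_coupling_in_second_half(self):
        exp = synth.gen_experiment("mk801_w1", seed=0)
        d = exp.truth.coupling_depth_during
        assert np.mean(d[5:]) < np.mean(d[:5])
        assert exp.truth.plasticity.decay_tau_min == pytest.approx(240.0)

    @pytest.mark.parametrize("condition", synth.CONDITIONS)
    def test_recording_covers_all_five_windows(self, condition):
        exp = synth.gen_experiment(condition, seed=1)
        onset = min(ev.time_s for ev in exp.recording.hfs_events())
        assert onset >= 100.0
        assert exp.recording.duration_s >= onset + 400.0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            synth.gen_experiment("sham", seed=0)

    def test_experiment_determinism(self):
        a = synth.gen_experiment("control", seed=5)
        b = synth.gen_experiment("control", seed=5)
        np.testing.assert_array_equal(a.recording.samples, b.recording.samples)
        np.testing.assert_array_equal(a.sweeps[3][1][2].samples, b.sweeps[3][1][2].samples)
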