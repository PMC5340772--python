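"""Morlet filtering, ESC, surrogate normalization and comodulograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from thetagamma import pac, synth
from thetagamma.pac import WaveletSpec
from conftest import make_epoch

FS = 2000.0


def _tone(freq, duration=4.1, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def _filtered_pair(samples, f_low=8.0, f_high=78.0, fs=FS):
    low = np.real(pac.morlet_filter(samples, fs, WaveletSpec(f_low)))
    env = np.abs(pac.morlet_filter(samples, fs, WaveletSpec(f_high)))
    trim = int(np.ceil(WaveletSpec(f_low).sigma_t() * fs))
    return low[trim:-trim], env[trim:-trim]


class TestMorletFilter:
    def test_unit_tone_at_center_has_unit_envelope(self):
        out = pac.morlet_filter(_tone(8.0), FS, WaveletSpec(8.0))
        env = np.abs(out)[1500:-1500]
        assert np.all(np.abs(env - 1.0) < 0.05)

    def test_out_of_band_tone_rejected(self):
        out = pac.morlet_filter(_tone(8.0), FS, WaveletSpec(78.0))
        assert np.max(np.abs(out)[1500:-1500]) < 0.05

    def test_zero_signal_zero_envelope_same_length(self):
        out = pac.morlet_filter(np.zeros(5000), FS, WaveletSpec(40.0))
        assert len(out) == 5000 and np.allclose(np.abs(out), 0.0)

    def test_phase_tracks_tone(self):
        out = pac.morlet_filter(np.cos(2 * np.pi * 8.0 * np.arange(8200) / FS),
                                FS, WaveletSpec(8.0))
        inst_freq = np.diff(np.unwrap(np.angle(out)))[2000:-2000] * FS / (2 * np.pi)
        assert np.mean(inst_freq) == pytest.approx(8.0, abs=0.05)

    def test_center_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            pac.morlet_filter(np.zeros(100), FS, WaveletSpec(1000.0))

    def test_invalid_wavelet_spec_rejected(self):
        with pytest.raises(ValueError):
            WaveletSpec(8.0, width_cycles=0.0)


class TestESC:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(500)
        assert pac.esc(x, x) == pytest.approx(1.0)

    def test_perfect_anticorrelation_is_minus_one(self, rng):
        x = rng.standard_normal(500)
        assert pac.esc(x, -x + 5.0) == pytest.approx(-1.0)

    def test_noise_free_coupling_scores_above_095(self):
        cfg = synth.SynthConfig(duration_s=4.1, coupling_depth=0.8, noise_amp_uv=0.0,
                                line_amp_uv=0.0, theta_phase_drift=0.0, seed=0)
        rec = synth.gen_coupled_eeg(cfg)
        low, env = _filtered_pair(rec.samples)
        assert pac.esc(low, env) > 0.95

    def test_phase_lag_pi_flips_the_sign(self):
        kw = dict(duration_s=4.1, coupling_depth=0.8, noise_amp_uv=0.0,
                  line_amp_uv=0.0, theta_phase_drift=0.0, seed=0)
        rec0 = synth.gen_coupled_eeg(synth.SynthConfig(coupling_phase_lag=0.0, **kw))
        rec_pi = synth.gen_coupled_eeg(synth.SynthConfig(coupling_phase_lag=np.pi, **kw))
        s0 = pac.esc(*_filtered_pair(rec0.samples))
        s_pi = pac.esc(*_filtered_pair(rec_pi.samples))
        assert s0 > 0.95 and s_pi < -0.95

    def test_constant_input_warns_and_returns_zero(self):
        with pytest.warns(pac.DegenerateInputWarning):
            assert pac.esc(np.ones(100), np.arange(100.0)) == 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            pac.esc(np.zeros(10), np.zeros(11))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hnp.arrays(np.float64, st.integers(10, 200),
                      elements=st.floats(-1e6, 1e6, allow_nan=False)),
           st.integers(0, 2 ** 31 - 1))
    def test_score_always_bounded(self, a, seed):
        b = np.random.default_rng(seed).standard_normal(len(a))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", pac.DegenerateInputWarning)
            score = pac.esc(a, b)
        assert -1.0 <= score <= 1.0


class TestSurrogateNormalize:
    def test_identical_seed_identical_z(self, coupled_epoch_factory):
        epo = coupled_epoch_factory(depth=0.6, seed=2)
        low, env = _filtered_pair(epo.samples)
        raw = pac.esc(low, env)
        z1 = pac.surrogate_normalize(raw, low, env, seed=42)
        z2 = pac.surrogate_normalize(raw, low, env, seed=42)
        assert z1 == z2
        assert z1 != pac.surrogate_normalize(raw, low, env, seed=43)

    def test_strong_coupling_at_high_snr_gives_large_z(self):
        hits = 0
        for seed in range(20):
            cfg = synth.SynthConfig(duration_s=8.0, coupling_depth=0.8,
                                    noise_amp_uv=10.0, seed=seed)
            rec = synth.gen_coupled_eeg(cfg)
            low, env = _filtered_pair(rec.samples)
            z = pac.surrogate_normalize(pac.esc(low, env), low, env, seed=seed)
            hits += z > 3.0
        assert hits >= 19

    def test_uncoupled_noise_rarely_exceeds_z_bounds(self):
        exceed = 0
        n = 40
        for seed in range(n):
            x = np.random.default_rng(seed).standard_normal(8200)
            low, env = _filtered_pair(x)
            z = pac.surrogate_normalize(pac.esc(low, env), low, env, seed=seed)
            exceed += abs(z) > 1.96
        assert exceed / n <= 0.15

    def test_degenerate_surrogate_sd_rejected(self):
        low = np.sin(np.linspace(0, 20 * np.pi, 2000))
        env = np.ones(2000)
        with pytest.raises(ValueError, match="surrogate"):
            pac.surrogate_normalize(0.0, low, env, seed=0)

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValueError):
            pac.surrogate_normalize(0.5, np.zeros(10), np.zeros(10), n_shuffles=1)


class TestComodulogram:
    def test_true_pair_among_top_cells_high_snr(self, coupled_epoch_factory):
        """Single-epoch maps rank the true pair at/near the top; exact argmax
        localization needs epoch pooling (tested below) because adjacent gamma
        bins overlap the width-7 wavelet's passband."""
        epo = coupled_epoch_factory(depth=0.8, seed=1, noise_amp_uv=15.0)
        com = pac.comodulogram(epo, n_shuffles=200, seed=1)
        i = com.env_centers.index(78.0)
        j = com.sig_centers.index(8.0)
        true_z = com.z[i, j]
        finite = com.z[np.isfinite(com.z)]
        assert true_z >= np.quantile(finite, 0.97)

    def test_pooled_peak_recovered_at_study_noise(self):
        cfg = synth.SynthConfig(duration_s=20.5, coupling_depth=0.8, seed=1)
        rec = synth.gen_coupled_eeg(cfg)
        n = int(4.1 * FS)
        eps = [make_epoch(rec.samples[k * n:(k + 1) * n], index=k) for k in range(5)]
        com = pac.comodulogram_mean(eps, n_shuffles=200, seed=1)
        env_c, sig_c = com.argmax_pair()
        assert abs(env_c - 78.0) <= 5.0 and abs(sig_c - 8.0) <= 5.0
        assert com.t is not None and com.n_epochs == 5

    def test_lower_triangle_is_null_marker(self, coupled_epoch_factory):
        epo = coupled_epoch_factory(seed=0)
        com = pac.comodulogram(epo, n_shuffles=50, seed=0)
        centers = np.array(com.env_centers)
        lower = centers[:, None] <= centers[None, :]   # env slower or equal
        assert np.isnan(com.z[lower]).all()
        assert np.isfinite(com.z[~lower]).all()

    def test_notch_band_cells_flagged(self, coupled_epoch_factory):
        epo = coupled_epoch_factory(seed=0)
        com = pac.comodulogram(epo, n_shuffles=50, seed=0)
        i48 = com.env_centers.index(48.0)
        i53 = com.env_centers.index(53.0)
        j3 = com.sig_centers.index(3.0)
        assert com.notch_flags[i48, j3] and com.notch_flags[i53, j3]
        assert not com.notch_flags[com.env_centers.index(78.0), j3]

    def test_short_epoch_rejected(self):
        epo = make_epoch(np.random.default_rng(0).standard_normal(2000))
        with pytest.raises(ValueError, match="too short"):
            pac.comodulogram(epo)


class TestThetaGammaScore:
    def test_score_increases_with_coupling_depth(self, coupled_epoch_factory):
        wins = 0
        for seed in range(6):
            hi = pac.theta_gamma_score(coupled_epoch_factory(depth=0.8, seed=seed),
                                       seed=seed, return_raw=True)[1]
            lo = pac.theta_gamma_score(coupled_epoch_factory(depth=0.2, seed=seed + 500),
                                       seed=seed, return_raw=True)[1]
            wins += hi > lo
        assert wins == 6

    def test_uncoupled_pooled_score_near_zero(self, coupled_epoch_factory):
        zs = [pac.theta_gamma_score(coupled_epoch_factory(depth=0.0, seed=s), seed=s)
              for s in range(10)]
        assert abs(np.mean(zs)) < 0.5

    def test_deterministic_given_seed(self, coupled_epoch_factory):
        epo = coupled_epoch_factory(depth=0.5, seed=9)
        assert pac.theta_gamma_score(epo, seed=5) == pac.theta_gamma_score(epo, seed=5)


class TestCouplingTimecourse:
    def test_identical_epochs_give_identical_scores(self, coupled_epoch_factory):
        epo = coupled_epoch_factory(depth=0.5, seed=4)
        during = [make_epoch(epo.samples, label="during", index=k) for k in range(4)]
        baseline = [make_epoch(epo.samples, label="pre", index=k) for k in range(2)]
        tc = pac.hfs_coupling_timecourse(during, baseline, n_shuffles=50, seed=0)
        assert len(set(np.round(tc.scores_raw, 12))) == 1
        assert tc.missing_indices == list(range(4, 10))

    def test_relative_scores_against_baseline_mean(self, coupled_epoch_factory):
        during = [coupled_epoch_factory(depth=0.6, seed=s) for s in range(3)]
        for k, e in enumerate(during):
            e.sub_window_index = k
        baseline = [coupled_epoch_factory(depth=0.6, seed=100 + s) for s in range(3)]
        tc = pac.hfs_coupling_timecourse(during, baseline, n_shuffles=50, seed=1)
        np.testing.assert_allclose(tc.scores_rel_baseline,
                                   np.array(tc.scores_z) / tc.baseline_mean_z)

    def test_single_epoch_rejected(self, coupled_epoch_factory):
        with pytest.raises(ValueError):
            pac.hfs_coupling_timecourse([coupled_epoch_factory()], [], seed=0)


class TestOracleEquivalence:
    def test_morlet_envelope_matches_bandpass_hilbert(self):
        """Morlet and band-pass+Hilbert envelopes agree on narrowband signals."""
        from scipy.signal import butter, hilbert, sosfiltfilt

        for seed in range(5):
            cfg = synth.SynthConfig(duration_s=4.1, coupling_depth=0.6, seed=seed)
            x = synth.gen_coupled_eeg(cfg).samples
            env_m = np.abs(pac.morlet_filter(x, FS, WaveletSpec(78.0)))
            half_bw = 0.5 * 2.355 * 78.0 / 7.0
            sos = butter(1, [78.0 - half_bw, 78.0 + half_bw], btype="bandpass",
                         fs=FS, output="sos")
            env_h = np.abs(hilbert(sosfiltfilt(sos, x)))
            r = np.corrcoef(env_m[1000:-1000], env_h[1000:-1000])[0, 1]
            assert r > 0.95
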