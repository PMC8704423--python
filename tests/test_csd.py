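"""Current source density: analytic oracles, sink finding, MUA envelope."""

import numpy as np
import pytest

from ffrkit.csd import (CSDProfile, compute_csd, extract_mua,
                        find_earliest_sink, stimulus_csd_correlation)

FS = 2000.0
DEPTHS = np.arange(16) * 150.0


def _profile_from_spatial(spatial, n_t=200, smoothing=0.0):
    lfp = np.outer(spatial, np.ones(n_t))
    return compute_csd(lfp, DEPTHS, FS, smoothing_sd_um=smoothing,
                       t0_ms=-25.0)


class TestComputeCsd:
    def test_linear_depth_profile_gives_zero(self):
        prof = _profile_from_spatial(0.01 * DEPTHS + 3.0)
        np.testing.assert_allclose(prof.csd, 0.0, atol=1e-12)

    def test_quadratic_profile_matches_analytic_second_derivative(self):
        a = 2.5e-5
        prof = _profile_from_spatial(a * DEPTHS ** 2)
        np.testing.assert_allclose(prof.csd, -2.0 * a, rtol=1e-2)

    def test_reference_free_exact(self, rng):
        lfp = rng.standard_normal((len(DEPTHS), 100))
        p1 = compute_csd(lfp, DEPTHS, FS, smoothing_sd_um=250.0, t0_ms=-25.0)
        p2 = compute_csd(lfp + 42.0, DEPTHS, FS, smoothing_sd_um=250.0,
                         t0_ms=-25.0)
        np.testing.assert_allclose(p1.csd, p2.csd, atol=1e-9)

    def test_spacing_doubling_quarters_csd(self, rng):
        spatial = rng.standard_normal(len(DEPTHS))
        p1 = _profile_from_spatial(spatial)
        p2 = compute_csd(np.outer(spatial, np.ones(200)), 2.0 * DEPTHS, FS,
                         smoothing_sd_um=0.0, t0_ms=-25.0)
        np.testing.assert_allclose(p2.csd, p1.csd / 4.0, atol=1e-12)

    def test_interior_depths_only(self):
        prof = _profile_from_spatial(np.ones(len(DEPTHS)))
        assert prof.csd.shape[0] == len(DEPTHS) - 2
        np.testing.assert_array_equal(prof.depths_um, DEPTHS[1:-1])

    def test_nonuniform_spacing_rejected(self, rng):
        bad = DEPTHS.copy()
        bad[3] += 40.0
        with pytest.raises(ValueError, match="spaced"):
            compute_csd(rng.standard_normal((16, 50)), bad, FS)

    def test_vaknin_padding_keeps_all_depths(self, rng):
        lfp = rng.standard_normal((16, 50))
        prof = compute_csd(lfp, DEPTHS, FS, vaknin=True)
        assert prof.csd.shape[0] == 16


class TestFindEarliestSink:
    def _pulse_profile(self, depth_idx, lat_ms, amp=10.0, rng=None):
        n_t = 300
        t = -25.0 + 1e3 * np.arange(n_t) / FS
        lfp = (0.05 * (rng.standard_normal((16, n_t)) if rng is not None
                       else np.zeros((16, n_t))))
        u = np.clip(t - lat_ms, 0.0, None)  # true onset at lat_ms
        pulse = (u / 2.0) * np.exp(1.0 - u / 2.0)
        x = (DEPTHS - DEPTHS[depth_idx]) / 250.0
        hat = (1 - x ** 2) * np.exp(-0.5 * x ** 2)
        lfp += np.outer(-amp * hat, pulse)  # LFP dips at the target depth
        return compute_csd(lfp, DEPTHS, FS, smoothing_sd_um=250.0,
                           t0_ms=-25.0)

    def test_recovers_injected_sink_depth_and_latency(self, rng):
        prof = self._pulse_profile(7, 12.0, rng=rng)
        sink = find_earliest_sink(prof)
        assert sink is not None
        d_idx, lat = sink
        assert abs(prof.depths_um[d_idx] - DEPTHS[7]) <= 150.0
        assert lat == pytest.approx(12.0, abs=1.5)

    def test_all_positive_csd_reports_no_sink(self, rng):
        n_t = 300
        lfp = 0.01 * rng.standard_normal((16, n_t))
        lfp[:, 60:] -= 5.0  # depth-uniform negative step -> zero CSD
        prof = compute_csd(lfp, DEPTHS, FS, smoothing_sd_um=250.0,
                           t0_ms=-25.0)
        assert find_earliest_sink(prof, k_sd=50.0) is None

    def test_earliest_of_two_sinks_wins(self):
        prof_a = self._pulse_profile(4, 10.0)
        prof_b = self._pulse_profile(10, 20.0)
        both = CSDProfile(prof_a.csd + prof_b.csd, prof_a.depths_um, FS,
                          -25.0, 150.0, 250.0)
        sink = find_earliest_sink(both)
        assert abs(both.depths_um[sink[0]] - DEPTHS[4]) <= 150.0
        assert sink[1] == pytest.approx(10.0, abs=1.5)

    def test_negative_window_start_rejected(self, rng):
        prof = self._pulse_profile(7, 12.0, rng=rng)
        with pytest.raises(ValueError, match="onset"):
            find_earliest_sink(prof, search_window_ms=(-10.0, 50.0))

    def test_forward_model_sink_near_granular_depth(self, rec_noiseless):
        """End-to-end: the simulator's laminar FFR produces its earliest
        sink within one electrode of the configured granular depth."""
        lam = [i for i, c in enumerate(rec_noiseless.channels)
               if c.kind == "laminar"]
        depths = np.array([rec_noiseless.channels[i].depth_um for i in lam])
        sel = rec_noiseless.tone_id == "T3"
        lfp = rec_noiseless.data[sel][:, lam, :].mean(axis=0)
        prof = compute_csd(lfp, depths, rec_noiseless.fs,
                           t0_ms=rec_noiseless.t0_ms)
        sink = find_earliest_sink(prof)
        assert sink is not None
        assert abs(prof.depths_um[sink[0]] - 1050.0) <= 150.0


class TestStimulusCsdCorrelation:
    def test_delayed_feature_recovered(self, rng):
        feat = rng.standard_normal(400)
        shift = int(0.013 * FS)
        rows = np.array([np.roll(feat, shift) for _ in range(5)])
        prof = CSDProfile(rows, DEPTHS[:5], FS, -25.0, 150.0, 0.0)
        r, lags = stimulus_csd_correlation(prof, feat)
        np.testing.assert_allclose(lags, 13.0, atol=0.51)
        assert np.all(r > 0.9)

    def test_polarity_flip_preserves_lag_flips_sign(self, rng):
        feat = rng.standard_normal(400)
        shift = int(0.013 * FS)
        rows = np.array([np.roll(feat, shift), -np.roll(feat, shift)])
        prof = CSDProfile(rows, DEPTHS[:2], FS, -25.0, 150.0, 0.0)
        r, lags = stimulus_csd_correlation(prof, feat)
        assert r[0] > 0.9 and r[1] < -0.9
        assert lags[0] == pytest.approx(lags[1], abs=1e3 / FS)

    def test_length_mismatch_rejected(self, rng):
        prof = CSDProfile(rng.standard_normal((3, 100)), DEPTHS[:3], FS,
                          -25.0, 150.0, 0.0)
        with pytest.raises(ValueError, match="resampled"):
            stimulus_csd_correlation(prof, rng.standard_normal(90))


class TestExtractMua:
    def test_am_carrier_envelope_recovered(self):
        fs = 12000.0
        t = np.arange(int(0.3 * fs)) / fs
        modulator = 1.0 + 0.9 * np.sin(2 * np.pi * 97.0 * t)
        x = modulator * np.sin(2 * np.pi * 1500.0 * t)
        env = extract_mua(x, fs)
        r = np.corrcoef(env[500:-500], modulator[500:-500])[0, 1]
        assert r > 0.9

    def test_dc_input_gives_zero_envelope(self):
        env = extract_mua(np.full(6000, 5.0), 12000.0)
        assert np.max(np.abs(env[500:-500])) < 1e-6

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            extract_mua(np.zeros(1000), 4000.0)

    def test_f0_locked_bursts_follow_stimulus(self, stimuli4):
        from ffrkit.forward import f0_locked_bursts
        fs = 12000.0
        stim = stimuli4[0]  # T1
        x = f0_locked_bursts(stim, fs, latency_ms=13.0)
        env = extract_mua(x, fs)
        # envelope periodicity should match the stimulus F0 (129 Hz)
        from ffrkit.pitch import track_pitch
        tr = track_pitch(env[int(0.05 * fs):], fs)
        assert np.median(tr.voiced_f0()) == pytest.approx(129.0, abs=3.0)
        # and correlate > 0.5 with the F0-rate periodicity of the stimulus
        n = len(env)
        idx = np.minimum((np.arange(n) * stim.fs / fs).astype(int),
                         len(stim.waveform) - 1)
        stim_env = np.abs(stim.waveform[idx])
        shift = int(0.013 * fs)
        r = np.corrcoef(env[shift:], stim_env[:-shift])[0, 1]
        assert abs(r) > 0.3
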