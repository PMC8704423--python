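"""Line-noise regression, zero-phase filtering, rejection, polarity averaging."""

import numpy as np
import pytest
from scipy import signal

from ffrkit.forward import ForwardModelConfig, simulate_ffr_dataset
from ffrkit.preprocess import (average_polarities, filter_epochs,
                               reject_artifacts, remove_line_noise)
from ffrkit.recording import ChannelMeta, EpochedRecording

FS = 1000.0


def _rec_from(trials: np.ndarray, polarity=None, tone=None):
    trials = np.asarray(trials, dtype=float)[:, None, :]
    n = trials.shape[0]
    return EpochedRecording(
        trials, FS, -25.0, [ChannelMeta("ch", "scalp")],
        np.array(polarity if polarity is not None
                 else ["condensation"] * n),
        np.array(tone if tone is not None else ["T1"] * n))


def _band_power(x, f, fs=FS):
    freqs, psd = signal.periodogram(x, fs=fs)
    return psd[np.argmin(np.abs(freqs - f))]


class TestRemoveLineNoise:
    def test_pure_60hz_attenuated_20db(self, rng):
        t = np.arange(600) / FS
        x = np.sin(2 * np.pi * 60.0 * t + 0.7)
        rec = _rec_from([x])
        out = remove_line_noise(rec, 60.0, 1)
        before = _band_power(x, 60.0)
        after = _band_power(out.data[0, 0], 60.0)
        assert 10 * np.log10(before / max(after, 1e-300)) >= 20.0

    def test_non_line_content_preserved(self, rng):
        x = rng.standard_normal(600)
        # remove any energy at the line regressor frequencies first
        rec0 = remove_line_noise(_rec_from([x]), 60.0, 3)
        clean = rec0.data[0, 0]
        out = remove_line_noise(_rec_from([clean]), 60.0, 3)
        np.testing.assert_allclose(out.data[0, 0], clean, atol=1e-10)

    def test_all_three_harmonics_attenuated(self):
        t = np.arange(1000) / FS
        x = sum(np.sin(2 * np.pi * f * t + i) for i, f in
                enumerate((60.0, 120.0, 180.0)))
        out = remove_line_noise(_rec_from([x]), 60.0, 3)
        for f in (60.0, 120.0, 180.0):
            assert _band_power(out.data[0, 0], f) < 1e-3 * _band_power(x, f)

    def test_harmonic_above_nyquist_skipped(self, caplog):
        x = np.ones((1, 100))
        with caplog.at_level("WARNING"):
            remove_line_noise(_rec_from(x), 400.0, 3)
        assert "Nyquist" in caplog.text


class TestFilterEpochs:
    def test_zero_phase_impulse(self):
        x = np.zeros(500)
        x[250] = 1.0
        out = filter_epochs(_rec_from([x]), (80.0, 400.0))
        assert abs(int(np.argmax(np.abs(out.data[0, 0]))) - 250) <= 1

    @pytest.mark.parametrize("freq,limit,kind", [
        (40.0, 0.10, "stop"), (200.0, 0.05, "pass")])
    def test_band_response(self, freq, limit, kind):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * freq * t)
        out = filter_epochs(_rec_from([x]), (80.0, 400.0))
        ratio = np.sqrt(np.mean(out.data[0, 0, 500:1500] ** 2) /
                        np.mean(x[500:1500] ** 2))
        if kind == "stop":
            assert ratio < limit
        else:
            assert ratio == pytest.approx(1.0, abs=limit)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            filter_epochs(_rec_from([np.zeros(100)]), (300.0, 80.0))


class TestRejectArtifacts:
    def test_over_threshold_trial_dropped(self):
        quiet = np.zeros(100)
        loud = np.zeros(100)
        loud[10] = 80.0
        rec = _rec_from([quiet, loud], tone=["T1", "T1"])
        kept, counts = reject_artifacts(rec, 75.0)
        assert kept.n_trials == 1 and counts["T1"] == 1

    def test_no_rejections_below_threshold(self, rng):
        rec = _rec_from(10.0 * rng.standard_normal((5, 100)))
        kept, counts = reject_artifacts(rec, 75.0)
        assert kept.n_trials == 5 and counts["T1"] == 0

    def test_matches_brute_force_oracle(self, rng):
        trials = 25.0 * rng.standard_normal((40, 200))
        rec = _rec_from(trials)
        kept, _ = reject_artifacts(rec, 75.0)
        oracle = [i for i in range(40) if np.abs(trials[i]).max() <= 75.0]
        assert np.array_equal(kept.data[:, 0, :], trials[oracle])

    def test_all_rejected_is_an_error(self):
        rec = _rec_from([np.full(50, 100.0)])
        with pytest.raises(ValueError, match="75"):
            reject_artifacts(rec, 75.0)


class TestAveragePolarities:
    def test_identical_polarities_equal_plain_mean(self, rng):
        trials = rng.standard_normal((4, 120))
        rec = _rec_from(trials, polarity=["condensation", "condensation",
                                          "rarefaction", "rarefaction"])
        out = average_polarities(rec)["T1"]
        np.testing.assert_allclose(out.samples, trials.mean(axis=0))

    def test_sign_flipping_artifact_cancels(self, stimuli4):
        cfg = ForwardModelConfig(n_trials=4, noise_rms_uv=0.0,
                                 line_amps_uv=(0, 0, 0),
                                 artifact_gain_uv=5.0)
        rec = simulate_ffr_dataset(cfg, stimuli4[:1])
        ref = simulate_ffr_dataset(
            ForwardModelConfig(n_trials=4, noise_rms_uv=0.0,
                               line_amps_uv=(0, 0, 0), artifact_gain_uv=0.0),
            stimuli4[:1])
        avg = average_polarities(rec)["T1"].samples
        clean = average_polarities(ref)["T1"].samples
        single = rec.data[rec.polarity == "condensation"][:, 0].mean(axis=0)
        artifact_in_single = single - clean
        artifact_in_avg = avg - clean
        assert np.mean(artifact_in_avg ** 2) <= \
            0.01 * np.mean(artifact_in_single ** 2)

    def test_unbalanced_counts_weight_polarities_equally(self):
        a = np.ones((1, 50))
        rec = _rec_from(np.vstack([a, a, 3 * a]),
                        polarity=["condensation", "condensation",
                                  "rarefaction"])
        out = average_polarities(rec)["T1"]
        np.testing.assert_allclose(out.samples, 2.0)  # (1 + 3)/2, not 5/3

    def test_missing_polarity_falls_back_with_warning(self, caplog):
        rec = _rec_from(np.ones((2, 50)))
        with caplog.at_level("WARNING"):
            out = average_polarities(rec)["T1"]
        assert "polarity" in caplog.text
        np.testing.assert_allclose(out.samples, 1.0)
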