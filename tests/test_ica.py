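"""ICA source separation: blind recovery, PVAF identities, attribution."""

import numpy as np
import pytest

from ffrkit.forward import (ForwardModelConfig, simulate_ffr_dataset,
                            source_response)
from ffrkit.ica import (classify_components, component_latency,
                        component_power_coherence, fit_ica, pvaf)
from ffrkit.preprocess import average_polarities
from ffrkit.pipeline import _stimulus_waveform_on_grid
from ffrkit.stimuli import TONE_IDS


def _two_source_mixture(rng, n_ch=6, n_t=2000):
    """Two independent non-Gaussian sources mixed into n_ch channels."""
    t = np.arange(n_t)
    s1 = np.sign(np.sin(2 * np.pi * 0.013 * t))  # sub-Gaussian square wave
    s2 = rng.laplace(size=n_t)  # super-Gaussian
    S = np.vstack([s1, s2])
    A = rng.uniform(-1.0, 1.0, size=(n_ch, 2))
    return A @ S, S


def _averaged_ffrs(rec):
    tones = list(np.unique(rec.tone_id))
    return np.array([
        np.concatenate([average_polarities(rec, i)[t].samples for t in tones])
        for i in range(len(rec.channels))])


class TestFitIca:
    def test_blind_recovery_of_two_sources(self, rng):
        x, true = _two_source_mixture(rng)
        d = fit_ica(x, fs=1000.0, var_threshold=0.999, seed=0)
        for s in true:
            best = max(abs(np.corrcoef(s, d.activations[c])[0, 1])
                       for c in range(d.n_components))
            assert best > 0.95

    def test_rank_one_mixture_single_component(self, rng):
        s = rng.laplace(size=1500)
        x = np.outer(rng.uniform(0.5, 2.0, 5), s)
        d = fit_ica(x, fs=1000.0, var_threshold=0.96, seed=0)
        for e in range(5):
            assert pvaf(d, 0, e) == pytest.approx(100.0, abs=1e-6)

    def test_deterministic_under_seed(self, rng):
        x, _ = _two_source_mixture(rng)
        d1 = fit_ica(x, fs=1000.0, seed=3)
        d2 = fit_ica(x, fs=1000.0, seed=3)
        np.testing.assert_array_equal(d1.unmixing, d2.unmixing)
        np.testing.assert_array_equal(d1.activations, d2.activations)

    def test_back_projection_identity(self, rng):
        x, _ = _two_source_mixture(rng)
        d = fit_ica(x, fs=1000.0, var_threshold=0.999, seed=0)
        recon = d.mixing @ d.activations
        reduced = d.data  # centred input
        rel = np.sqrt(np.mean((recon - reduced) ** 2) /
                      np.mean(reduced ** 2))
        assert rel < 1e-6

    def test_components_ordered_by_pvaf(self, rng):
        x, _ = _two_source_mixture(rng)
        d = fit_ica(x, fs=1000.0, var_threshold=0.999, seed=0)
        totals = [d.total_pvaf(c) for c in range(d.n_components)]
        assert np.all(np.diff(totals) <= 1e-9)

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            fit_ica(rng.standard_normal((1, 100)), fs=1000.0)


class TestPvaf:
    def test_all_components_jointly_explain_everything(self, rng):
        x, _ = _two_source_mixture(rng)
        d = fit_ica(x, fs=1000.0, var_threshold=0.999, seed=0)
        recon = d.mixing @ d.activations
        for e in range(x.shape[0]):
            joint = 100.0 * (1.0 - np.var(d.data[e] - recon[e]) /
                             np.var(d.data[e]))
            assert joint == pytest.approx(100.0, abs=1e-6)

    def test_orthogonal_component_scores_zero(self, rng):
        # channel 2 carries none of source 1
        s1 = np.sign(np.sin(0.07 * np.arange(2000)))
        s2 = rng.laplace(size=2000)
        x = np.vstack([s1 + 0.3 * s2, 0.5 * s1 - s2, 0.8 * s2])
        x[2] = s2  # pure source-2 channel
        d = fit_ica(x, fs=1000.0, var_threshold=0.999, seed=0)
        which = np.argmax([abs(np.corrcoef(s1, d.activations[c])[0, 1])
                           for c in range(d.n_components)])
        assert pvaf(d, int(which), 2) == pytest.approx(0.0, abs=5.0)

    def test_zero_variance_electrode_rejected(self, rng):
        x, _ = _two_source_mixture(rng)
        d = fit_ica(x, fs=1000.0, seed=0)
        d.data[1] = 0.0
        with pytest.raises(ValueError, match="variance"):
            pvaf(d, 0, 1)


class TestComponentCharacterization:
    def test_shifted_stimulus_latency_recovered(self, rng):
        x = rng.standard_normal(2000)
        shift = int(0.0034 * 2000.0)  # 3.4 ms at 2 kHz... in samples
        act = np.concatenate([np.zeros(shift), x[:-shift]])
        lag, r, ok = component_latency(act, x, fs=2000.0)
        assert ok and r > 0.9
        assert lag == pytest.approx(shift / 2.0, abs=0.5)

    def test_white_noise_activation_flagged(self, rng, caplog):
        with caplog.at_level("WARNING"):
            lag, r, ok = component_latency(rng.standard_normal(2000),
                                           rng.standard_normal(2000),
                                           fs=2000.0)
        assert not ok and "unreliable" in caplog.text

    def test_self_coherence_equals_psd(self, rng):
        x = rng.standard_normal(4096)
        f, coh = component_power_coherence(x, x, fs=2000.0)
        from scipy.signal import welch
        _, psd = welch(x, fs=2000.0, window="hamming", nperseg=1024,
                       noverlap=512)
        np.testing.assert_allclose(coh, psd, rtol=1e-9)

    def test_cortical_component_coherence_declines_faster(self, stimuli4):
        cfg = ForwardModelConfig()
        fs = cfg.fs
        sub = source_response(stimuli4[0], cfg.subcortical, fs, -25.0, 275.0)
        cort = source_response(stimuli4[0], cfg.cortical, fs, -25.0, 275.0)
        stim = stimuli4[0]
        n = len(sub)
        idx = np.minimum((np.arange(n) * stim.fs / fs).astype(int),
                         len(stim.waveform) - 1)
        ref = stim.waveform[idx]
        f, c_sub = component_power_coherence(sub, ref, fs=fs, nperseg=512)
        _, c_cort = component_power_coherence(cort, ref, fs=fs, nperseg=512)
        f0 = np.argmin(np.abs(f - 129.0))
        h2 = np.argmin(np.abs(f - 258.0))
        ratio_sub = c_sub[h2] / c_sub[f0]
        ratio_cort = c_cort[h2] / c_cort[f0]
        assert ratio_cort < ratio_sub


class TestClassifyComponents:
    def _decomp_and_latencies(self, stimuli, seed):
        cfg = ForwardModelConfig(n_trials=24, seed=seed)
        rec = simulate_ffr_dataset(cfg, stimuli)
        x = _averaged_ffrs(rec)
        d = fit_ica(x, rec.fs, seed=0,
                    channel_labels=[c.label for c in rec.channels])
        tones = list(np.unique(rec.tone_id))
        feat = np.concatenate([
            _stimulus_waveform_on_grid(stimuli[TONE_IDS.index(t)], rec)
            for t in tones])
        lats = [component_latency(d.activations[c], feat, rec.fs)[0]
                for c in range(d.n_components)]
        intracranial = np.array([c.kind != "scalp" for c in rec.channels])
        return d, lats, intracranial

    def test_ground_truth_mixture_recovered(self, stimuli4):
        """Components with PVAF > 10% carry the correct source label."""
        d, lats, mask = self._decomp_and_latencies(stimuli4, seed=21)
        labels = classify_components(d, lats, mask)
        strong = [(c, labels[c]) for c in range(d.n_components)
                  if d.total_pvaf(c) > 10.0]
        assert len(strong) >= 2
        assert any(lab == "putative_cortical" for _, lab in strong)
        assert any(lab == "putative_subcortical" for _, lab in strong)

    def test_low_pvaf_components_not_labeled(self, stimuli4):
        d, lats, mask = self._decomp_and_latencies(stimuli4, seed=22)
        labels = classify_components(d, lats, mask)
        for c in range(d.n_components):
            if d.total_pvaf(c) < 10.0:
                assert labels[c] == "unclassified"

    def test_labels_invariant_to_sign_flip_and_reorder(self, stimuli4):
        d, lats, mask = self._decomp_and_latencies(stimuli4, seed=23)
        base = classify_components(d, lats, mask)
        # flip the sign of every component
        d.mixing = -d.mixing
        d.activations = -d.activations
        flipped = classify_components(d, lats, mask)
        assert base == flipped
        # reorder components
        order = np.arange(d.n_components)[::-1]
        d.mixing = d.mixing[:, order]
        d.activations = d.activations[order]
        reordered = classify_components(d, [lats[i] for i in order], mask)
        assert reordered == [flipped[i] for i in order]

    def test_single_uniform_source_is_subcortical(self, rng):
        s = rng.laplace(size=1500)
        x = np.outer(np.full(6, 0.8), s) + 1e-4 * rng.standard_normal((6, 1500))
        d = fit_ica(x, fs=1000.0, var_threshold=0.96, seed=0)
        labels = classify_components(d, [3.0] * d.n_components,
                                     np.ones(6, dtype=bool))
        assert labels[0] == "putative_subcortical"
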