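"""HMM tone decoding: pseudo-trials, separability, confusion contracts."""

import numpy as np
import pytest

from ffrkit.decode import (ConfusionMatrix, classify, decode_confusion,
                           fit_hmm_decoder, make_averaged_trials,
                           track_features)
from ffrkit.stimuli import TONE_IDS, make_f0_contour


def _contour_features(tone, n_windows=22, noise=0.0, rng=None):
    """(f0, df0) sequences straight from the ground-truth contours."""
    c = make_f0_contour(tone, n_windows, 100.0)
    if noise and rng is not None:
        c = c + noise * rng.standard_normal(n_windows)
    return np.column_stack([c, np.gradient(c)])


def _feature_set(n_per_tone, noise=0.0, rng=None):
    feats, labels = [], []
    for tone in TONE_IDS:
        for _ in range(n_per_tone):
            feats.append(_contour_features(tone, noise=noise, rng=rng))
            labels.append(tone)
    return feats, np.array(labels)


class TestMakeAveragedTrials:
    def test_k1_returns_single_trials(self, rec_default):
        waves, labels = make_averaged_trials(rec_default, 1, seed=0)
        assert len(waves) == rec_default.n_trials
        # every pseudo-trial is literally one of the raw trials
        raw = rec_default.data[:, 0, :]
        assert np.isin(waves[:5], raw).all()

    def test_k_equals_n_gives_grand_mean(self, rec_default):
        sel = rec_default.tone_id == "T1"
        n = int(sel.sum())
        waves, labels = make_averaged_trials(
            rec_default.pick_trials(sel), n, seed=0)
        assert len(waves) == 1
        np.testing.assert_allclose(
            waves[0], rec_default.data[sel, 0, :].mean(axis=0))

    def test_insufficient_trials_error_names_shortfall(self, rec_default):
        with pytest.raises(ValueError, match="pseudo-trials"):
            make_averaged_trials(rec_default, 10_000, seed=0)

    def test_snr_grows_as_sqrt_k(self, rec_default, rec_noiseless):
        """Pseudo-trial RMS-SNR scales ~ sqrt(k): slope ~0.5 on log-log."""
        clean = rec_noiseless.data[rec_noiseless.tone_id == "T1"][0, 0]
        ks = [1, 4, 16]
        snrs = []
        sel = rec_default.pick_trials(rec_default.tone_id == "T1")
        for k in ks:
            waves, _ = make_averaged_trials(sel, k, seed=1)
            resid = waves - clean[None, :]
            snrs.append(np.sqrt(np.mean(clean ** 2) /
                                np.mean(resid ** 2)))
        slope = np.polyfit(np.log(ks), np.log(snrs), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.15)


class TestHmmDecoder:
    def test_noiseless_contours_fully_separable(self):
        feats, labels = _feature_set(4)
        cm = decode_confusion(feats, labels, cv_scheme="loo")
        assert cm.accuracy == 1.0
        np.testing.assert_allclose(cm.matrix, np.eye(4))

    def test_rows_sum_to_one(self, rng):
        feats, labels = _feature_set(4, noise=8.0, rng=rng)
        cm = decode_confusion(feats, labels, cv_scheme=("kfold", 4))
        np.testing.assert_allclose(cm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_shuffled_labels_decode_at_chance(self, rng):
        feats, labels = _feature_set(8, noise=1.0, rng=rng)
        shuffled = rng.permutation(labels)
        cm = decode_confusion(feats, shuffled, cv_scheme=("kfold", 4), seed=0)
        # binomial 99% band around chance for 128 pseudo-trials
        assert abs(cm.accuracy - 0.25) < 0.12

    def test_degraded_falling_tone_decodes_worse_than_rising(self, rng):
        """When falling-tone (T4) tracks intermittently collapse toward the
        level tone's contour — the loss of distinctiveness that weak
        high-frequency phase-locking produces — its diagonal entry drops
        below the intact rising tone's (T2)."""
        t1 = make_f0_contour("T1", 22, 100.0)
        feats, labels = [], []
        for tone in TONE_IDS:
            for j in range(12):
                c = make_f0_contour(tone, 22, 100.0)
                if tone == "T4":
                    # every third track loses the contour entirely
                    lam = 1.0 if j % 3 == 0 else rng.uniform(0.3, 0.9)
                    c = (1 - lam) * c + lam * t1
                c = c + 2.0 * rng.standard_normal(22)
                feats.append(np.column_stack([c, np.gradient(c)]))
                labels.append(tone)
        cm = decode_confusion(feats, np.array(labels),
                              cv_scheme=("kfold", 4), seed=1)
        d = dict(zip(cm.labels, np.diag(cm.matrix)))
        assert d["T2"] > d["T4"]

    def test_too_few_training_tracks_rejected(self):
        feats, labels = _feature_set(1)
        with pytest.raises(ValueError, match="training tracks"):
            fit_hmm_decoder(feats, labels)

    def test_tie_goes_to_lowest_tone(self, caplog):
        feats, labels = _feature_set(3)
        models = fit_hmm_decoder(feats, labels)
        # identical models for every tone force exact ties
        same = {t: models["T1"] for t in TONE_IDS}
        with caplog.at_level("WARNING"):
            pred = classify(same, feats[:2])
        assert list(pred) == ["T1", "T1"]
        assert "ties" in caplog.text

    def test_confusion_rows_must_be_stochastic(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ConfusionMatrix(np.full((4, 4), 0.5), list(TONE_IDS),
                            np.ones((4, 4)))


def test_accuracy_monotone_in_averaging_size(rec_default):
    """More trials per pseudo-trial never hurts decoding (3 k-levels)."""
    accs = []
    for k in (1, 4, 16):
        waves, labels = make_averaged_trials(rec_default, k, seed=2,
                                             channel="Cz")
        feats = [track_features(w, rec_default.fs, rec_default.t0_ms)
                 for w in waves]
        cm = decode_confusion(feats, labels, cv_scheme=("kfold", 4), seed=2,
                              averaging_size=k)
        accs.append(cm.accuracy)
    assert accs[0] <= accs[1] + 0.05 and accs[1] <= accs[2] + 0.05
    assert accs[2] > 0.6
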