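"""HMM decoding of Mandarin tone categories from FFR pitch tracks.

One left-to-right Gaussian-emission HMM is trained per tone on (F0, dF0)
features extracted from pitch tracks of (pseudo-)trial FFR waveforms; a test
track is assigned to the tone whose model gives the highest log-likelihood.
Pseudo-trials are disjoint random groups of k single trials averaged
together — the "averaging size" that trades trial count against SNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .pitch import track_pitch
from .recording import EpochedRecording

__all__ = ["ConfusionMatrix", "make_averaged_trials", "track_features",
           "fit_hmm_decoder", "classify", "decode_confusion"]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Row-stochastic decoding confusion matrix over tone categories."""

    matrix: np.ndarray  # rows true tone, cols decoded tone
    labels: list[str]
    counts: np.ndarray  # raw n per cell
    averaging_size: int = 1

    def __post_init__(self):
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion matrix rows must sum to 1")

    @property
    def accuracy(self) -> float:
        return float(np.mean(np.diag(self.matrix)))

    def off_diagonal(self) -> np.ndarray:
        """The off-diagonal cells, row-major (the diagonal removed)."""
        mask = ~np.eye(len(self.labels), dtype=bool)
        return self.matrix[mask]


def make_averaged_trials(rec: EpochedRecording, k: int, seed: int = 0,
                         channel: int | str = 0,
                         min_pseudo: int = 1):
    """Average disjoint random groups of k trials into pseudo-trials.

    Returns ``(waveforms, labels)``: a (n_pseudo, n_samples) array of
    polarity-pooled pseudo-trial waveforms and their tone labels.  Grouping
    is seeded; leftover trials (fewer than k) are discarded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(channel, str):
        channel = rec.channel_index(channel)
    rng = np.random.default_rng(seed)
    waves, labels = [], []
    for tone in np.unique(rec.tone_id):
        idx = np.nonzero(rec.tone_id == tone)[0]
        n_pseudo = len(idx) // k
        if n_pseudo < min_pseudo:
            raise ValueError(
                f"tone {tone}: {len(idx)} trials give {n_pseudo} pseudo-trials "
                f"of size {k}, fewer than the required {min_pseudo}")
        perm = rng.permutation(idx)[:n_pseudo * k].reshape(n_pseudo, k)
        for group in perm:
            waves.append(rec.data[group, channel].mean(axis=0))
            labels.append(str(tone))
    return np.array(waves), np.array(labels)


def track_features(waveform: np.ndarray, fs: float, t0_ms: float = 0.0,
                   response_window=(0.0, 250.0), **track_kw) -> np.ndarray:
    """(F0, dF0) feature sequence for the HMM, from the response window."""
    t = t0_ms + 1e3 * np.arange(len(waveform)) / fs
    seg = waveform[(t >= response_window[0]) & (t < response_window[1])]
    track_kw.setdefault("parabolic", True)
    tr = track_pitch(seg, fs, **track_kw)
    f0 = np.where(np.isfinite(tr.f0_hz), tr.f0_hz, np.nanmean(tr.f0_hz))
    df0 = np.gradient(f0)
    return np.column_stack([f0, df0])


def _left_to_right_hmm(n_states: int, seed: int) -> GaussianHMM:
    # transitions stay fixed at the left-to-right topology (params excludes
    # "st"): EM on short tracks can otherwise starve the final state
    model = GaussianHMM(n_components=n_states, covariance_type="diag",
                        n_iter=20, min_covar=1.0, random_state=seed,
                        init_params="mc", params="mc")
    start = np.zeros(n_states)
    start[0] = 1.0
    trans = np.zeros((n_states, n_states))
    for i in range(n_states):
        trans[i, i] = 0.5
        if i + 1 < n_states:
            trans[i, i + 1] = 0.5
        else:
            trans[i, i] = 1.0
    model.startprob_ = start
    model.transmat_ = trans
    return model


def fit_hmm_decoder(features: list[np.ndarray], labels, n_states: int = 4,
                    seed: int = 0) -> dict[str, GaussianHMM]:
    """Fit one left-to-right HMM per tone on its training feature sequences."""
    labels = np.asarray(labels)
    models: dict[str, GaussianHMM] = {}
    for tone in np.unique(labels):
        seqs = [features[i] for i in np.nonzero(labels == tone)[0]]
        if len(seqs) < 2:
            raise ValueError(f"tone {tone}: need >= 2 training tracks")
        X = np.concatenate(seqs)
        if np.any(X.std(axis=0) < 1e-9):
            logger.warning("tone %s: near-constant feature; variance floor "
                           "will apply", tone)
        model = _left_to_right_hmm(n_states, seed)
        model.fit(X, lengths=[len(s) for s in seqs])
        models[str(tone)] = model
    return models


def classify(models: dict[str, GaussianHMM], features: list[np.ndarray]
             ) -> np.ndarray:
    """Assign each track to the argmax-log-likelihood tone.

    Ties go to the lowest tone index and are counted in a logged warning.
    """
    tones = sorted(models)
    n_ties = 0
    pred = []
    for x in features:
        ll = np.array([models[t].score(x) for t in tones])
        ll = np.where(np.isfinite(ll), ll, -np.inf)
        best = np.flatnonzero(ll == ll.max())
        if len(best) > 1:
            n_ties += 1
        pred.append(tones[best[0]])
    if n_ties:
        logger.warning("%d log-likelihood ties resolved to the lowest tone",
                       n_ties)
    return np.array(pred)


def decode_confusion(features: list[np.ndarray], labels, cv_scheme="loo",
                     n_states: int = 4, seed: int = 0,
                     averaging_size: int = 1) -> ConfusionMatrix:
    """Cross-validated confusion matrix of HMM tone decoding.

    ``cv_scheme`` is ``"loo"`` (leave-one-track-out) or ``("kfold", k)``
    with stratified folds; no track is ever in both train and test of the
    same fold.
    """
    labels = np.asarray(labels)
    tones = sorted(np.unique(labels))
    n = len(labels)
    if cv_scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif isinstance(cv_scheme, tuple) and cv_scheme[0] == "kfold":
        k = cv_scheme[1]
        rng = np.random.default_rng(seed)
        folds = [[] for _ in range(k)]
        for tone in tones:  # stratified assignment
            idx = rng.permutation(np.nonzero(labels == tone)[0])
            for j, i in enumerate(idx):
                folds[j % k].append(i)
        folds = [np.array(sorted(f)) for f in folds if f]
    else:
        raise ValueError(f"unknown cv_scheme {cv_scheme!r}")

    counts = np.zeros((len(tones), len(tones)))
    tone_pos = {t: i for i, t in enumerate(tones)}
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        assert not np.any(~train_mask & train_mask)
        models = fit_hmm_decoder([features[i] for i in np.nonzero(train_mask)[0]],
                                 labels[train_mask], n_states, seed)
        pred = classify(models, [features[i] for i in test_idx])
        for i, p in zip(test_idx, pred):
            counts[tone_pos[labels[i]], tone_pos[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    matrix = counts / np.where(row_sums == 0, 1, row_sums)
    return ConfusionMatrix(matrix, list(tones), counts, averaging_size)
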