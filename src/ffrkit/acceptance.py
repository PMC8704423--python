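"""Headline quantities recomputed end-to-end from the package itself.

Each function synthesizes its own inputs (stimuli, simulated recordings),
runs the relevant analysis chain, and returns a measured number: the pitch
readouts of the four tone stimuli, the exact ITPC of replicated trials, and
the cross-validated HMM decoding accuracy on simulated FFRs.  Used by
``scripts/acceptance.py`` and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from .decode import decode_confusion, make_averaged_trials, track_features
from .forward import ForwardModelConfig, simulate_ffr_dataset
from .itpc import itpc
from .pitch import track_pitch
from .stimuli import TONE_IDS, synthesize_tone

__all__ = ["stimulus_pitch_facts", "itpc_of_replicated_trials",
           "decoding_accuracy_moderate_noise"]


def stimulus_pitch_facts() -> dict[str, tuple[float, int]]:
    """Pitch-track readouts of the synthesized stimuli, (value_hz, n_windows).

    * t1_mean_f0_t1 — mean F0 over voiced windows of T1 (high-level tone)
    * first voiced window of T2 (low-rising), last of T4 (high-falling),
      minimum over T3 (low-dipping)
    """
    tracks = {}
    for tone in TONE_IDS:
        s = synthesize_tone(tone)
        tr = track_pitch(s.waveform, s.fs, window_ms=40.0, step_ms=10.0,
                         f0_range=(80.0, 180.0))
        tracks[tone] = tr.voiced_f0()
    return {
        "t1": (float(np.mean(tracks["T1"])), len(tracks["T1"])),
        "t2": (float(tracks["T2"][0]), len(tracks["T2"])),
        "t3": (float(tracks["T4"][-1]), len(tracks["T4"])),
        "t4": (float(np.min(tracks["T3"])), len(tracks["T3"])),
    }


def itpc_of_replicated_trials(n_trials: int = 50) -> tuple[float, int]:
    """ITPC at the T1 F0, mid-epoch, for n copies of one noiseless trial."""
    cfg = ForwardModelConfig(n_trials=1, noise_rms_uv=0.0,
                             line_amps_uv=(0.0, 0.0, 0.0), seed=0)
    stim = synthesize_tone("T1")
    rec = simulate_ffr_dataset(cfg, [stim])
    trial = rec.data[0, rec.channel_index("PAC_surface"), :]
    spec = itpc(np.tile(trial, (n_trials, 1)), fs=rec.fs, t0_ms=rec.t0_ms,
                n_freqs=130, fmin=70.0, fmax=200.0)
    f_bin = int(np.argmin(np.abs(spec.freqs_hz - 129.0)))
    t_bin = int(np.argmin(np.abs(spec.times_ms - 125.0)))
    return float(spec.values[f_bin, t_bin]), n_trials


def decoding_accuracy_moderate_noise(seed: int = 7, n_trials_per_tone: int = 200,
                                     averaging_size: int = 16
                                     ) -> tuple[float, int, int]:
    """Cross-validated HMM decoding accuracy on simulated FFR pseudo-trials.

    Default forward model (trial SNR ~0.5 at the scalp), pseudo-trials of
    ``averaging_size`` raw trials, leave-one-pseudo-trial-out CV.  Returns
    (mean diagonal of the confusion matrix, n_pseudo_trials, n_correct).
    """
    stimuli = [synthesize_tone(t) for t in TONE_IDS]
    cfg = ForwardModelConfig(n_trials=n_trials_per_tone // 2, seed=seed)
    rec = simulate_ffr_dataset(cfg, stimuli)
    waves, labels = make_averaged_trials(rec, averaging_size, seed=7,
                                         channel="Cz")
    feats = [track_features(w, rec.fs, rec.t0_ms) for w in waves]
    cm = decode_confusion(feats, labels, cv_scheme="loo", seed=7,
                          averaging_size=averaging_size)
    n = int(cm.counts.sum())
    n_correct = int(np.trace(cm.counts))
    return float(cm.accuracy), n, n_correct
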