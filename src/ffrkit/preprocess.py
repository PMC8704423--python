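"""Cleaning, filtering, artifact rejection and polarity averaging.

The default chain, in fixed order: power-line removal (least-squares
sine/cosine regression at the line frequency and harmonics), zero-phase
band-pass filtering, amplitude-threshold artifact rejection, then averaging
across the two stimulus polarities to cancel any component that sign-flips
with the presentation polarity (stimulus artifact, cochlear microphonic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EpochedRecording

__all__ = ["FFRWaveform", "remove_line_noise", "filter_epochs",
           "reject_artifacts", "average_polarities"]

logger = logging.getLogger(__name__)


@dataclass
class FFRWaveform:
    """An averaged FFR for one tone at one channel."""

    samples: np.ndarray  # µV
    fs: float
    t0_ms: float
    tone_id: str
    channel: str
    n_trials: int

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + 1e3 * np.arange(len(self.samples)) / self.fs

    def window(self, start_ms: float, stop_ms: float) -> np.ndarray:
        t = self.times_ms
        return self.samples[(t >= start_ms) & (t < stop_ms)]


def remove_line_noise(rec: EpochedRecording, line_freq_hz: float = 60.0,
                      n_harmonics: int = 3) -> EpochedRecording:
    """Regress out sine+cosine components at the line frequency and harmonics.

    A least-squares fit of sin/cos regressors at ``k * line_freq_hz`` is
    subtracted per trial and channel; everything orthogonal to the regressors
    is untouched.  Harmonics at or above Nyquist are skipped with a warning.
    """
    if line_freq_hz >= rec.fs / 2:
        raise ValueError("line frequency must be below Nyquist")
    n = rec.data.shape[2]
    t = np.arange(n) / rec.fs
    cols = []
    for k in range(1, n_harmonics + 1):
        f = k * line_freq_hz
        if f >= rec.fs / 2:
            logger.warning("skipping line harmonic %.0f Hz (>= Nyquist)", f)
            continue
        cols += [np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)]
    if not cols:
        return rec
    X = np.column_stack(cols)  # n x p
    proj = X @ np.linalg.solve(X.T @ X, X.T)  # hat matrix, p small
    flat = rec.data.reshape(-1, n)
    cleaned = flat - flat @ proj.T
    return EpochedRecording(cleaned.reshape(rec.data.shape), rec.fs, rec.t0_ms,
                            rec.channels, rec.polarity, rec.tone_id)


def filter_epochs(rec: EpochedRecording, band: tuple[float, float | None],
                  order: int = 3) -> EpochedRecording:
    """Zero-phase Butterworth filtering (forward-backward, `sosfiltfilt`).

    ``band`` is (low, high); pass ``None`` as the high edge for a pure
    high-pass (no low-pass applied, as when the sampling rate itself limits
    the upper band edge).
    """
    low, high = band
    if high is not None and low >= high:
        raise ValueError("band edges inverted")
    if low <= 0 or (high is not None and high >= rec.fs / 2):
        raise ValueError("band must lie within (0, fs/2)")
    if high is None:
        sos = signal.butter(order, low, btype="highpass", fs=rec.fs,
                            output="sos")
    else:
        sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                            output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return EpochedRecording(filtered, rec.fs, rec.t0_ms, rec.channels,
                            rec.polarity, rec.tone_id)


def reject_artifacts(rec: EpochedRecording, threshold_uv: float = 75.0
                     ) -> tuple[EpochedRecording, dict[str, int]]:
    """Drop trials whose peak absolute amplitude exceeds the threshold.

    The criterion is evaluated per trial over all analyzed channels (a trial
    is rejected if any channel exceeds the threshold).  Returns the retained
    recording and per-tone rejection counts.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    peak = np.max(np.abs(rec.data), axis=(1, 2))
    keep = peak <= threshold_uv
    if not keep.any():
        raise ValueError(f"all trials exceed the {threshold_uv} µV threshold")
    counts: dict[str, int] = {}
    for tone in np.unique(rec.tone_id):
        counts[str(tone)] = int(np.sum(~keep & (rec.tone_id == tone)))
    return rec.pick_trials(keep), counts


def average_polarities(rec: EpochedRecording, channel: int | str = 0
                       ) -> dict[str, FFRWaveform]:
    """Per tone: mean of (condensation mean, rarefaction mean) at one channel.

    Polarity means are weighted equally regardless of trial counts, so any
    component that sign-flips with polarity cancels exactly in expectation.
    Falls back to the plain mean (with a warning) if a polarity is absent.
    """
    if isinstance(channel, str):
        channel = rec.channel_index(channel)
    label = rec.channels[channel].label
    out: dict[str, FFRWaveform] = {}
    for tone in np.unique(rec.tone_id):
        sel = rec.tone_id == tone
        cond = sel & (rec.polarity == "condensation")
        rare = sel & (rec.polarity == "rarefaction")
        if cond.any() and rare.any():
            avg = 0.5 * (rec.data[cond, channel].mean(axis=0) +
                         rec.data[rare, channel].mean(axis=0))
        else:
            logger.warning("tone %s: only one polarity present; plain mean",
                           tone)
            avg = rec.data[sel, channel].mean(axis=0)
        out[str(tone)] = FFRWaveform(avg, rec.fs, rec.t0_ms, str(tone),
                                     label, int(sel.sum()))
    return out
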