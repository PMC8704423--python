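"""Synthesis of the four Mandarin-tone vowel stimuli.

The stimuli are /i/-like vowels whose fundamental frequency follows one of
the four Mandarin lexical tone contours:

* T1 — high-level, F0 constant at 129 Hz
* T2 — low-rising, F0 from 109 to 133 Hz
* T3 — low-dipping, F0 from 105 Hz down to 89 Hz and back up to 111 Hz
* T4 — high-falling, F0 from 140 to 92 Hz

All contours respect the printed endpoints/extrema above.  Trajectories are
cosine-eased (zero slope at onset and offset, and around the T3 dip), the
shape natural tone productions take; only T1 is constant.  The vowel itself
is a harmonic pulse train shaped by a fixed two-resonance spectral envelope,
which is all the downstream periodicity analyses require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = ["ToneStimulus", "TONE_IDS", "make_f0_contour", "synthesize_tone",
           "write_wav", "read_wav"]

TONE_IDS = ("T1", "T2", "T3", "T4")

#: printed endpoint / extremum values (Hz) per tone
_CONTOUR_SPECS = {
    "T1": {"kind": "flat", "f0": 129.0},
    "T2": {"kind": "rise", "start": 109.0, "end": 133.0},
    "T3": {"kind": "dip", "start": 105.0, "min": 89.0, "dip_frac": 0.6,
           "end": 111.0},
    "T4": {"kind": "fall", "start": 140.0, "end": 92.0},
}


@dataclass
class ToneStimulus:
    """A synthesized tone stimulus with its ground-truth F0 contour."""

    tone_id: str
    waveform: np.ndarray
    fs: float
    f0_contour: np.ndarray = field(repr=False)

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / self.fs

    def __post_init__(self) -> None:
        if self.tone_id not in TONE_IDS:
            raise ValueError(f"unknown tone_id {self.tone_id!r}")
        if len(self.waveform) != len(self.f0_contour):
            raise ValueError("waveform and f0_contour lengths differ")


def _eased(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Cosine ramp from ``lo`` at t=0 to ``hi`` at t=1 with zero edge slope."""
    return lo + (hi - lo) * 0.5 * (1.0 - np.cos(np.pi * t))


def make_f0_contour(tone_id: str, n_samples: int, fs: float) -> np.ndarray:
    """Ground-truth F0 trajectory (Hz per sample) for one Mandarin tone.

    Parameters
    ----------
    tone_id : {"T1", "T2", "T3", "T4"}
    n_samples : int
        Length of the contour in samples.
    fs : float
        Sampling rate (only fixes the time base; shapes are relative).
    """
    if tone_id not in _CONTOUR_SPECS:
        raise ValueError(f"unknown tone_id {tone_id!r}; expected one of {TONE_IDS}")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    spec = _CONTOUR_SPECS[tone_id]
    u = np.linspace(0.0, 1.0, n_samples)
    if spec["kind"] == "flat":
        return np.full(n_samples, spec["f0"])
    if spec["kind"] == "rise":
        return _eased(u, spec["start"], spec["end"])
    if spec["kind"] == "fall":
        return _eased(u, spec["start"], spec["end"])
    # low-dipping: two eased half-arcs meeting at the minimum
    split = spec["dip_frac"]
    contour = np.empty(n_samples)
    down = u <= split
    contour[down] = _eased(u[down] / split, spec["start"], spec["min"])
    contour[~down] = _eased((u[~down] - split) / (1.0 - split),
                            spec["min"], spec["end"])
    return contour


def _resonator(freq_hz: float, q: float, fs: float):
    b, a = signal.iirpeak(freq_hz, q, fs=fs)
    return b, a


def synthesize_tone(tone_id: str, fs: float = 48000.0,
                    duration_s: float = 0.25, n_harmonics: int = 30,
                    ramp_ms: float = 10.0) -> ToneStimulus:
    """Synthesize one vowel stimulus (harmonic source + /i/-like envelope).

    The source is a sum of harmonics of the instantaneous F0 with 1/h
    amplitudes; a fixed pair of resonances near 300 and 2200 Hz imposes a
    minimal /i/-like spectral envelope.  The output is peak-normalized to
    |x| <= 1 and gated with cosine-squared onset/offset ramps.  Deterministic
    for fixed inputs.
    """
    if fs < 8000:
        raise ValueError("fs must be >= 8000 Hz")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * fs))
    contour = make_f0_contour(tone_id, n, fs)
    phase = 2.0 * np.pi * np.cumsum(contour) / fs
    x = np.zeros(n)
    nyq = fs / 2.0
    for h in range(1, n_harmonics + 1):
        if h * contour.max() >= nyq:
            break
        x += np.sin(h * phase) / h
    # two-resonance vowel envelope
    for freq, q in ((300.0, 4.0), (2200.0, 8.0)):
        b, a = _resonator(freq, q, fs)
        x = x + 3.0 * signal.lfilter(b, a, x)
    n_ramp = int(round(ramp_ms * 1e-3 * fs))
    if n_ramp > 0:
        ramp = np.sin(np.linspace(0, np.pi / 2, n_ramp)) ** 2
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    x /= np.max(np.abs(x))
    return ToneStimulus(tone_id=tone_id, waveform=x, fs=fs, f0_contour=contour)


def write_wav(path, stim: ToneStimulus) -> None:
    """Write a stimulus as 32-bit float mono WAV."""
    wavfile.write(path, int(stim.fs), stim.waveform.astype(np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV; returns (waveform, fs)."""
    fs, x = wavfile.read(path)
    return np.asarray(x, dtype=float), float(fs)
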