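"""Scalp-versus-cortex spectrotemporal comparison.

Three views of how two FFRs (typically one scalp and one intracortical
channel, same stimuli) relate:

* normalized Welch power spectral density (maximum set to 0 dB), averaged
  over the four tones before normalization, exposing the relative roll-off
  of harmonics above the F0;
* the magnitude of the Welch cross-spectral density, averaged over tones —
  shared power regardless of latency;
* frequency-wise cross-correlation latency of generalized-Morse-wavelet band
  signals — positive lags mean the cortical FFR lags the scalp FFR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import FFRWaveform

__all__ = ["LatencyByFrequency", "welch_psd_norm", "cross_spectral_density",
           "morse_bank_fft", "wavelet_xcorr_latency"]

logger = logging.getLogger(__name__)


@dataclass
class LatencyByFrequency:
    freqs_hz: np.ndarray
    lag_ms: np.ndarray  # positive => cortical lags scalp
    r: np.ndarray  # signed coefficient at the best |r| lag
    cpsd_mag: np.ndarray  # |CPSD| interpolated onto freqs_hz
    ambiguous: np.ndarray  # |lag| >= one period at that frequency


def _as_arrays(ffrs) -> tuple[list[np.ndarray], float]:
    """Accept one FFRWaveform/array or a list of them; return arrays + fs."""
    if isinstance(ffrs, (FFRWaveform, np.ndarray)):
        ffrs = [ffrs]
    arrays, fs = [], None
    for f in ffrs:
        if isinstance(f, FFRWaveform):
            arrays.append(np.asarray(f.samples, float))
            fs = f.fs if fs is None else fs
        else:
            arrays.append(np.asarray(f, float))
    return arrays, fs


def _welch_args(n: int, nperseg: int):
    if n < nperseg:
        logger.warning("signal shorter than nperseg=%d; shrinking to %d",
                       nperseg, n)
        nperseg = n
    return dict(window="hamming", nperseg=nperseg, noverlap=nperseg // 2)


def welch_psd_norm(ffrs, fs: float | None = None, nperseg: int = 1024
                   ) -> tuple[np.ndarray, np.ndarray]:
    """dB-scaled Welch PSD averaged over tones, maximum exactly 0 dB.

    Returns ``(freqs_hz, psd_db)``.
    """
    arrays, fs_found = _as_arrays(ffrs)
    fs = fs or fs_found
    if fs is None:
        raise ValueError("fs required with array input")
    psds = []
    for x in arrays:
        if not np.any(x):
            raise ValueError("all-zero signal has no PSD to normalize")
        f, p = signal.welch(x, fs=fs, **_welch_args(len(x), nperseg))
        psds.append(p)
    mean_psd = np.mean(psds, axis=0)
    db = 10.0 * np.log10(np.maximum(mean_psd, 1e-300))
    return f, db - db.max()


def cross_spectral_density(ffrs_a, ffrs_b, fs: float | None = None,
                           nperseg: int = 1024
                           ) -> tuple[np.ndarray, np.ndarray]:
    """|Welch cross-spectrum| between paired FFRs, averaged over tones.

    Mismatched lengths are truncated to the shorter signal (warning).
    """
    arrays_a, fs_a = _as_arrays(ffrs_a)
    arrays_b, fs_b = _as_arrays(ffrs_b)
    fs = fs or fs_a or fs_b
    if fs_a is not None and fs_b is not None and fs_a != fs_b:
        raise ValueError("sampling rates differ")
    if len(arrays_a) != len(arrays_b):
        raise ValueError("need the same number of signals on both sides")
    mags = []
    for x, y in zip(arrays_a, arrays_b):
        if len(x) != len(y):
            logger.warning("length mismatch (%d vs %d); truncating",
                           len(x), len(y))
            n = min(len(x), len(y))
            x, y = x[:n], y[:n]
        f, pxy = signal.csd(x, y, fs=fs, **_welch_args(len(x), nperseg))
        mags.append(np.abs(pxy))
    return f, np.mean(mags, axis=0)


def morse_bank_fft(freqs_hz: np.ndarray, n_fft: int, fs: float,
                   gamma: float = 3.0, beta: float = 20.0) -> np.ndarray:
    """Generalized Morse wavelet bank in the frequency domain.

    The mother wavelet is ``a * w^beta * exp(-w^gamma)`` for w > 0, peak
    frequency ``(beta/gamma)^(1/gamma)``; each row is scaled so its peak
    sits at the requested analysis frequency and has unit gain there.
    """
    w = 2.0 * np.pi * np.fft.fftfreq(n_fft, 1.0 / fs)
    w_peak = (beta / gamma) ** (1.0 / gamma)
    bank = np.zeros((len(freqs_hz), n_fft))
    for i, f0 in enumerate(freqs_hz):
        ws = w * w_peak / (2.0 * np.pi * f0)
        pos = ws > 0
        bank[i, pos] = np.exp(beta * np.log(ws[pos]) - ws[pos] ** gamma
                              - (beta * np.log(w_peak) - w_peak ** gamma))
    return 2.0 * bank  # analytic convention


def _band_signals(x: np.ndarray, freqs_hz, fs, gamma, beta) -> np.ndarray:
    n = len(x)
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    bank = morse_bank_fft(np.asarray(freqs_hz, float), n_fft, fs, gamma, beta)
    spec = np.fft.fft(x, n=n_fft)
    return np.real(np.fft.ifft(spec[None, :] * bank, axis=-1))[:, :n]


def wavelet_xcorr_latency(ffr_scalp, ffr_cortex, freqs_hz,
                          fs: float | None = None, max_lag_ms: float = 30.0,
                          gamma: float = 3.0, beta: float = 20.0
                          ) -> LatencyByFrequency:
    """Per-frequency cross-correlation lag between scalp and cortical FFRs.

    Both waveforms are decomposed with the Morse bank; the real-valued band
    signals are Pearson-cross-correlated within ±``max_lag_ms`` and the lag
    of the maximum |r| is reported, positive when the cortical FFR lags the
    scalp FFR.  Lags of at least one period at their frequency are flagged
    ambiguous (cycle slipping).
    """
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if freqs_hz.size == 0:
        raise ValueError("empty frequency grid")
    (xs,), fs_a = _as_arrays(ffr_scalp)
    (xc,), fs_b = _as_arrays(ffr_cortex)
    fs = fs or fs_a or fs_b
    if len(xs) != len(xc):
        raise ValueError("scalp and cortical FFRs must share the time base")
    bands_s = _band_signals(xs, freqs_hz, fs, gamma, beta)
    bands_c = _band_signals(xc, freqs_hz, fs, gamma, beta)
    n = len(xs)
    max_lag = int(round(max_lag_ms * 1e-3 * fs))
    lags_full = signal.correlation_lags(n, n, mode="full")
    keep = np.abs(lags_full) <= max_lag
    lag_ms = np.empty(len(freqs_hz))
    r = np.empty(len(freqs_hz))
    for i in range(len(freqs_hz)):
        a = bands_s[i] - bands_s[i].mean()
        b = bands_c[i] - bands_c[i].mean()
        cc = signal.correlate(b, a, mode="full")[keep]
        cc = cc / (n * a.std() * b.std())
        k = int(np.argmax(np.abs(cc)))
        lag_ms[i] = lags_full[keep][k] / fs * 1e3
        r[i] = cc[k]
    f_csd, mag = cross_spectral_density([xs], [xc], fs=fs,
                                        nperseg=min(1024, n))
    cpsd = np.interp(freqs_hz, f_csd, mag)
    ambiguous = np.abs(lag_ms) >= 1e3 / freqs_hz
    if ambiguous.any():
        logger.warning("%d frequencies have period-ambiguous lags",
                       int(ambiguous.sum()))
    return LatencyByFrequency(freqs_hz, lag_ms, r, cpsd, ambiguous)
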