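"""Inter-trial phase coherence (ITPC) spectrograms.

Each trial is decomposed with a bank of complex Morlet wavelets; every
time-frequency coefficient is normalized to unit magnitude, the unit vectors
are averaged across trials, and the magnitude of the resultant is the ITPC:
0 means no phase consistency across trials, 1 perfect phase-locking.  ITPC
is by construction independent of per-trial amplitude.

The default bank has 130 linearly spaced frequencies between 70 and 200 Hz
with *equal temporal widths* (one fixed Gaussian envelope duration across
frequencies); a constant-cycles Morlet bank is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import EpochedRecording

__all__ = ["ITPCSpectrogram", "itpc", "itpc_at_f0"]

_EPS_MAG = 1e-12


@dataclass
class ITPCSpectrogram:
    values: np.ndarray  # freq x time, in [0, 1]
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    n_trials: int

    def __post_init__(self):
        if self.values.shape != (len(self.freqs_hz), len(self.times_ms)):
            raise ValueError("inconsistent ITPC dimensions")


def _wavelet_bank_fft(freqs: np.ndarray, n_fft: int, fs: float,
                      width_ms: float | None, n_cycles: float | None
                      ) -> np.ndarray:
    """Frequency-domain complex Morlet bank (analytic, Gaussian envelope).

    With ``width_ms`` the Gaussian SD is fixed across frequencies (equal
    temporal widths); with ``n_cycles`` it scales as n_cycles / freq.
    """
    fft_freqs = np.fft.fftfreq(n_fft, 1.0 / fs)
    bank = np.empty((len(freqs), n_fft), dtype=complex)
    for i, f0 in enumerate(freqs):
        sigma_t = (width_ms * 1e-3) if width_ms is not None else n_cycles / (2 * np.pi * f0)
        # FT of (analytic) Morlet: Gaussian centred at f0, zero at f < 0
        h = np.exp(-2.0 * (np.pi * sigma_t) ** 2 * (fft_freqs - f0) ** 2)
        h[fft_freqs < 0] = 0.0
        bank[i] = 2.0 * h  # analytic-signal convention
    return bank


def itpc(rec_or_data, fs: float | None = None,
         freqs_hz: np.ndarray | None = None, n_freqs: int = 130,
         fmin: float = 70.0, fmax: float = 200.0,
         width_ms: float | None = 40.0, n_cycles: float | None = None,
         t0_ms: float = 0.0) -> ITPCSpectrogram:
    """ITPC spectrogram of a set of epochs.

    Parameters
    ----------
    rec_or_data : EpochedRecording (single channel picked) or array
        Either a (trials, samples) array with ``fs`` given, or an
        EpochedRecording whose first channel is analyzed.
    freqs_hz : array, optional
        Analysis frequencies; defaults to ``n_freqs`` linearly spaced in
        [fmin, fmax].
    width_ms : float
        Gaussian envelope SD of every wavelet (equal-width bank).  Set to
        None and pass ``n_cycles`` for a constant-cycles bank instead.
    """
    if isinstance(rec_or_data, EpochedRecording):
        fs = rec_or_data.fs
        t0_ms = rec_or_data.t0_ms
        data = rec_or_data.data[:, 0, :]
    else:
        data = np.asarray(rec_or_data, dtype=float)
        if fs is None:
            raise ValueError("fs required with array input")
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need >= 2 trials of shape (trials, samples)")
    if freqs_hz is None:
        freqs_hz = np.linspace(fmin, fmax, n_freqs)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs_hz >= fs / 2):
        raise ValueError("analysis frequency at or above Nyquist")
    if (width_ms is None) == (n_cycles is None):
        raise ValueError("give exactly one of width_ms or n_cycles")

    n_trials, n_samples = data.shape
    n_fft = int(2 ** np.ceil(np.log2(2 * n_samples)))
    bank = _wavelet_bank_fft(freqs_hz, n_fft, fs, width_ms, n_cycles)
    spec = np.fft.fft(data, n=n_fft, axis=-1)  # trials x nfft
    resultant = np.zeros((len(freqs_hz), n_samples), dtype=complex)
    counts = np.zeros((len(freqs_hz), n_samples))
    for i in range(len(freqs_hz)):
        coeff = np.fft.ifft(spec * bank[i][None, :], axis=-1)[:, :n_samples]
        mag = np.abs(coeff)
        good = mag > _EPS_MAG  # exclude numerically dead coefficients
        unit = np.where(good, coeff / np.where(good, mag, 1.0), 0.0)
        resultant[i] = unit.sum(axis=0)
        counts[i] = good.sum(axis=0)
    values = np.abs(resultant) / np.maximum(counts, 1)
    values[counts == 0] = 0.0
    times_ms = t0_ms + 1e3 * np.arange(n_samples) / fs
    return ITPCSpectrogram(np.clip(values, 0.0, 1.0), freqs_hz, times_ms,
                           n_trials)


def itpc_at_f0(spec: ITPCSpectrogram, f0_contour_hz: np.ndarray,
               contour_times_ms: np.ndarray | None = None) -> np.ndarray:
    """Sample the spectrogram along a stimulus F0 trajectory.

    Nearest-frequency sampling; contour values outside the frequency grid
    are clamped to the nearest edge (with a warning).  If contour times are
    given the contour is interpolated onto the spectrogram's time axis
    (times outside the contour return NaN).
    """
    f0 = np.asarray(f0_contour_hz, dtype=float)
    if f0.size == 0:
        raise ValueError("empty F0 contour")
    if contour_times_ms is not None:
        f0 = np.interp(spec.times_ms, contour_times_ms, f0,
                       left=np.nan, right=np.nan)
    elif len(f0) != len(spec.times_ms):
        raise ValueError("contour length must match the time axis "
                         "(or pass contour_times_ms)")
    lo, hi = spec.freqs_hz.min(), spec.freqs_hz.max()
    if np.nanmin(f0) < lo or np.nanmax(f0) > hi:
        import logging
        logging.getLogger(__name__).warning(
            "F0 contour exits the frequency grid; clamping")
    out = np.full(len(spec.times_ms), np.nan)
    valid = np.isfinite(f0)
    idx = np.argmin(np.abs(spec.freqs_hz[:, None] -
                           np.clip(f0[valid], lo, hi)[None, :]), axis=0)
    out[valid] = spec.values[idx, np.nonzero(valid)[0]]
    return out
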