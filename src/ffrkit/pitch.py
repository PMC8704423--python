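"""Sliding-window autocorrelation pitch tracking.

Per window, the normalized autocorrelation is evaluated over the lags
spanning the F0 search range; the best lag gives the window's F0 and the
maximum coefficient its pitch strength.  Windows whose strength falls below
a threshold are flagged unvoiced and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PitchTrack", "track_pitch", "track_correlation"]


@dataclass
class PitchTrack:
    times_ms: np.ndarray  # window centres
    f0_hz: np.ndarray
    strength: np.ndarray  # max autocorrelation per window, floored at 0
    voiced: np.ndarray  # bool per window
    window_ms: float
    step_ms: float
    f0_range: tuple[float, float]

    def voiced_f0(self) -> np.ndarray:
        return self.f0_hz[self.voiced]


def track_pitch(waveform: np.ndarray, fs: float, window_ms: float = 40.0,
                step_ms: float = 10.0, f0_range: tuple[float, float] = (80.0, 180.0),
                voicing_threshold: float = 0.3,
                parabolic: bool = False) -> PitchTrack:
    """Sliding-window autocorrelation F0 track of a waveform.

    Parameters
    ----------
    parabolic : bool
        Refine the best lag by parabolic interpolation of the
        autocorrelation peak (never moves it by more than one lag step);
        off by default so tracks stay on the exact lag grid.
    """
    x = np.asarray(waveform, dtype=float)
    f_lo, f_hi = f0_range
    if f_lo <= 0 or f_hi <= f_lo:
        raise ValueError("invalid f0_range")
    win = int(round(window_ms * 1e-3 * fs))
    step = int(round(step_ms * 1e-3 * fs))
    if win > len(x):
        raise ValueError("window longer than waveform")
    if win < 2 * fs / f_lo:
        raise ValueError("window must span >= 2 periods of the lowest F0")
    lag_min = int(np.floor(fs / f_hi))
    lag_max = int(np.ceil(fs / f_lo))
    starts = np.arange(0, len(x) - win + 1, step)
    times, f0s, strengths = [], [], []
    for s in starts:
        seg = x[s:s + win] - x[s:s + win].mean()
        denom = np.dot(seg, seg)
        if denom == 0:
            times.append((s + win / 2) / fs * 1e3)
            f0s.append(np.nan)
            strengths.append(0.0)
            continue
        lags = np.arange(lag_min, min(lag_max, win - 1) + 1)
        ac = np.array([np.dot(seg[:-lag], seg[lag:]) /
                       np.sqrt(np.dot(seg[:-lag], seg[:-lag]) *
                               np.dot(seg[lag:], seg[lag:]))
                       for lag in lags])
        k = int(np.argmax(ac))
        best = float(lags[k])
        if parabolic and 0 < k < len(ac) - 1:
            denom2 = ac[k - 1] - 2 * ac[k] + ac[k + 1]
            if denom2 < 0:
                delta = 0.5 * (ac[k - 1] - ac[k + 1]) / denom2
                best += float(np.clip(delta, -1.0, 1.0))
        times.append((s + win / 2) / fs * 1e3)
        f0s.append(fs / best)
        strengths.append(max(float(ac[k]), 0.0))
    f0s = np.array(f0s)
    strengths = np.array(strengths)
    voiced = (strengths >= voicing_threshold) & np.isfinite(f0s)
    return PitchTrack(np.array(times), f0s, strengths, voiced,
                      window_ms, step_ms, f0_range)


def track_correlation(track_a: PitchTrack, track_b: PitchTrack) -> float:
    """Pearson correlation of two F0 tracks over their shared voiced windows."""
    if len(track_a.times_ms) != len(track_b.times_ms) or \
            not np.allclose(track_a.times_ms, track_b.times_ms):
        raise ValueError("tracks must share the same window grid")
    both = track_a.voiced & track_b.voiced
    if both.sum() < 3:
        raise ValueError("fewer than 3 shared voiced windows")
    a = track_a.f0_hz[both]
    b = track_b.f0_hz[both]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance track")
    return float(np.corrcoef(a, b)[0, 1])
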