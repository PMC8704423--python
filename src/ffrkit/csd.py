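"""Laminar current source density (CSD) analysis.

CSD is the second spatial derivative of the laminar LFP across depth after
Gaussian smoothing along the depth axis.  Sign convention: **sinks are
negative** (net inward current).  Edge depths are dropped (no padding), so
the profile has two fewer depths than the input.  The earliest post-onset
sink localizes the putative thalamorecipient (granular) layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

__all__ = ["CSDProfile", "compute_csd", "find_earliest_sink",
           "stimulus_csd_correlation", "extract_mua"]

logger = logging.getLogger(__name__)


@dataclass
class CSDProfile:
    csd: np.ndarray  # depth x time, sink-negative
    depths_um: np.ndarray  # interior depths
    fs: float
    t0_ms: float
    spacing_um: float
    smoothing_sd_um: float

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + 1e3 * np.arange(self.csd.shape[1]) / self.fs


def compute_csd(lfp_by_depth: np.ndarray, depths_um: np.ndarray, fs: float,
                smoothing_sd_um: float = 250.0, t0_ms: float = 0.0,
                vaknin: bool = False) -> CSDProfile:
    """CSD from a (depths x time) LFP array at uniformly spaced depths.

    Gaussian smoothing (the stated SD, in µm) is applied along depth, then
    the finite-difference second derivative
    ``-(V[d-1] - 2 V[d] + V[d+1]) / spacing**2`` at each interior depth.
    The result is reference-free: any depth-constant offset cancels.
    ``vaknin=True`` duplicates the edge channels first so all input depths
    are retained.
    """
    lfp = np.asarray(lfp_by_depth, dtype=float)
    depths = np.asarray(depths_um, dtype=float)
    if lfp.ndim != 2 or lfp.shape[0] != len(depths):
        raise ValueError("lfp must be depths x time matching depths_um")
    if len(depths) < 3:
        raise ValueError("need at least 3 depth channels")
    spacings = np.diff(depths)
    if not np.allclose(spacings, spacings[0]):
        raise ValueError("electrode depths must be uniformly spaced")
    spacing = float(spacings[0])
    if vaknin:
        lfp = np.vstack([lfp[:1], lfp, lfp[-1:]])
        depths = np.concatenate([[depths[0] - spacing], depths,
                                 [depths[-1] + spacing]])
    if smoothing_sd_um > 0:
        lfp = gaussian_filter1d(lfp, smoothing_sd_um / spacing, axis=0,
                                mode="nearest")
    csd = -(lfp[:-2] - 2.0 * lfp[1:-1] + lfp[2:]) / spacing ** 2
    return CSDProfile(csd, depths[1:-1], fs, t0_ms, spacing, smoothing_sd_um)


def find_earliest_sink(profile: CSDProfile, search_window_ms=(0.0, 50.0),
                       k_sd: float = 3.0, min_duration_ms: float = 1.0):
    """Earliest post-onset sink: first crossing of -k·SD(baseline) per depth.

    A crossing only counts if it stays below threshold for
    ``min_duration_ms`` (guards against single-sample baseline noise).
    Returns ``(depth_index, latency_ms)`` of the earliest threshold-crossing
    negative deflection across depths, or ``None`` if no depth crosses
    ("no sink" is a result, not an error).
    """
    if search_window_ms[0] < 0:
        raise ValueError("search window must start at or after stimulus onset")
    t = profile.times_ms
    base = profile.csd[:, t < 0.0]
    if base.size == 0:
        raise ValueError("no prestimulus baseline in the CSD")
    sd = base.std(axis=1)
    # floor for (near-)noiseless data, where any baseline SD would otherwise
    # make the threshold degenerate
    floor = 1e-3 * np.max(np.abs(profile.csd))
    sd = np.maximum(sd, floor if floor > 0 else np.inf)
    in_win = (t >= search_window_ms[0]) & (t < search_window_ms[1])
    win_t = t[in_win]
    min_run = max(int(round(min_duration_ms * 1e-3 * profile.fs)), 1)
    candidates = []  # (latency, depth, sink magnitude)
    for d in range(profile.csd.shape[0]):
        below = profile.csd[d, in_win] < -k_sd * sd[d]
        for start in np.nonzero(below)[0]:
            if start + min_run <= len(below) and \
                    below[start:start + min_run].all():
                candidates.append((float(win_t[start]), d,
                                   -float(profile.csd[d, in_win].min())))
                break
    if not candidates:
        return None
    earliest = min(c[0] for c in candidates)
    # simultaneous crossings (within one sample): strongest sink wins
    tied = [c for c in candidates
            if c[0] <= earliest + 1e3 / profile.fs + 1e-9]
    lat, d, _ = max(tied, key=lambda c: c[2])
    return d, lat


def stimulus_csd_correlation(profile: CSDProfile, stimulus_feature: np.ndarray,
                             max_lag_ms: float = 30.0):
    """Per depth, the max-|r| cross-correlation against a stimulus feature.

    The feature (stimulus envelope by default upstream, or the waveform)
    must already be on the CSD time base.  The sign of r is retained so
    polarity flips across layers stay visible.  Returns ``(r, lag_ms)``
    arrays over depths; lags at the search bound are flagged via a warning.
    """
    feat = np.asarray(stimulus_feature, dtype=float)
    if len(feat) != profile.csd.shape[1]:
        raise ValueError("stimulus feature must be resampled to the CSD grid")
    n = len(feat)
    max_lag = int(round(max_lag_ms * 1e-3 * profile.fs))
    lags_full = signal.correlation_lags(n, n, mode="full")
    keep = np.abs(lags_full) <= max_lag
    a = feat - feat.mean()
    rs, lags = [], []
    clipped = 0
    for d in range(profile.csd.shape[0]):
        b = profile.csd[d] - profile.csd[d].mean()
        cc = signal.correlate(b, a, mode="full")[keep]
        cc /= (n * a.std() * b.std()) or np.inf
        k = int(np.argmax(np.abs(cc)))
        if k in (0, keep.sum() - 1):
            clipped += 1
        rs.append(float(cc[k]))
        lags.append(lags_full[keep][k] / profile.fs * 1e3)
    if clipped:
        logger.warning("%d depths hit the ±%.0f ms lag bound", clipped,
                       max_lag_ms)
    return np.array(rs), np.array(lags)


def extract_mua(raw_by_depth: np.ndarray, fs: float,
                band=(300.0, 3000.0), envelope_lowpass: float = 200.0
                ) -> np.ndarray:
    """Multi-unit activity envelope: bandpass, full-wave rectify, low-pass.

    ``raw_by_depth`` is (depths x time) at the raw rate (>= 6 kHz for the
    default band).
    """
    arr = np.asarray(raw_by_depth, dtype=float)
    raw = np.atleast_2d(arr)
    if band[1] >= fs / 2:
        raise ValueError(f"fs={fs} too low for band {band}")
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    hp = signal.sosfiltfilt(sos, raw, axis=-1)
    rect = np.abs(hp)
    sos_lp = signal.butter(4, envelope_lowpass, btype="lowpass", fs=fs,
                           output="sos")
    env = signal.sosfiltfilt(sos_lp, rect, axis=-1)
    return env if arr.ndim == 2 else env[0]
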