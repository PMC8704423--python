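"""Bootstrap / permutation statistics for FFR significance and paired tests."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats as sps

from .recording import EpochedRecording

__all__ = ["SnrReport", "ffr_snr_and_significance", "compare_paired"]


@dataclass
class SnrReport:
    """FFR signal-to-noise ratio with its bootstrap significance."""

    snr: float  # RMS(response window) / RMS(baseline window) of the average
    p_value: float
    n_boot: int


def _rms(x: np.ndarray, axis=-1) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=axis))


def _window_slice(rec: EpochedRecording, start_ms: float, stop_ms: float):
    t = rec.times_ms
    return (t >= start_ms) & (t < stop_ms)


def ffr_snr_and_significance(rec: EpochedRecording, channel: int | str = 0,
                             response_window=(0.0, 250.0),
                             baseline_window=(-25.0, 0.0),
                             n_boot: int = 1000, seed: int = 0) -> SnrReport:
    """SNR of the averaged FFR plus a bootstrapped permutation-t significance
    test.

    SNR is the RMS ratio of the response window to the prestimulus baseline
    of the trial-averaged waveform.  Significance: the response window is cut
    into baseline-length segments so all windows share one length (RMS of a
    short window is biased low, so unequal windows would bias the test); per
    trial the paired difference between the mean response-segment RMS and
    the baseline RMS feeds a t statistic.  The null relabels which window
    counts as "baseline" within each trial (windows are exchangeable under
    stationary noise) across bootstrap resamples of trials; p is the
    fraction of null statistics at or beyond the observed one (two-sided).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable p-value")
    if response_window[0] < baseline_window[1] and \
            baseline_window[0] < response_window[1]:
        raise ValueError("windows must be disjoint")
    if baseline_window[1] > 0:
        raise ValueError("baseline window must end at or before 0 ms")
    if isinstance(channel, str):
        channel = rec.channel_index(channel)
    resp_mask = _window_slice(rec, *response_window)
    base_mask = _window_slice(rec, *baseline_window)
    x = rec.data[:, channel, :]
    avg = x.mean(axis=0)
    snr = float(_rms(avg[resp_mask]) / _rms(avg[base_mask]))

    n = x.shape[0]
    base = x[:, base_mask]
    resp = x[:, resp_mask]
    n_seg = base.shape[1]
    k = resp.shape[1] // n_seg
    if k < 1:
        raise ValueError("response window shorter than the baseline window")
    segments = resp[:, :k * n_seg].reshape(n, k, n_seg)
    # windows: baseline first, then the k response segments (all same length)
    rms_w = np.concatenate([_rms(base)[:, None], _rms(segments)], axis=1)

    def t_stat(rows: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
        take = np.take_along_axis(rows, b_idx[:, :, None], axis=2)[:, :, 0]
        d = (rows.sum(axis=2) - take) / k - take
        sd = d.std(axis=1, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return d.mean(axis=1) / (sd / np.sqrt(n))

    t_obs = float(t_stat(rms_w[None], np.zeros((1, n), dtype=int))[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    b_idx = rng.integers(0, k + 1, size=(n_boot, n))
    t_null = t_stat(rms_w[idx], b_idx)
    p = float((np.sum(np.abs(t_null) >= abs(t_obs)) + 1) / (n_boot + 1))
    return SnrReport(snr=snr, p_value=p, n_boot=n_boot)


def compare_paired(a, b, n_boot: int = 10000, seed: int = 0,
                   statistic: str = "signed_rank") -> float:
    """Two-sided sign-flip permutation test on paired samples.

    ``statistic`` is the Wilcoxon signed-rank statistic (default) or the
    paired ``t``.  For n <= 15 pairs the 2^n sign assignments are enumerated
    exactly; otherwise ``n_boot`` seeded random flips are drawn.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D paired samples")
    d = a - b
    n = len(d)
    if n < 5:
        raise ValueError("need at least 5 pairs")

    def stat(diffs: np.ndarray) -> np.ndarray:
        # diffs: (m, n)
        if statistic == "t":
            sd = diffs.std(axis=-1, ddof=1)
            sd = np.where(sd == 0, np.inf, sd)
            return diffs.mean(axis=-1) / (sd / np.sqrt(n))
        ranks = sps.rankdata(np.abs(diffs), axis=-1)
        return np.sum(np.sign(diffs) * ranks, axis=-1)

    t_obs = float(stat(d[None, :])[0])
    if n <= 15:
        signs = np.array(list(product([-1.0, 1.0], repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_boot, n))
    t_null = stat(signs * np.abs(d)[None, :])
    return float(np.mean(np.abs(t_null) >= abs(t_obs) - 1e-12))
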