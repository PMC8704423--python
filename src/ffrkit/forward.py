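"""Two-source forward model generating synthetic multi-level FFR recordings.

The model has a subcortical generator (short latency, shallow phase-locking
roll-off with frequency) and a cortical generator (longer latency, steeper
roll-off).  Each produces an envelope-following response to the stimulus F0
contour; volume conduction mixes both into scalp, cortical-surface and
laminar montages.  Laminar channels carry, for the cortical source, a
Mexican-hat depth profile centred on a "granular" depth, so the current
source density shows a sink there flanked by opposite-signed sources.
Rarefaction trials are driven by the sign-inverted stimulus: the neural
component is polarity-invariant while a cochlear-microphonic-like artifact
term flips sign, which is what polarity averaging must cancel.  Additive
noise is 1/f plus power-line harmonics; all randomness flows through one
seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .recording import ChannelMeta, EpochedRecording
from .stimuli import ToneStimulus

__all__ = ["SourceParams", "MontageChannel", "ForwardModelConfig",
           "phase_locking_gain", "source_response", "simulate_ffr_dataset",
           "default_montage", "f0_locked_bursts"]


@dataclass(frozen=True)
class SourceParams:
    """Latency and phase-locking roll-off of one generator."""

    latency_ms: float
    rolloff_knee_hz: float
    rolloff_slope_db_oct: float  # gain decline above the knee
    amp_uv: float = 1.0
    onset_amp_uv: float = 2.0  # transient at response onset


@dataclass(frozen=True)
class MontageChannel:
    """One electrode with its per-source volume-conduction weights."""

    label: str
    kind: str
    w_sub: float
    w_cort: float
    depth_um: float | None = None

    def meta(self) -> ChannelMeta:
        return ChannelMeta(self.label, self.kind, self.depth_um)


def default_montage(n_laminar: int = 16, spacing_um: float = 150.0,
                    granular_depth_um: float = 1050.0,
                    profile_sigma_um: float = 300.0) -> list[MontageChannel]:
    """Scalp (Cz, T4-like), one cortical-surface and a laminar probe.

    Subcortical weights are spatially flat on the probe (volume conduction
    from a distant generator); cortical weights follow a negative Mexican-hat
    depth profile peaked (sink-like) at the granular depth.
    """
    channels = [
        MontageChannel("Cz", "scalp", w_sub=1.0, w_cort=0.3),
        MontageChannel("T4", "scalp", w_sub=0.6, w_cort=0.8),
        MontageChannel("PAC_surface", "cortical_surface", w_sub=0.3, w_cort=2.5),
    ]
    for i in range(n_laminar):
        depth = i * spacing_um
        x = (depth - granular_depth_um) / profile_sigma_um
        hat = (1.0 - x * x) * np.exp(-0.5 * x * x)
        channels.append(MontageChannel(
            label=f"lam{i:02d}", kind="laminar",
            w_sub=0.4, w_cort=-3.0 * hat, depth_um=depth))
    return channels


@dataclass
class ForwardModelConfig:
    """Everything the simulator needs; defaults are the study conditions."""

    subcortical: SourceParams = field(default_factory=lambda: SourceParams(
        latency_ms=3.0, rolloff_knee_hz=120.0, rolloff_slope_db_oct=6.0))
    cortical: SourceParams = field(default_factory=lambda: SourceParams(
        latency_ms=15.0, rolloff_knee_hz=90.0, rolloff_slope_db_oct=18.0))
    montage: list[MontageChannel] = field(default_factory=default_montage)
    granular_depth_um: float = 1050.0
    fs: float = 2000.0  # recording rate, Hz
    t0_ms: float = -25.0
    t1_ms: float = 275.0
    n_trials: int = 100  # per polarity, per tone
    noise_rms_uv: float = 1.4  # ~0.5 single-trial SNR at Cz
    noise_exponent: float = 1.0
    line_freq_hz: float = 60.0
    line_amps_uv: tuple = (0.5, 0.25, 0.12)  # fundamental + 2 harmonics
    artifact_gain_uv: float = 0.0  # cochlear-microphonic-like, sign-flips
    n_harmonics: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.cortical.latency_ms <= self.subcortical.latency_ms:
            raise ValueError("cortical latency must exceed subcortical latency")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for ch in self.montage:
            if not (np.isfinite(ch.w_sub) and np.isfinite(ch.w_cort)):
                raise ValueError(f"non-finite mixing weight on {ch.label}")

    def source(self, name: str) -> SourceParams:
        if name == "subcortical":
            return self.subcortical
        if name == "cortical":
            return self.cortical
        raise ValueError(f"unknown source {name!r}")


def phase_locking_gain(freq_hz, source: str | SourceParams,
                       config: ForwardModelConfig | None = None):
    """Phase-locking gain in [0, 1]: unity below the source's knee, then a
    fixed dB/octave decline.  The cortical source declines faster, mirroring
    the steeper loss of phase-locking with frequency at the cortex.
    """
    if isinstance(source, str):
        source = (config or ForwardModelConfig()).source(source)
    freq_hz = np.asarray(freq_hz, dtype=float)
    if np.any(freq_hz <= 0):
        raise ValueError("freq_hz must be positive")
    octaves = np.log2(np.maximum(freq_hz / source.rolloff_knee_hz, 1.0))
    gain = 10.0 ** (-source.rolloff_slope_db_oct * octaves / 20.0)
    return gain if gain.ndim else float(gain)


def _onset_transient(n: int, fs: float, amp: float, tau_ms: float = 4.0):
    """Gamma-shaped onset deflection (unit peak scaled by ``amp``)."""
    t = np.arange(n) / fs * 1e3
    g = (t / tau_ms) * np.exp(1.0 - t / tau_ms)
    return amp * g


def source_response(stim: ToneStimulus, source: SourceParams, fs: float,
                    t0_ms: float, t1_ms: float,
                    n_harmonics: int = 8) -> np.ndarray:
    """Noiseless single-source response on the epoch time base (µV).

    A sum of F0 harmonics whose instantaneous amplitudes follow the
    phase-locking gain at the harmonic's instantaneous frequency, delayed by
    the source latency, plus a gamma-shaped onset transient.
    """
    n_epoch = int(round((t1_ms - t0_ms) * 1e-3 * fs))
    n_stim = int(round(stim.duration_s * fs))
    # resample the contour onto the recording rate
    idx = np.minimum((np.arange(n_stim) * stim.fs / fs).astype(int),
                     len(stim.f0_contour) - 1)
    f0 = stim.f0_contour[idx]
    phase = 2.0 * np.pi * np.cumsum(f0) / fs
    resp = np.zeros(n_stim)
    nyq = fs / 2.0
    for h in range(1, n_harmonics + 1):
        if h * f0.max() >= nyq:
            break
        resp += phase_locking_gain(h * f0, source) / h * np.sin(h * phase)
    resp *= source.amp_uv
    ramp_n = max(int(round(5e-3 * fs)), 1)
    ramp = np.sin(np.linspace(0, np.pi / 2, ramp_n)) ** 2
    resp[:ramp_n] *= ramp
    resp[-ramp_n:] *= ramp[::-1]
    resp += _onset_transient(n_stim, fs, source.onset_amp_uv)
    # place on the epoch time base, shifted by the source latency
    out = np.zeros(n_epoch)
    start = int(round((source.latency_ms - t0_ms) * 1e-3 * fs))
    stop = min(start + n_stim, n_epoch)
    out[start:stop] = resp[:stop - start]
    return out


def _one_over_f_noise(shape, exponent: float, rms: float,
                      fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, given RMS."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    shaped *= rms / np.sqrt(np.mean(shaped ** 2, axis=-1, keepdims=True))
    return shaped


def simulate_ffr_dataset(config: ForwardModelConfig,
                         stimuli: list[ToneStimulus]) -> EpochedRecording:
    """Simulate an epoched dataset for the given stimuli under the config.

    Each trial is ``w_sub * r_sub + w_cort * r_cort (+/- artifact) + noise``
    per channel; identical seeds give bitwise-identical outputs.
    """
    if not config.montage:
        raise ValueError("montage has no channels")
    if not stimuli:
        raise ValueError("need at least one stimulus")
    rng = np.random.default_rng(config.seed)
    fs, t0, t1 = config.fs, config.t0_ms, config.t1_ms
    n_epoch = int(round((t1 - t0) * 1e-3 * fs))
    n_ch = len(config.montage)

    data, tone_ids, polarities = [], [], []
    for stim in stimuli:
        r_sub = source_response(stim, config.subcortical, fs, t0, t1,
                                config.n_harmonics)
        r_cort = source_response(stim, config.cortical, fs, t0, t1,
                                 config.n_harmonics)
        # cochlear-microphonic-like term: stimulus waveform at the recording
        # rate, zero latency, flips sign with presentation polarity
        artifact = np.zeros(n_epoch)
        if config.artifact_gain_uv:
            n_stim = int(round(stim.duration_s * fs))
            idx = np.minimum((np.arange(n_stim) * stim.fs / fs).astype(int),
                             len(stim.waveform) - 1)
            start = int(round(-t0 * 1e-3 * fs))
            stop = min(start + n_stim, n_epoch)
            artifact[start:stop] = (config.artifact_gain_uv *
                                    stim.waveform[idx][:stop - start])
        w_sub = np.array([ch.w_sub for ch in config.montage])
        w_cort = np.array([ch.w_cort for ch in config.montage])
        clean = np.outer(w_sub, r_sub) + np.outer(w_cort, r_cort)  # ch x t
        for pol_sign, pol in ((1.0, "condensation"), (-1.0, "rarefaction")):
            base = clean + pol_sign * artifact[None, :]
            trials = np.broadcast_to(base, (config.n_trials, n_ch, n_epoch)
                                     ).copy()
            if config.noise_rms_uv > 0:
                trials += _one_over_f_noise((config.n_trials, n_ch, n_epoch),
                                            config.noise_exponent,
                                            config.noise_rms_uv, fs, rng)
            if config.line_amps_uv and any(config.line_amps_uv):
                t = np.arange(n_epoch) / fs
                for k, amp in enumerate(config.line_amps_uv, start=1):
                    f_line = k * config.line_freq_hz
                    if f_line >= fs / 2 or amp == 0:
                        continue
                    phi = rng.uniform(0, 2 * np.pi,
                                      size=(config.n_trials, n_ch, 1))
                    trials = trials + amp * np.sin(
                        2 * np.pi * f_line * t[None, None, :] + phi)
            data.append(trials)
            tone_ids.extend([stim.tone_id] * config.n_trials)
            polarities.extend([pol] * config.n_trials)

    return EpochedRecording(
        data=np.concatenate(data, axis=0), fs=fs, t0_ms=t0,
        channels=[ch.meta() for ch in config.montage],
        polarity=np.array(polarities), tone_id=np.array(tone_ids))


def f0_locked_bursts(stim: ToneStimulus, fs: float, carrier_hz: float = 1500.0,
                     burst_width_ms: float = 2.0, latency_ms: float = 13.0,
                     rng: np.random.Generator | None = None,
                     noise_rms: float = 0.0) -> np.ndarray:
    """High-rate surrogate of F0-locked multi-unit firing.

    One burst of band-limited carrier per F0 cycle, Gaussian burst envelope;
    used to exercise the MUA envelope extraction chain.
    """
    n = int(round(stim.duration_s * fs))
    idx = np.minimum((np.arange(n) * stim.fs / fs).astype(int),
                     len(stim.f0_contour) - 1)
    phase = 2.0 * np.pi * np.cumsum(stim.f0_contour[idx]) / fs
    # burst envelope peaks once per cycle (von Mises-like in phase)
    kappa = (1e3 / (2 * np.pi * burst_width_ms)) ** 2
    env = np.exp(kappa * (np.cos(phase) - 1.0))
    t = np.arange(n) / fs
    x = env * np.sin(2 * np.pi * carrier_hz * t)
    shift = int(round(latency_ms * 1e-3 * fs))
    x = np.concatenate([np.zeros(shift), x[:n - shift]])
    if noise_rms > 0:
        rng = rng or np.random.default_rng()
        x = x + noise_rms * rng.standard_normal(n)
    return x
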