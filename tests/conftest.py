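"""Shared fixtures: synthesized stimuli and simulated recordings.

Everything is generated at test time from the package's own stimulus
synthesis and forward model; sizes are kept small so the full suite runs in
minutes on one CPU.
"""

import numpy as np
import pytest

from ffrkit.forward import ForwardModelConfig, simulate_ffr_dataset
from ffrkit.stimuli import TONE_IDS, synthesize_tone


@pytest.fixture(scope="session")
def stimuli4():
    return [synthesize_tone(t) for t in TONE_IDS]


@pytest.fixture(scope="session")
def rec_default(stimuli4):
    """Default forward model, 48 trials/polarity/tone (96 per tone)."""
    cfg = ForwardModelConfig(n_trials=48, seed=11)
    return simulate_ffr_dataset(cfg, stimuli4)


@pytest.fixture(scope="session")
def rec_noiseless(stimuli4):
    """Deterministic recording: no noise, no line interference."""
    cfg = ForwardModelConfig(n_trials=2, noise_rms_uv=0.0,
                             line_amps_uv=(0.0, 0.0, 0.0), seed=5)
    return simulate_ffr_dataset(cfg, stimuli4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
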