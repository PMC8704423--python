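"""Shared plumbing for the numbered analysis drivers: one simulated dataset
(cached under scratch/) and the preprocessed version every stage consumes."""

from pathlib import Path

from ffrkit.forward import ForwardModelConfig, simulate_ffr_dataset
from ffrkit.preprocess import filter_epochs, reject_artifacts, remove_line_noise
from ffrkit.recording import load_recording, save_recording
from ffrkit.stimuli import TONE_IDS, synthesize_tone

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 11
N_TRIALS = 48  # per polarity per tone -> 96 sweeps/tone


def get_stimuli():
    return [synthesize_tone(t) for t in TONE_IDS]


def get_recording():
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / "recording"
    if cache.with_suffix(".npz").exists():
        return load_recording(cache)
    rec = simulate_ffr_dataset(ForwardModelConfig(n_trials=N_TRIALS,
                                                  seed=SEED), get_stimuli())
    save_recording(cache, rec)
    return rec


def get_clean_recording():
    rec = remove_line_noise(get_recording(), 60.0)
    rec = filter_epochs(rec, (70.0, None))
    rec, _ = reject_artifacts(rec, 75.0)
    return rec
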