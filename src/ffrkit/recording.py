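"""Epoched multi-channel recording container and its on-disk format.

An :class:`EpochedRecording` holds trials x channels x samples data (µV)
plus the metadata every analysis stage needs: channel kind (scalp /
cortical_surface / laminar), laminar depth, per-trial stimulus polarity and
tone identity, and the epoch time base.

On disk a recording is a ``.npz`` array container next to a versioned JSON
sidecar carrying the metadata (layout version ``1``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ChannelMeta", "EpochedRecording", "save_recording", "load_recording"]

CHANNEL_KINDS = ("scalp", "cortical_surface", "laminar")
POLARITIES = ("condensation", "rarefaction")

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ChannelMeta:
    """Metadata for one recorded channel."""

    label: str
    kind: str
    depth_um: float | None = None  # laminar channels only

    def __post_init__(self):
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.kind == "laminar" and self.depth_um is None:
            raise ValueError("laminar channels need a depth_um")


@dataclass
class EpochedRecording:
    """Trials x channels x samples epoched data with channel/trial metadata."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), µV
    fs: float
    t0_ms: float  # epoch start relative to stimulus onset; <= 0
    channels: list[ChannelMeta]
    polarity: np.ndarray  # str per trial
    tone_id: np.ndarray  # str per trial

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.polarity = np.asarray(self.polarity)
        self.tone_id = np.asarray(self.tone_id)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials, n_channels, _ = self.data.shape
        if len(self.channels) != n_channels:
            raise ValueError("channel metadata count mismatch")
        if len(self.polarity) != n_trials or len(self.tone_id) != n_trials:
            raise ValueError("per-trial metadata count mismatch")
        if self.t0_ms > 0:
            raise ValueError("t0_ms must be <= 0 (a prestimulus baseline exists)")
        depths = [c.depth_um for c in self.channels if c.kind == "laminar"]
        if depths and np.any(np.diff(depths) <= 0):
            raise ValueError("laminar channel depths must be strictly increasing")

    # -- convenience -----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + 1e3 * np.arange(self.data.shape[2]) / self.fs

    def channel_index(self, label: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.label == label:
                return i
        raise KeyError(label)

    def pick_trials(self, mask: np.ndarray) -> "EpochedRecording":
        mask = np.asarray(mask)
        return EpochedRecording(self.data[mask], self.fs, self.t0_ms,
                                self.channels, self.polarity[mask],
                                self.tone_id[mask])

    def pick_channels(self, indices) -> "EpochedRecording":
        indices = list(indices)
        return EpochedRecording(self.data[:, indices], self.fs, self.t0_ms,
                                [self.channels[i] for i in indices],
                                self.polarity, self.tone_id)


def save_recording(path, rec: EpochedRecording) -> None:
    """Persist a recording as ``<path>.npz`` + ``<path>.json``."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=rec.data)
    meta = {
        "format_version": _FORMAT_VERSION,
        "fs": rec.fs,
        "t0_ms": rec.t0_ms,
        "channels": [{"label": c.label, "kind": c.kind, "depth_um": c.depth_um}
                     for c in rec.channels],
        "polarity": rec.polarity.tolist(),
        "tone_id": rec.tone_id.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_recording(path) -> EpochedRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["format_version"] != _FORMAT_VERSION:
        raise ValueError(f"unsupported container version {meta['format_version']}")
    data = np.load(path.with_suffix(".npz"))["data"]
    channels = [ChannelMeta(c["label"], c["kind"], c["depth_um"])
                for c in meta["channels"]]
    return EpochedRecording(data, meta["fs"], meta["t0_ms"], channels,
                            np.array(meta["polarity"]), np.array(meta["tone_id"]))
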