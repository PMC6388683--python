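"""In-memory containers shared across the pipeline: continuous recordings,
epoch sets and averaged ERP waveforms, with their on-disk formats (EDF + TSV
event sidecar for continuous data, HDF5 with a JSON metadata attribute for
epochs)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import edf

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "ERPWaveform",
    "VEOG_LABELS",
    "write_recording",
    "read_recording",
]

VEOG_LABELS = ("VEOGL", "VEOGR")


@dataclass
class ContinuousRecording:
    """Continuous multi-channel signal (EEG + VEOG) with event markers."""

    labels: tuple[str, ...]
    data: np.ndarray  # channels x samples, relative uV
    fs: float
    events: tuple[tuple[int, str], ...] = ()
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.events = tuple((int(s), str(lab)) for s, lab in self.events)
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        n = self.data.shape[1]
        for sample, label in self.events:
            if not 0 <= sample < n:
                raise ValueError(f"event {label!r} at sample {sample} outside record [0, {n})")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def eeg_indices(self) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab not in VEOG_LABELS]

    def veog_indices(self) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab in VEOG_LABELS]


def write_recording(recording: ContinuousRecording, path: str | Path) -> tuple[Path, Path]:
    """EDF signal file plus TSV event sidecar (onset_sample, duration, label)."""
    path = Path(path)
    edf_path = path if path.suffix == ".edf" else path.with_suffix(".edf")
    events_path = edf_path.with_suffix(".events.tsv")
    edf.write_edf(edf_path, recording.data, recording.fs, list(recording.labels))
    frame = pd.DataFrame(
        {
            "onset_sample": [s for s, _ in recording.events],
            "duration": [0 for _ in recording.events],
            "label": [lab for _, lab in recording.events],
        }
    )
    frame.to_csv(events_path, sep="\t", index=False)
    return edf_path, events_path


def read_recording(path: str | Path) -> ContinuousRecording:
    path = Path(path)
    edf_path = path if path.suffix == ".edf" else path.with_suffix(".edf")
    signals, fs, labels = edf.read_edf(edf_path)
    events_path = edf_path.with_suffix(".events.tsv")
    events: tuple[tuple[int, str], ...] = ()
    if events_path.exists():
        frame = pd.read_csv(events_path, sep="\t")
        if len(frame):
            events = tuple(
                (int(row.onset_sample), str(row.label)) for row in frame.itertuples()
            )
    return ContinuousRecording(labels=tuple(labels), data=signals, fs=fs, events=events)


@dataclass
class EpochSet:
    """Stimulus-locked trials: trials x channels x samples.

    The time axis spans the half-open window [-200, 1000) ms by default with
    t = 0 at the stimulus sample; baseline samples are those with t < 0.
    """

    data: np.ndarray
    times: np.ndarray  # ms
    channels: tuple[str, ...]
    conditions: tuple[str, ...]
    fs: float
    subject: str = "sim"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = tuple(self.channels)
        self.conditions = tuple(self.conditions)
        if self.data.ndim != 3:
            raise ValueError(f"epoch data must be trials x channels x samples, got {self.data.shape}")
        n_trials, n_channels, n_samples = self.data.shape
        if n_channels != len(self.channels):
            raise ValueError(f"{len(self.channels)} channel labels for {n_channels} channels")
        if len(self.conditions) != n_trials:
            raise ValueError(f"{len(self.conditions)} condition labels for {n_trials} trials")
        if self.times.shape != (n_samples,):
            raise ValueError("time axis length must match the sample axis")
        if not (self.times.min() < 0 <= self.times.max()):
            raise ValueError("time axis must include 0 (stimulus) with baseline samples before it")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def baseline_mask(self) -> np.ndarray:
        return self.times < 0

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present in {self.channels}") from None

    def copy_with(self, **changes) -> "EpochSet":
        return replace(self, **changes)

    def to_hdf5(self, path: str | Path) -> None:
        meta = {
            "channels": list(self.channels),
            "conditions": list(self.conditions),
            "fs": self.fs,
            "subject": self.subject,
        }
        with h5py.File(path, "w") as handle:
            handle.create_dataset("data", data=self.data)
            handle.create_dataset("times", data=self.times)
            handle.attrs["metadata"] = json.dumps(meta, sort_keys=True)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EpochSet":
        with h5py.File(path, "r") as handle:
            data = handle["data"][()]
            times = handle["times"][()]
            meta = json.loads(handle.attrs["metadata"])
        return cls(
            data=data,
            times=times,
            channels=tuple(meta["channels"]),
            conditions=tuple(meta["conditions"]),
            fs=meta["fs"],
            subject=meta["subject"],
        )


@dataclass
class ERPWaveform:
    """Across-trial (or across-subject) mean amplitude, channels x samples."""

    data: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    n: int
    condition: str = "all"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        self.channels = tuple(self.channels)
        if self.n < 1:
            raise ValueError("an average must contain at least one contributor")
        if self.data.shape != (len(self.channels), self.times.size):
            raise ValueError(
                f"waveform shape {self.data.shape} does not match "
                f"{len(self.channels)} channels x {self.times.size} samples"
            )

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present in {self.channels}") from None
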