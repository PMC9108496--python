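"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

HVA = "HVA"
LVA = "LVA"
CLASSES = (HVA, LVA)


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class Event:
    """A stimulation-onset marker on a continuous recording."""

    sample: int
    label: str
    trial_index: int


@dataclass
class EEGRecording:
    """Continuous multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    events: list[Event] = field(default_factory=list)
    subject_id: int | None = None
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = tuple(self.labels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ConfigurationError(
                f"data has {self.data.shape[0] if self.data.ndim == 2 else '?'} rows "
                f"but {len(self.labels)} channel labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("channel labels must be unique")
        for ev in self.events:
            if not 0 <= ev.sample < self.data.shape[1]:
                raise ConfigurationError(f"event sample {ev.sample} out of bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def get_channels(self, labels: Sequence[str]) -> np.ndarray:
        return self.data[[self.channel_index(lb) for lb in labels]]

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(
            data=data,
            fs=self.fs,
            labels=self.labels,
            events=list(self.events),
            subject_id=self.subject_id,
            aux=dict(self.aux),
        )


@dataclass
class TrialSegment:
    """One labeled stimulation epoch plus its pre-stimulus baseline window."""

    data: np.ndarray
    baseline: np.ndarray
    label: str
    subject_id: int | None
    trial_index: int
    fs: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if self.label not in CLASSES:
            raise ConfigurationError(f"unknown class label {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in segment") from None

    def get_channels(self, labels: Sequence[str]) -> np.ndarray:
        return self.data[[self.channel_index(lb) for lb in labels]]


@dataclass
class SampleMatrix:
    """A channels x points window of EEG, the pre-encoding image source."""

    X: np.ndarray
    label: str
    subject_id: int | None = None
    trial_index: int | None = None
    second: int | None = None
    channels: tuple[str, ...] | None = None


@dataclass
class ImageSample:
    """A pixel-scaled channels x points image in [0, 255], the classifier input."""

    Y: np.ndarray
    label: str
    subject_id: int | None = None
    trial_index: int | None = None
    second: int | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        if self.Y.min(initial=0) < 0 or self.Y.max(initial=0) > 255:
            raise ValueError("pixels must lie in [0, 255]")

    @property
    def planes(self) -> np.ndarray:
        """Grayscale image replicated into 3 identical planes (RGB form)."""
        return np.repeat(self.Y[np.newaxis].astype(np.float64), 3, axis=0)


@dataclass
class CoherenceMatrix:
    """Symmetric per-trial channel x channel band-averaged coherence."""

    values: np.ndarray
    channels: tuple[str, ...]
    band: tuple[float, float]
    trial_index: int
    subject_id: int | None
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.channels = tuple(self.channels)
        n = len(self.channels)
        if self.values.shape != (n, n):
            raise ValueError("coherence matrix shape does not match channel count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("coherence matrix must be symmetric")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("off-diagonal coherence must lie in [0, 1]")

    def upper_triangle(self) -> np.ndarray:
        """The unique off-diagonal coherence values (upper triangle, row order)."""
        n = len(self.channels)
        iu = np.triu_indices(n, k=1)
        return self.values[iu]


@dataclass
class ConfusionCounts:
    """Binary confusion-matrix counts with HVA as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Percentage metrics derived from confusion counts.

    A metric whose defining ratio has a zero denominator is reported as None
    (undefined), never as zero.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
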