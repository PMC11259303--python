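"""In-memory containers for continuous EEG and fixed-width epochs.

All signal data is stored as ``float64`` in microvolts, shaped
``(n_channels, n_samples)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np


@dataclass
class EEGRecording:
    """A continuous multi-channel EEG signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        10-20 system labels, one per row of ``data``; must be unique.
    start_time_s : float
        Time of the first sample relative to the recording origin.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.fs

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(),
                       channel_names=list(self.channel_names))


@dataclass
class Epoch:
    """A fixed-width labelled EEG window.

    ``origin`` records provenance as ``(subject_id, video_id, offset_s)``.
    ``label`` is 0 (normal) / 1 (sickness) when known; ``target`` is an
    optional regression target on the normalized SSQ scale [0, 1].
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    label: int | None = None
    origin: tuple[int, int, float] | None = None
    target: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def window_s(self) -> float:
        return self.n_samples / self.fs

    def as_recording(self) -> EEGRecording:
        offset = self.origin[2] if self.origin is not None else 0.0
        return EEGRecording(self.data.copy(), self.fs,
                            list(self.channel_names), start_time_s=offset)


@dataclass
class EpochSet:
    """An ordered collection of epochs sharing fs and channel layout."""

    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epochs:
            fs = self.epochs[0].fs
            names = self.epochs[0].channel_names
            ns = self.epochs[0].n_samples
            for ep in self.epochs:
                if ep.fs != fs or ep.channel_names != names or ep.n_samples != ns:
                    raise ValueError("epochs must share fs, channels and length")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return EpochSet(self.epochs[i])
        return self.epochs[i]

    def extend(self, other: "EpochSet") -> None:
        EpochSet(self.epochs + other.epochs)  # re-validate compatibility
        self.epochs.extend(other.epochs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([-1 if ep.label is None else ep.label
                         for ep in self.epochs], dtype=int)

    @property
    def targets(self) -> np.ndarray:
        return np.array([np.nan if ep.target is None else ep.target
                         for ep in self.epochs], dtype=float)

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([-1 if ep.origin is None else ep.origin[0]
                         for ep in self.epochs], dtype=int)

    @property
    def video_ids(self) -> np.ndarray:
        return np.array([-1 if ep.origin is None else ep.origin[1]
                         for ep in self.epochs], dtype=int)

    def stack(self) -> np.ndarray:
        """Return all epoch data as ``(n_epochs, n_channels, n_samples)``."""
        return np.stack([ep.data for ep in self.epochs])


def check_channel_subset(names: Sequence[str], available: Sequence[str]) -> None:
    missing = [n for n in names if n not in available]
    if missing:
        raise KeyError(f"channels not present: {', '.join(missing)}")
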