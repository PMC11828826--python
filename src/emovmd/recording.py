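"""The in-memory container for a labeled multichannel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

#: Label used for samples that carry no emotion condition.
RELAX = "relax"

#: Label used when a recording is loaded without an events sidecar.
UNKNOWN = "unknown"


@dataclass
class Recording:
    """Channels x samples sample matrix (µV) with a per-sample label timeline.

    ``labels`` holds one class string per sample (``"relax"`` or an emotion
    name); ``data.shape == (len(channel_names), len(labels))``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 2:
            raise ConfigurationError("data must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} rows"
            )
        if self.labels.shape[0] != self.data.shape[1]:
            raise ConfigurationError("label array length must equal sample count")
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with a new sample matrix (same shape)."""
        if data.shape != self.data.shape:
            raise ConfigurationError("replacement data must preserve shape")
        return replace(self, data=np.asarray(data, dtype=float))

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(f"channel {name!r} not in recording") from None


def label_segments(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Contiguous runs of equal labels as half-open (start, end, label) spans."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(s), int(e), str(labels[s])) for s, e in zip(starts, ends)]
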