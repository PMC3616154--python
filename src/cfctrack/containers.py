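"""In-memory containers shared across the pipeline stages.

A :class:`TimeSeries` is a uniformly sampled real- or complex-valued signal
with a sampling rate and a time origin.  An :class:`EpochSet` is a balanced
collection of fixed-length multichannel trials labelled by subject, condition
and trial index, as produced by event-related EEG experiments (and by the
synthetic group-dataset generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["TimeSeries", "Epoch", "EpochSet"]


@dataclass
class TimeSeries:
    """Uniformly sampled signal.

    Parameters
    ----------
    data : ndarray, shape (n_samples,) or (n_samples, n_channels)
        Sample values.  Real or complex.
    fs : float
        Sampling rate in Hz.  Signals defined in normalized frequency
        (cycles/sample) use ``fs=1.0``.
    t0_ms : float
        Time of the first sample, in epoch-relative milliseconds.
    labels : tuple of str, optional
        Channel labels for multichannel data.
    """

    data: np.ndarray
    fs: float
    t0_ms: float = 0.0
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (1, 2):
            raise ValueError("data must be 1-D or 2-D (samples x channels)")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be a positive finite number, got {self.fs}")
        if self.labels is not None:
            self.labels = tuple(self.labels)
            if self.data.ndim != 2 or len(self.labels) != self.data.shape[1]:
                raise ValueError("labels must match the number of channels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 1 else self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) / self.fs * 1000.0

    def channel(self, label: str) -> "TimeSeries":
        """Extract a single channel by label."""
        if self.labels is None or label not in self.labels:
            raise KeyError(f"unknown channel label: {label!r}")
        j = self.labels.index(label)
        return TimeSeries(self.data[:, j], self.fs, self.t0_ms)

    def with_data(self, data: np.ndarray, **kw) -> "TimeSeries":
        """Copy of this series with new sample values (same fs/t0 unless overridden)."""
        out = replace(self, data=np.asarray(data))
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class Epoch:
    """One trial: a fixed-length multichannel segment with its labels."""

    subject: str
    condition: str
    trial: int
    data: np.ndarray  # (n_samples, n_channels)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (samples x channels)")


@dataclass
class EpochSet:
    """Balanced collection of trials sharing fs, length and channel labels.

    ``onset_ms`` is the stimulus-onset time relative to the start of each
    epoch (the event-related convention: a 2000 ms trial with onset at
    500 ms has 500 ms of pre-stimulus baseline).
    """

    epochs: list[Epoch]
    fs: float
    channel_labels: tuple[str, ...]
    onset_ms: float = 500.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        if not self.epochs:
            raise ValueError("EpochSet requires at least one epoch")
        n0 = self.epochs[0].data.shape[0]
        for ep in self.epochs:
            if ep.data.shape != (n0, len(self.channel_labels)):
                raise ValueError(
                    "all epochs must share length and channel count; "
                    f"got {ep.data.shape} vs ({n0}, {len(self.channel_labels)})"
                )
        if not (0 <= self.onset_ms <= n0 / self.fs * 1000.0):
            raise ValueError("stimulus onset must lie within the epoch span")

    @property
    def n_samples(self) -> int:
        return self.epochs[0].data.shape[0]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for ep in self.epochs:
            seen.setdefault(ep.subject, None)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for ep in self.epochs:
            seen.setdefault(ep.condition, None)
        return list(seen)

    def select(self, subject: str | None = None, condition: str | None = None) -> list[Epoch]:
        out = []
        for ep in self.epochs:
            if subject is not None and ep.subject != subject:
                continue
            if condition is not None and ep.condition != condition:
                continue
            out.append(ep)
        return out

    def channel_index(self, label: str) -> int:
        if label not in self.channel_labels:
            raise KeyError(f"unknown channel label: {label!r}")
        return self.channel_labels.index(label)
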