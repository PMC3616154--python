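"""Front-end conditioning: resampling, notch, spatial averaging, filter bank.

All filters are applied forward and reverse (zero-phase), so band-limited
features are not delayed relative to the raw signal.  Samples near the epoch
borders remain susceptible to filter transients; mirror padding of the head
is provided for initializing the adaptive tracker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import TimeSeries

__all__ = [
    "BandDefinition",
    "FilterBankConfig",
    "DEFAULT_BANDS",
    "resample_to",
    "notch",
    "spatial_average",
    "bandpass",
    "bandpass_bank",
    "mirror_pad_head",
    "trim_head",
]


@dataclass(frozen=True)
class BandDefinition:
    """A fixed analysis band [f_lo, f_hi] in Hz."""

    f_lo: float
    f_hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"require 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")
        if not self.label:
            object.__setattr__(self, "label", f"{self.f_lo:g}-{self.f_hi:g} Hz")

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    def validate_at(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(f"band {self.label} exceeds Nyquist at fs={fs} Hz")


#: The eight fixed EEG analysis bands used throughout.
DEFAULT_BANDS: tuple[BandDefinition, ...] = tuple(
    BandDefinition(lo, hi)
    for lo, hi in [(1, 4), (4, 8), (8, 12), (15, 25), (35, 45), (45, 55), (55, 65), (65, 75)]
)


@dataclass(frozen=True)
class FilterBankConfig:
    """Band-pass bank design: Butterworth order (per side) and zero-phase flag.

    ``order`` is the scipy Butterworth prototype order; the resulting
    band-pass has twice that many poles, and forward-reverse application
    doubles the attenuation in dB again.
    """

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("filter bank requires at least one band")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def resample_to(ts: TimeSeries, target_fs: float) -> TimeSeries:
    """Anti-aliased rate reduction to ``target_fs`` (polyphase FIR).

    Upsampling is rejected: the pipeline only ever reduces the rate
    (e.g. 500 Hz recordings to 250 Hz).
    """
    if target_fs > ts.fs:
        raise ValueError(f"upsampling not supported ({ts.fs} -> {target_fs} Hz)")
    if target_fs == ts.fs:
        return ts.with_data(ts.data.copy())
    frac = Fraction(target_fs / ts.fs).limit_denominator(1000)
    out = signal.resample_poly(ts.data, frac.numerator, frac.denominator, axis=0, padtype="line")
    return TimeSeries(out, fs=target_fs, t0_ms=ts.t0_ms, labels=ts.labels)


def notch(ts: TimeSeries, f0: float, bandwidth_hz: float = 1.0) -> TimeSeries:
    """Zero-phase second-order IIR notch at ``f0`` Hz (power-line removal).

    ``bandwidth_hz`` is the −3 dB width of a single pass; the forward-reverse
    application narrows it slightly and doubles the attenuation in dB.
    """
    if not (0 < f0 < ts.fs / 2):
        raise ValueError(f"notch frequency {f0} Hz outside (0, Nyquist)")
    b, a = signal.iirnotch(f0, Q=f0 / bandwidth_hz, fs=ts.fs)
    out = signal.filtfilt(b, a, ts.data, axis=0)
    return ts.with_data(out)


def spatial_average(ts: TimeSeries, subset: list[str] | tuple[str, ...]) -> TimeSeries:
    """Per-sample arithmetic mean over a subset of channels (e.g. a posterior
    electrode cluster)."""
    if not subset:
        raise ValueError("channel subset must be non-empty")
    if ts.labels is None:
        raise ValueError("spatial_average requires labelled multichannel data")
    idx = []
    for lab in subset:
        if lab not in ts.labels:
            raise KeyError(f"unknown channel label: {lab!r}")
        idx.append(ts.labels.index(lab))
    return TimeSeries(ts.data[:, idx].mean(axis=1), fs=ts.fs, t0_ms=ts.t0_ms)


def _band_sos(band: BandDefinition, fs: float, order: int) -> np.ndarray:
    band.validate_at(fs)
    return signal.butter(order, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass(ts: TimeSeries, band: BandDefinition, cfg: FilterBankConfig | None = None) -> TimeSeries:
    """Zero-phase Butterworth band-pass of one series into one band."""
    cfg = cfg or FilterBankConfig(bands=(band,))
    sos = _band_sos(band, ts.fs, cfg.order)
    if cfg.zero_phase:
        out = signal.sosfiltfilt(sos, ts.data, axis=0)
    else:
        out = signal.sosfilt(sos, ts.data, axis=0)
    return ts.with_data(out)


def bandpass_bank(ts: TimeSeries, cfg: FilterBankConfig | None = None) -> dict[str, TimeSeries]:
    """Apply every band of the bank; returns ``{band label: filtered series}``."""
    cfg = cfg or FilterBankConfig()
    return {band.label: bandpass(ts, band, cfg) for band in cfg.bands}


def mirror_pad_head(ts: TimeSeries, duration_ms: float = 500.0) -> tuple[TimeSeries, int]:
    """Prepend the time-reversed head of the signal (tracker burn-in).

    The reflection excludes the boundary sample: with ``n_pad`` padded
    samples the prefix is ``x[1..n_pad]`` reversed, so no sample is
    duplicated at the seam.  Returns the padded series and ``n_pad`` for
    later trimming with :func:`trim_head`.
    """
    n_pad = int(round(duration_ms * ts.fs / 1000.0))
    if n_pad < 0 or n_pad + 1 > ts.n_samples:
        raise ValueError(
            f"pad duration {duration_ms} ms needs {n_pad + 1} samples, "
            f"signal has {ts.n_samples}"
        )
    if n_pad == 0:
        return ts.with_data(ts.data.copy()), 0
    prefix = ts.data[1 : n_pad + 1][::-1]
    out = np.concatenate([prefix, ts.data], axis=0)
    return TimeSeries(out, fs=ts.fs, t0_ms=ts.t0_ms - n_pad / ts.fs * 1000.0, labels=ts.labels), n_pad


def trim_head(ts: TimeSeries, n_pad: int) -> TimeSeries:
    """Drop the first ``n_pad`` samples (inverse of :func:`mirror_pad_head`)."""
    if n_pad == 0:
        return ts
    return TimeSeries(ts.data[n_pad:], fs=ts.fs, t0_ms=ts.t0_ms + n_pad / ts.fs * 1000.0, labels=ts.labels)
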