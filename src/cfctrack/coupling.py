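"""Phase/amplitude extraction and phase-locking statistics over sliding windows.

Two coupling measures are computed, both phase-locking values (PLV):

* phase–amplitude (PA): locking between the phase of a low-frequency
  component and the phase of the amplitude envelope of a high-frequency
  component, ``PLV = |mean exp(j(φ_low − φ_ampHigh))|``;
* n:m phase–phase (PP): ``PLV = |mean exp(j(n·φ_low − m·φ_high))|``, the
  integer coefficients letting oscillations at different frequencies be
  compared (e.g. 7:1 for a frequency ratio of 7).

The expectation is replaced by the sample mean over the samples of a
sliding window, pooled across a subject's trials.  An (n, m) pair is only
meaningful for a band pair when the bands overlap once multiplied by the
coefficients; :func:`valid_coefficients` encodes that rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .containers import EpochSet, TimeSeries
from .preprocessing import BandDefinition, bandpass
from .sft import TrackedComponent

__all__ = [
    "COEFFICIENT_GRID",
    "CouplingSpec",
    "WindowGrid",
    "Window",
    "WindowedFeatures",
    "instantaneous_phase",
    "amplitude_envelope",
    "envelope_phase",
    "plv",
    "pa_plv",
    "pp_plv",
    "valid_coefficients",
    "make_windows",
    "windowed_features",
]

#: The n:m coefficient pairs examined (n multiplies the low-frequency phase).
COEFFICIENT_GRID: tuple[tuple[int, int], ...] = (
    (4, 3), (3, 2), (2, 1), (3, 1), (4, 1), (5, 1), (6, 1), (7, 1), (8, 1), (9, 1),
)


def valid_coefficients(band_low: BandDefinition, band_high: BandDefinition, n: int, m: int) -> bool:
    """Whether an (n, m) pair makes sense for a band pair.

    True iff the intervals [n·f_lo_low, n·f_hi_low] and
    [m·f_lo_high, m·f_hi_high] overlap with positive length (touching
    endpoints do not count).
    """
    if n < 1 or m < 1:
        raise ValueError("coupling coefficients must be positive integers")
    lo = max(n * band_low.f_lo, m * band_high.f_lo)
    hi = min(n * band_low.f_hi, m * band_high.f_hi)
    return hi - lo > 0


@dataclass(frozen=True)
class CouplingSpec:
    """One coupling to measure between a low and a high band.

    ``kind`` is ``"phase_amplitude"`` or ``"phase_phase"``; the n:m
    coefficients apply to phase_phase only (n on the low-band phase).
    """

    band_low: BandDefinition
    band_high: BandDefinition
    kind: str = "phase_phase"
    n: int = 1
    m: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("phase_amplitude", "phase_phase"):
            raise ValueError(f"unknown coupling kind: {self.kind!r}")
        if self.kind == "phase_phase" and not valid_coefficients(
            self.band_low, self.band_high, self.n, self.m
        ):
            raise ValueError(
                f"coefficients {self.n}:{self.m} invalid for bands "
                f"{self.band_low.label} / {self.band_high.label}"
            )

    @property
    def label(self) -> str:
        if self.kind == "phase_amplitude":
            return f"PA {self.band_low.label} / {self.band_high.label}"
        return f"PP {self.band_low.label} / {self.band_high.label} {self.n}:{self.m}"


@dataclass(frozen=True)
class Window:
    """A sliding window: sample slice plus its centre time."""

    start: int
    stop: int
    center_ms: float
    inside: bool = True

    @property
    def sl(self) -> slice:
        return slice(self.start, self.stop)

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window geometry: 300 ms windows shifted by 10 ms by default."""

    win_ms: float = 300.0
    shift_ms: float = 10.0
    fs: float = 250.0

    def __post_init__(self) -> None:
        if self.win_ms <= 0 or self.shift_ms <= 0:
            raise ValueError("window length and shift must be positive")

    @property
    def n_win_samples(self) -> int:
        return int(round(self.win_ms * self.fs / 1000.0))


def make_windows(
    span_ms: float,
    grid: WindowGrid,
    onset_ms: float = 0.0,
    center_interval_ms: tuple[float, float] | None = None,
) -> list[Window]:
    """Build the ordered window list for an epoch of ``span_ms``.

    Centres are expressed relative to ``onset_ms`` (stimulus time).  With
    ``center_interval_ms`` given, centres run from its start to its end in
    steps of ``grid.shift_ms`` (e.g. (0, 1000) at a 10 ms shift yields 101
    windows); otherwise every window fully inside the epoch is returned.
    Windows that would extend past the epoch edges are marked
    ``inside=False`` and clipped out of the returned list only when no
    explicit interval was requested.
    """
    n_total = int(round(span_ms * grid.fs / 1000.0))
    n_win = grid.n_win_samples
    if n_win > n_total:
        raise ValueError("window longer than the epoch span")
    half_lo = n_win // 2
    half_hi = n_win - half_lo
    if center_interval_ms is None:
        first = half_lo / grid.fs * 1000.0 - onset_ms
        last = (n_total - half_hi) / grid.fs * 1000.0 - onset_ms
        n_steps = int(math.floor((last - first) / grid.shift_ms + 1e-9))
        centers = first + grid.shift_ms * np.arange(n_steps + 1)
    else:
        c0, c1 = center_interval_ms
        n_steps = int(round((c1 - c0) / grid.shift_ms))
        centers = c0 + grid.shift_ms * np.arange(n_steps + 1)
    out: list[Window] = []
    for c in centers:
        c_samp = int(round((onset_ms + c) * grid.fs / 1000.0))
        start, stop = c_samp - half_lo, c_samp + half_hi
        inside = start >= 0 and stop <= n_total
        if not inside and center_interval_ms is None:
            continue
        out.append(Window(start, stop, float(c), inside))
    return out


def instantaneous_phase(x, unwrap: bool = False) -> np.ndarray:
    """Phase via the Hilbert transform (or the argument of a complex input).

    Output lies in (−π, π]; pass ``unwrap=True`` for a continuous phase.
    """
    if isinstance(x, TrackedComponent):
        data = x.y
    else:
        data = x.data if isinstance(x, TimeSeries) else np.asarray(x)
    if not np.any(data):
        raise ValueError("phase undefined for an all-zero signal")
    if not np.iscomplexobj(data):
        data = hilbert(np.asarray(data, dtype=float), axis=0)
    ph = np.angle(data)
    return np.unwrap(ph, axis=0) if unwrap else ph


def amplitude_envelope(x) -> np.ndarray:
    """Analytic-signal magnitude (nonnegative amplitude envelope)."""
    if isinstance(x, TrackedComponent):
        return np.abs(x.y)
    data = x.data if isinstance(x, TimeSeries) else np.asarray(x)
    if not np.iscomplexobj(data):
        data = hilbert(np.asarray(data, dtype=float), axis=0)
    return np.abs(data)


def envelope_phase(
    high,
    fs: float | None = None,
    low_band: BandDefinition | None = None,
    mode: str = "band_filtered",
) -> np.ndarray:
    """Phase of the amplitude envelope of the high-frequency component.

    With ``mode="band_filtered"`` (default) the envelope is mean-removed
    and band-passed to the low component's band before phase extraction,
    so the PA measure picks up envelope fluctuations at the modulating
    rhythm only; ``mode="raw"`` keeps the literal phase of the mean-removed
    envelope.
    """
    env = amplitude_envelope(high)
    if isinstance(high, (TimeSeries,)):
        fs = high.fs
    elif isinstance(high, TrackedComponent):
        fs = high.fs
    if np.ptp(env) < 1e-12 * max(1.0, np.max(np.abs(env))):
        raise ValueError("degenerate (constant) amplitude envelope; PA phase undefined")
    env = env - env.mean()
    if mode == "band_filtered":
        if low_band is None or fs is None:
            raise ValueError("band_filtered envelope phase requires fs and low_band")
        env = bandpass(TimeSeries(env, fs=fs), low_band).data
    elif mode != "raw":
        raise ValueError(f"unknown envelope phase mode: {mode!r}")
    return np.angle(hilbert(env))


def plv(angle_diff: np.ndarray, windows=None) -> np.ndarray | float:
    """Resultant length of unit phasors of a phase-difference series.

    With ``windows`` (list of :class:`Window`) returns one PLV per window
    computed over that window's samples; otherwise a single PLV over the
    whole series.  ``angle_diff`` may be 2-D (samples x trials); samples
    are then pooled across trials within each window.
    """
    z = np.exp(1j * np.asarray(angle_diff))
    if windows is None:
        return float(np.abs(z.mean()))
    # cumulative sums give O(1) per-window sums over the sample axis
    flat = z.reshape(z.shape[0], -1)
    csum = np.vstack([np.zeros((1, flat.shape[1]), complex), np.cumsum(flat, axis=0)])
    out = np.empty(len(windows))
    for i, w in enumerate(windows):
        seg = csum[w.stop] - csum[w.start]
        out[i] = np.abs(seg.sum()) / (w.n_samples * flat.shape[1])
    return out


def pa_plv(
    low,
    high,
    windows=None,
    fs: float | None = None,
    low_band: BandDefinition | None = None,
    envelope_mode: str = "band_filtered",
):
    """Phase–amplitude PLV between a low component and the envelope phase of
    a high component, per window (or over the full overlap if no windows)."""
    phi_low = instantaneous_phase(low)
    phi_env = envelope_phase(high, fs=fs, low_band=low_band, mode=envelope_mode)
    if phi_low.shape != phi_env.shape:
        raise ValueError("low and high series must cover the same samples")
    return plv(phi_low - phi_env, windows)


def pp_plv(phase1: np.ndarray, phase2: np.ndarray, n: int, m: int, windows=None):
    """n:m phase–phase PLV: ``|mean exp(j(n·φ₁ − m·φ₂))|`` per window."""
    if n < 1 or m < 1:
        raise ValueError("coupling coefficients must be positive integers")
    phase1 = np.asarray(phase1)
    phase2 = np.asarray(phase2)
    if phase1.shape != phase2.shape:
        raise ValueError("phase series must have equal shape")
    return plv(n * phase1 - m * phase2, windows)


@dataclass
class WindowedFeatures:
    """One feature laid out window x subject x group (balanced, 2 groups)."""

    values: np.ndarray  # (n_windows, n_subjects, 2)
    feature: str
    window_centers_ms: np.ndarray
    subjects: list[str]
    groups: tuple[str, str]
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 2:
            raise ValueError("values must be (windows, subjects, 2)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("balanced design requires no missing cells")

    def to_frame(self) -> pd.DataFrame:
        w, s, g = np.meshgrid(
            np.arange(self.values.shape[0]),
            np.arange(self.values.shape[1]),
            np.arange(2),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "window_center_ms": self.window_centers_ms[w.ravel()],
                "subject": np.asarray(self.subjects)[s.ravel()],
                "group": np.asarray(self.groups)[g.ravel()],
                "feature": self.feature,
                "value": self.values.ravel(),
            }
        )


def _epoch_phase_env(
    epochs,
    ch_low: int,
    ch_high: int,
    fs: float,
    env_bands: list[BandDefinition | None],
    tracked: dict | None,
    envelope_mode: str,
):
    """Per-trial low/high phases plus one envelope-phase array per requested
    envelope filtering band (None = raw mean-removed envelope)."""
    phis_low, phis_high, omegas = [], [], {}
    envs = []
    for ep in epochs:
        if tracked is not None:
            tc_low: TrackedComponent = tracked[(id(ep), ch_low)]
            tc_high: TrackedComponent = tracked[(id(ep), ch_high)]
            low_y, high_y = tc_low.y, tc_high.y
            omegas.setdefault("low", []).append(tc_low.omega)
            omegas.setdefault("high", []).append(tc_high.omega)
        else:
            low_y = hilbert(ep.data[:, ch_low])
            high_y = hilbert(ep.data[:, ch_high])
        phis_low.append(np.angle(low_y))
        phis_high.append(np.angle(high_y))
        envs.append(np.abs(high_y) - np.abs(high_y).mean())
    phi_env: dict = {}
    for band in env_bands:
        cols = []
        for env in envs:
            e = env
            if envelope_mode == "band_filtered" and band is not None:
                e = bandpass(TimeSeries(e, fs=fs), band).data
            cols.append(np.angle(hilbert(e)))
        key = band.label if band is not None else None
        phi_env[key] = np.column_stack(cols)
    return (
        np.column_stack(phis_low),
        np.column_stack(phis_high),
        phi_env,
        omegas,
    )


def windowed_features(
    dataset: EpochSet,
    specs: list[CouplingSpec],
    windows: list[Window],
    *,
    channel_low: str = "low",
    channel_high: str = "high",
    tracked: dict | None = None,
    include_frequency: bool = False,
    frequency_channel: str = "low",
    envelope_mode: str = "band_filtered",
) -> dict[str, WindowedFeatures]:
    """Per-window, per-subject, per-condition feature matrices.

    For PLV features the sample mean is pooled over all window samples of a
    subject's trials in that condition.  ``tracked`` maps
    ``(id(epoch), channel_index) -> TrackedComponent``; when given, phases
    and envelopes come from the tracked components, and the mean
    instantaneous frequency becomes available (``include_frequency``) —
    requesting it without tracking is an error, as the fixed-filter path
    has no frequency estimate.
    """
    if include_frequency and tracked is None:
        raise ValueError("mean instantaneous frequency requires the tracking path")
    subjects = dataset.subjects
    conditions = dataset.conditions
    if len(conditions) != 2:
        raise ValueError("windowed_features expects exactly two conditions")
    ch_low = dataset.channel_index(channel_low)
    ch_high = dataset.channel_index(channel_high)
    centers = np.array([w.center_ms for w in windows])
    out: dict[str, WindowedFeatures] = {}
    buffers = {spec.label: np.empty((len(windows), len(subjects), 2)) for spec in specs}
    if include_frequency:
        buffers["mean_frequency"] = np.empty((len(windows), len(subjects), 2))
    for si, subj in enumerate(subjects):
        for gi, cond in enumerate(conditions):
            eps = dataset.select(subject=subj, condition=cond)
            if not eps:
                raise ValueError(f"no epochs for subject {subj!r} condition {cond!r}")
            env_bands = []
            for spec in specs:
                if spec.kind == "phase_amplitude":
                    band = spec.band_low if envelope_mode == "band_filtered" else None
                    if band not in env_bands:
                        env_bands.append(band)
            phi_l, phi_h, phi_e, omegas = _epoch_phase_env(
                eps, ch_low, ch_high, dataset.fs,
                env_bands, tracked, envelope_mode,
            )
            for spec in specs:
                if spec.kind == "phase_amplitude":
                    key = spec.band_low.label if envelope_mode == "band_filtered" else None
                    vals = plv(phi_l - phi_e[key], windows)
                else:
                    vals = plv(spec.n * phi_l - spec.m * phi_h, windows)
                buffers[spec.label][:, si, gi] = vals
            if include_frequency:
                om = np.column_stack(omegas["low" if frequency_channel == channel_low else "high"])
                freq_hz = om * dataset.fs / (2 * math.pi)
                csum = np.vstack([np.zeros((1, freq_hz.shape[1])), np.cumsum(freq_hz, axis=0)])
                mf = np.array(
                    [(csum[w.stop] - csum[w.start]).mean() / w.n_samples for w in windows]
                )
                buffers["mean_frequency"][:, si, gi] = mf
    for label, vals in buffers.items():
        out[label] = WindowedFeatures(
            values=vals,
            feature=label,
            window_centers_ms=centers,
            subjects=subjects,
            groups=(conditions[0], conditions[1]),
        )
    return out
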