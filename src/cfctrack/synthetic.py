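"""Synthetic-signal generators used to validate the tracking and coupling
pipeline without any recorded data.

Three families are provided:

* a pair of phase-locked sinusoids at normalized frequencies 0.05 and 0.35
  in independent white Gaussian noise (the broad-band-noise stress case;
  their 7:1 phase-phase locking is exactly 1 without noise),
* an EEG-mimicking pair with 5.5 Hz and 44 Hz components under a Hann
  amplitude envelope, a transient 36 Hz interferer and noise (the
  oscillatory-interference stress case),
* multi-subject two-condition trial collections with an injected
  stimulus-locked change in phase-amplitude coupling, for exercising the
  statistics stage.

Phase-randomized surrogates (amplitude spectrum preserved exactly,
Fourier phases drawn uniformly) are also generated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .containers import Epoch, EpochSet, TimeSeries

__all__ = [
    "CoupledSinusoidModel",
    "EEGMimicModel",
    "GroupModel",
    "gen_coupled_sinusoids",
    "gen_eeg_mimic_pair",
    "gen_surrogate",
    "gen_group_dataset",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class CoupledSinusoidModel:
    """Two noisy sinusoids with an exact 7:1 frequency ratio.

    ``snr_db`` is applied per signal as sinusoid power over noise power,
    after the 1/3 amplitude scale on the high-frequency signal (the scale
    reflects the 1/f-like power decrease of high-frequency EEG activity).
    ``snr_db=inf`` yields noiseless signals.  ``n_samples`` defaults to
    1075 so that discarding 500 guard samples at each end leaves a
    75-sample analysis window.
    """

    f_low: float = 0.05
    f_high: float = 0.35
    high_amp_scale: float = 1.0 / 3.0
    snr_db: float = math.inf
    n_samples: int = 1075
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high < 0.5):
            raise ValueError("require 0 < f_low < f_high < 0.5 cycles/sample")
        if self.high_amp_scale <= 0:
            raise ValueError("high_amp_scale must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if math.isnan(self.snr_db) or self.snr_db == -math.inf:
            raise ValueError("snr_db must be finite or +inf")


def gen_coupled_sinusoids(
    model: CoupledSinusoidModel, rng: np.random.Generator | None = None
) -> tuple[TimeSeries, TimeSeries]:
    """Draw one realization of the two-sinusoid model.

    Phases are uniform on [0, 2π); phases and the two noises come from
    independent generator substreams.  Returns two real series at unit
    (normalized) sampling rate.
    """
    rng = rng if rng is not None else _rng(model.seed)
    phase_rng, noise_rng = rng.spawn(2)
    phi1, phi2 = phase_rng.uniform(0.0, 2 * math.pi, size=2)
    n = np.arange(model.n_samples)
    s1 = np.cos(2 * math.pi * model.f_low * n + phi1)
    s2 = model.high_amp_scale * np.cos(2 * math.pi * model.f_high * n + phi2)
    if math.isinf(model.snr_db):
        x1, x2 = s1, s2
    else:
        snr_lin = 10.0 ** (model.snr_db / 10.0)
        var1 = 0.5 / snr_lin
        var2 = 0.5 * model.high_amp_scale**2 / snr_lin
        x1 = s1 + noise_rng.normal(0.0, math.sqrt(var1), model.n_samples)
        x2 = s2 + noise_rng.normal(0.0, math.sqrt(var2), model.n_samples)
    return TimeSeries(x1, fs=1.0), TimeSeries(x2, fs=1.0)


@dataclass(frozen=True)
class EEGMimicModel:
    """EEG-like pair: 5.5 Hz and 44 Hz components with a Hann amplitude
    envelope, a transient 36 Hz interferer on the high channel, and noise.

    Signal 1 = a(n)·cos(2π·5.5/fs·n + φ₁) + e₁(n)  with var(e₁)=25.
    Signal 2 = a(n)·cos(2π·44/fs·n + φ₂) + i(n) + e₂(n) with var(e₂)=4.

    The envelope is a baseline plus a 250-sample Hann bump starting at
    sample ``env_start`` (default 125: peak at sample 250, i.e. 1000 ms,
    centred on the 600–1400 ms effect interval during which the 8:1
    phase-phase coupling of the two sinusoids is strongest).  The
    interferer ``i(n)`` is a 36 Hz cosine with its own Hann envelope over
    ``interf_len`` samples from ``interf_start`` (default 600–1200 ms), so
    it corrupts fixed-band phase extraction in the middle of the effect
    interval and subsides before its end.
    """

    fs: float = 250.0
    n_samples: int = 500
    f1: float = 5.5
    f2: float = 44.0
    f_interf: float = 36.0
    noise_var1: float = 25.0
    noise_var2: float = 4.0
    hann_len: int = 250
    env_base: float = 1.0
    env_gain: float = 10.0
    env_start: int = 125
    interf_amp: float = 15.0
    interf_len: int = 150
    interf_start: int = 150
    seed: int | None = None

    def __post_init__(self) -> None:
        ny = self.fs / 2
        if not (0 < self.f1 < ny and 0 < self.f2 < ny and 0 < self.f_interf < ny):
            raise ValueError("all frequencies must lie below Nyquist")
        if self.noise_var1 < 0 or self.noise_var2 < 0:
            raise ValueError("noise variances must be nonnegative")
        if not (0 < self.hann_len <= self.n_samples):
            raise ValueError("hann_len must be in (0, n_samples]")

    def envelope(self) -> np.ndarray:
        """Time-varying amplitude a(n) of the two locked sinusoids."""
        a = np.full(self.n_samples, self.env_base, dtype=float)
        w = hann(self.hann_len, sym=True)
        stop = min(self.env_start + self.hann_len, self.n_samples)
        a[self.env_start : stop] += self.env_gain * w[: stop - self.env_start]
        return a

    def interferer_envelope(self) -> np.ndarray:
        env = np.zeros(self.n_samples)
        w = hann(self.interf_len, sym=True)
        stop = min(self.interf_start + self.interf_len, self.n_samples)
        env[self.interf_start : stop] = self.interf_amp * w[: stop - self.interf_start]
        return env


def gen_eeg_mimic_pair(
    model: EEGMimicModel, rng: np.random.Generator | None = None
) -> tuple[TimeSeries, TimeSeries]:
    """Draw one realization of the EEG-mimicking pair (real series at model.fs)."""
    rng = rng if rng is not None else _rng(model.seed)
    phase_rng, noise_rng = rng.spawn(2)
    phi1, phi2, phi3 = phase_rng.uniform(0.0, 2 * math.pi, size=3)
    n = np.arange(model.n_samples)
    a = model.envelope()
    s1 = a * np.cos(2 * math.pi * model.f1 / model.fs * n + phi1)
    s2 = a * np.cos(2 * math.pi * model.f2 / model.fs * n + phi2)
    interf = model.interferer_envelope() * np.cos(2 * math.pi * model.f_interf / model.fs * n + phi3)
    x1 = s1 + noise_rng.normal(0.0, math.sqrt(model.noise_var1), model.n_samples)
    x2 = s2 + interf + noise_rng.normal(0.0, math.sqrt(model.noise_var2), model.n_samples)
    return TimeSeries(x1, fs=model.fs), TimeSeries(x2, fs=model.fs)


def gen_surrogate(x: TimeSeries | np.ndarray, seed=None) -> TimeSeries | np.ndarray:
    """Phase-randomized surrogate with the input's amplitude spectrum.

    The DFT magnitudes are kept bin-exactly; phases of the
    positive-frequency bins are drawn uniformly on [0, 2π) and mirrored
    conjugate onto the negative bins so the output is real.  The DC bin and
    (for even length) the Nyquist bin are left untouched, as their phases
    are constrained to 0 or π.  Works column-wise on multichannel data.
    """
    rng = _rng(seed)
    data = x.data if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)
    if data.size == 0:
        raise ValueError("cannot generate a surrogate of an empty signal")
    if not np.all(np.isfinite(data)):
        raise ValueError("surrogate generation requires finite input")
    single = data.ndim == 1
    arr = data[:, None] if single else data
    n = arr.shape[0]
    spec = np.fft.rfft(arr, axis=0)
    n_bins = spec.shape[0]
    # randomizable bins: exclude DC, and Nyquist when n is even
    hi = n_bins - 1 if n % 2 == 0 else n_bins
    phases = rng.uniform(0.0, 2 * math.pi, size=(hi - 1, arr.shape[1]))
    spec[1:hi] = np.abs(spec[1:hi]) * np.exp(1j * phases)
    out = np.fft.irfft(spec, n=n, axis=0)
    out = out[:, 0] if single else out
    if isinstance(x, TimeSeries):
        return x.with_data(out)
    return out


@dataclass(frozen=True)
class GroupModel:
    """Generator settings for multi-subject two-condition trial sets.

    Each 2000 ms epoch (onset at 500 ms) carries a low channel
    ``cos(ω_low n + φ) + noise`` and a high channel whose amplitude is
    modulated by the low phase with depth κ:
    ``(1 + κ(n)·cos(ω_low n + φ))·cos(ω_high n + ψ) + noise``.
    κ equals a per-subject baseline everywhere except the effect window
    (600–1400 ms post-epoch-start by default), where condition B gains
    ``condition_effect``.  With ``condition_effect = 0`` the two conditions
    are exchangeable.
    """

    n_subjects: int = 9
    n_trials: int = 12
    condition_effect: float = 0.0
    fs: float = 250.0
    n_samples: int = 500
    onset_ms: float = 500.0
    f_low: float = 5.5
    f_high: float = 44.0
    kappa_base: float = 0.30
    kappa_subject_sd: float = 0.05
    noise_sd: float = 0.7
    effect_window_ms: tuple[float, float] = (600.0, 1400.0)
    conditions: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_trials < 1:
            raise ValueError("need at least 1 trial per condition")


def gen_group_dataset(
    n_subjects: int = 9,
    n_trials: int = 12,
    condition_effect: float = 0.0,
    seed: int | np.random.Generator | None = None,
    model: GroupModel | None = None,
) -> EpochSet:
    """Simulate a balanced two-condition group experiment.

    Returns an :class:`EpochSet` with channels ``("low", "high")``; the
    injected coupling change is stimulus-locked to the configured effect
    window.  Identical seeds reproduce the dataset bit-for-bit.
    """
    if model is None:
        model = GroupModel(
            n_subjects=n_subjects, n_trials=n_trials, condition_effect=condition_effect
        )
    rng = _rng(seed)
    n = np.arange(model.n_samples)
    t_ms = n / model.fs * 1000.0
    in_window = (t_ms >= model.effect_window_ms[0]) & (t_ms < model.effect_window_ms[1])
    w_low = 2 * math.pi * model.f_low / model.fs
    w_high = 2 * math.pi * model.f_high / model.fs

    epochs: list[Epoch] = []
    for s in range(model.n_subjects):
        kappa_s = model.kappa_base + rng.normal(0.0, model.kappa_subject_sd)
        kappa_s = max(kappa_s, 0.05)
        for cond_i, cond in enumerate(model.conditions):
            kappa = np.full(model.n_samples, kappa_s)
            if cond_i == 1:
                kappa[in_window] += model.condition_effect
            np.clip(kappa, 0.0, 0.95, out=kappa)
            for trial in range(model.n_trials):
                phi, psi = rng.uniform(0.0, 2 * math.pi, size=2)
                low_phase = w_low * n + phi
                low = np.cos(low_phase) + rng.normal(0.0, model.noise_sd, model.n_samples)
                high = (1.0 + kappa * np.cos(low_phase)) * np.cos(w_high * n + psi)
                high = high + rng.normal(0.0, model.noise_sd, model.n_samples)
                epochs.append(Epoch(f"S{s + 1:02d}", cond, trial, np.column_stack([low, high])))
    return EpochSet(
        epochs,
        fs=model.fs,
        channel_labels=("low", "high"),
        onset_ms=model.onset_ms,
        meta={"model": model, "condition_effect": model.condition_effect},
    )
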