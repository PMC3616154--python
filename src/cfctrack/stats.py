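"""Group-level inference on windowed features.

PLV features are variance-stabilized with the arcsine transform
``asin(sqrt(v))`` before testing (mean-frequency features are left as-is).
Per sliding window, a randomized-block ANOVA (subject as the random
block, dataset/condition as the two-level fixed effect) yields a p-value
for the fixed effect; with two groups and one observation per cell this F
equals the squared paired t statistic on (S−1) error degrees of freedom.

Because 101 correlated windows are tested, a single significant window is
not trusted: the decision statistic is the longest run of consecutive
windows with p < α, calibrated by permutation.  Each permutation flips the
group labels within subjects (one flip pattern per subject, applied to all
windows, preserving the temporal correlation structure), the per-window
ANOVA is recomputed, and the null distribution of the maximal run is
accumulated.  An effect is declared significant when the run p-value is
below 5 % **and** the observed run spans at least 4 windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .coupling import WindowedFeatures

__all__ = [
    "arcsine_transform",
    "window_anova",
    "max_run",
    "significant_runs",
    "permutation_run_test",
    "RunLengthResult",
]


def arcsine_transform(v):
    """Variance-stabilizing map asin(√v) of proportion-like values in [0,1]."""
    v = np.asarray(v, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("arcsine transform defined on [0, 1] only")
    return np.arcsin(np.sqrt(v))


def _values(features) -> np.ndarray:
    if isinstance(features, WindowedFeatures):
        return features.values
    arr = np.asarray(features, dtype=float)
    if arr.ndim == 2:  # single window
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("expected a (windows, subjects, 2) array")
    return arr


def _block_anova_F(x: np.ndarray) -> np.ndarray:
    """Randomized-block ANOVA F for the group effect, vectorized.

    ``x`` has shape (..., S, 2): any number of leading axes (windows,
    permutations), S subject blocks, 2 groups.  Returns F with the leading
    shape.  F = MS_group / MS_{group x subject}, df = (1, S−1).
    """
    s = x.shape[-2]
    grand = x.mean(axis=(-2, -1), keepdims=True)
    g_mean = x.mean(axis=-2, keepdims=True)  # per group
    s_mean = x.mean(axis=-1, keepdims=True)  # per subject
    ss_group = s * ((g_mean - grand) ** 2).sum(axis=(-2, -1))
    ss_subj = 2 * ((s_mean - grand) ** 2).sum(axis=(-2, -1))
    ss_tot = ((x - grand) ** 2).sum(axis=(-2, -1))
    ss_err = ss_tot - ss_group - ss_subj
    ss_err = np.maximum(ss_err, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_group / (ss_err / (s - 1))
    return f


def window_anova(features) -> np.ndarray:
    """Per-window fixed-effect p-values of the subject-block ANOVA.

    Accepts a :class:`~cfctrack.coupling.WindowedFeatures` or a
    (windows, subjects, 2) array; requires at least two subject blocks.
    Degenerate windows (zero error variance) yield p = 1 when the group
    means are also equal, else p = 0.
    """
    x = _values(features)
    s = x.shape[1]
    if s < 2:
        raise ValueError("block ANOVA requires at least 2 subjects")
    f = _block_anova_F(x)
    p = sps.f.sf(f, 1, s - 1)
    # 0/0 windows: no group difference and no error variance
    bad = ~np.isfinite(f)
    if np.any(bad):
        diff = np.abs(x[..., 0].mean(-1) - x[..., 1].mean(-1))
        p = np.where(bad, np.where(diff > 0, 0.0, 1.0), p)
    return p


def max_run(pvals: np.ndarray, alpha: float = 0.05) -> int:
    """Length of the longest run of consecutive p-values below alpha."""
    sig = np.asarray(pvals) < alpha
    if sig.ndim != 1:
        raise ValueError("max_run expects a 1-D p-value series")
    best = cur = 0
    for flag in sig:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    return int(best)


def _max_run_rows(sig: np.ndarray) -> np.ndarray:
    """Row-wise maximal run length of True values in a 2-D boolean array."""
    n_rows, n_cols = sig.shape
    best = np.zeros(n_rows, dtype=np.int64)
    cur = np.zeros(n_rows, dtype=np.int64)
    for j in range(n_cols):
        cur = np.where(sig[:, j], cur + 1, 0)
        best = np.maximum(best, cur)
    return best


def significant_runs(pvals: np.ndarray, alpha: float = 0.05) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal runs of p < alpha (stop exclusive)."""
    sig = np.asarray(pvals) < alpha
    runs = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(sig)))
    return runs


@dataclass
class RunLengthResult:
    """Outcome of the run-length permutation test for one feature."""

    pvals: np.ndarray
    alpha: float
    observed_max_run: int
    null_runs: np.ndarray
    run_pvalue: float
    min_run: int
    significant: bool
    window_centers_ms: np.ndarray | None = None

    @property
    def longest_interval_ms(self) -> tuple[float, float] | None:
        """Centre times bounding the longest significant run, if any."""
        if self.window_centers_ms is None or self.observed_max_run == 0:
            return None
        runs = significant_runs(self.pvals, self.alpha)
        start, stop = max(runs, key=lambda r: r[1] - r[0])
        return (float(self.window_centers_ms[start]), float(self.window_centers_ms[stop - 1]))


def permutation_run_test(
    features,
    n_perm: int = 1000,
    seed=None,
    alpha: float = 0.05,
    min_run: int = 4,
) -> RunLengthResult:
    """Run-length permutation test over the windows of one feature.

    Flip patterns over subjects are drawn uniformly (with replacement) from
    the 2^S within-subject label swaps; one pattern applies to every window
    of a permutation, preserving the windows' correlation.  The run p-value
    is the proportion of permutations whose maximal run of significant
    windows is at least the observed one (ties count), and the final
    decision additionally requires the observed run to span ``min_run``
    windows so that punctual effects are not declared.
    """
    x = _values(features)
    n_w, s, _ = x.shape
    if s < 2:
        raise ValueError("permutation test requires at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if np.ptp(x) == 0:
        raise ValueError("all feature values equal; test undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pvals = window_anova(x)
    observed = max_run(pvals, alpha)

    # Within-subject swaps act on the paired differences as sign flips.
    d = x[:, :, 0] - x[:, :, 1]  # (W, S)
    signs = rng.integers(0, 2, size=(n_perm, s)) * 2 - 1
    dp = d.T[None, :, :] * signs[:, :, None]  # (P, S, W)
    m = dp.mean(axis=1)
    v = dp.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_null = s * m**2 / v
    f_crit = sps.f.isf(alpha, 1, s - 1)
    sig = f_null > f_crit
    sig[~np.isfinite(f_null)] = False
    null_runs = _max_run_rows(sig)

    run_pvalue = float(np.mean(null_runs >= observed)) if observed > 0 else 1.0
    significant = bool(run_pvalue < 0.05 and observed >= min_run)
    centers = features.window_centers_ms if isinstance(features, WindowedFeatures) else None
    return RunLengthResult(
        pvals=pvals,
        alpha=alpha,
        observed_max_run=observed,
        null_runs=null_runs,
        run_pvalue=run_pvalue,
        min_run=min_run,
        significant=significant,
        window_centers_ms=np.asarray(centers) if centers is not None else None,
    )
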