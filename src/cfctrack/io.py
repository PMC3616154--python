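"""Epoch file formats, run configuration and manifests.

Epoch sets travel either as delimited text (one long-format CSV: UTF-8,
comma-separated, '.' decimal, header
``subject,condition,trial,time_ms,<ch1>,<ch2>,...``) or as an ``.npz``
binary array container.  A JSON manifest records the configuration hash,
seeds and package version so deterministic stages can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Epoch, EpochSet
from .coupling import COEFFICIENT_GRID, WindowGrid
from .preprocessing import BandDefinition, DEFAULT_BANDS, FilterBankConfig

__all__ = [
    "AnalysisConfig",
    "read_epochs",
    "write_epochs",
    "run_config",
    "write_manifest",
]


@dataclass
class AnalysisConfig:
    """Resolved pipeline configuration with the study's default values.

    Defaults: the eight fixed analysis bands, 300 ms windows shifted by
    10 ms with centres 0–1000 ms post-stimulus, the n:m coefficient grid
    up to 9:1, a 2 Hz tracker bandwidth with forgetting factor 0.99, 1000
    permutations at α = 0.05 with a minimum run of 4 windows, 60 Hz notch
    and 250 Hz target rate.
    """

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    filter_order: int = 4
    notch_hz: float = 60.0
    target_fs: float = 250.0
    electrode_subset: tuple[str, ...] = ("P2", "P4", "P6", "PO4", "PO6")
    sft_bandwidth_hz: float = 2.0
    sft_delta: float = 0.99
    pad_ms: float = 500.0
    win_ms: float = 300.0
    shift_ms: float = 10.0
    center_interval_ms: tuple[float, float] = (0.0, 1000.0)
    coefficient_grid: tuple[tuple[int, int], ...] = COEFFICIENT_GRID
    envelope_mode: str = "band_filtered"
    n_perm: int = 1000
    alpha: float = 0.05
    min_run: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha: expected a level in (0,1), got {self.alpha}")
        if self.n_perm < 1:
            raise ValueError(f"n_perm: must be >= 1, got {self.n_perm}")
        if self.min_run < 1:
            raise ValueError(f"min_run: must be >= 1, got {self.min_run}")
        if self.win_ms <= 0 or self.shift_ms <= 0:
            raise ValueError("win_ms/shift_ms: must be positive")
        if self.envelope_mode not in ("band_filtered", "raw"):
            raise ValueError(f"envelope_mode: unknown value {self.envelope_mode!r}")

    @property
    def filter_bank(self) -> FilterBankConfig:
        return FilterBankConfig(bands=self.bands, order=self.filter_order)

    def window_grid(self, fs: float | None = None) -> WindowGrid:
        return WindowGrid(self.win_ms, self.shift_ms, fs or self.target_fs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [[b.f_lo, b.f_hi, b.label] for b in self.bands]
        return d


def run_config(path: str | Path | None = None, overrides: dict | None = None) -> AnalysisConfig:
    """Load and validate a JSON/YAML configuration file.

    An empty or missing file yields the study defaults.  Unknown keys and
    invalid values are reported with the offending field name.  Band
    entries are ``[f_lo, f_hi]`` or ``[f_lo, f_hi, label]`` pairs.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if text.strip():
            if str(path).endswith((".yaml", ".yml")):
                import yaml

                raw = yaml.safe_load(text) or {}
            else:
                raw = json.loads(text)
    if overrides:
        raw.update(overrides)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "bands" in raw:
        bands = []
        for i, entry in enumerate(raw["bands"]):
            try:
                bands.append(BandDefinition(*entry))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"bands[{i}]: {exc}") from exc
        raw["bands"] = tuple(bands)
    for tup_key in ("electrode_subset",):
        if tup_key in raw:
            raw[tup_key] = tuple(raw[tup_key])
    if "center_interval_ms" in raw:
        raw["center_interval_ms"] = tuple(raw["center_interval_ms"])
    if "coefficient_grid" in raw:
        raw["coefficient_grid"] = tuple(tuple(p) for p in raw["coefficient_grid"])
    return AnalysisConfig(**raw)


def write_epochs(dataset: EpochSet, path: str | Path, fmt: str | None = None) -> Path:
    """Write an epoch set as long-format CSV or as an npz container."""
    path = Path(path)
    fmt = fmt or ("npz" if path.suffix == ".npz" else "csv")
    if fmt == "csv":
        frames = []
        t_ms = np.arange(dataset.n_samples) / dataset.fs * 1000.0
        for ep in dataset.epochs:
            df = pd.DataFrame(ep.data, columns=list(dataset.channel_labels))
            df.insert(0, "time_ms", t_ms)
            df.insert(0, "trial", ep.trial)
            df.insert(0, "condition", ep.condition)
            df.insert(0, "subject", ep.subject)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        with open(path, "w") as fh:
            fh.write(f"# fs={dataset.fs} onset_ms={dataset.onset_ms}\n")
            out.to_csv(fh, index=False)
    elif fmt == "npz":
        np.savez(
            path,
            data=np.stack([ep.data for ep in dataset.epochs]),
            subject=np.array([ep.subject for ep in dataset.epochs]),
            condition=np.array([ep.condition for ep in dataset.epochs]),
            trial=np.array([ep.trial for ep in dataset.epochs]),
            fs=dataset.fs,
            onset_ms=dataset.onset_ms,
            channel_labels=np.array(dataset.channel_labels),
        )
    else:
        raise ValueError(f"unknown epoch format: {fmt!r}")
    return path


def read_epochs(path: str | Path, fmt: str | None = None) -> EpochSet:
    """Read an epoch set written by :func:`write_epochs` (CSV or npz), or an
    EDF recording as a single-trial set (requires the optional mne extra)."""
    path = Path(path)
    if fmt is None:
        fmt = {".npz": "npz", ".csv": "csv", ".edf": "edf"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt == "csv":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("missing '# fs=... onset_ms=...' header line")
            meta = dict(kv.split("=") for kv in header[1:].split())
            df = pd.read_csv(fh)
        required = {"subject", "condition", "trial", "time_ms"}
        if not required.issubset(df.columns):
            raise ValueError(f"CSV missing required columns {sorted(required - set(df.columns))}")
        labels = tuple(c for c in df.columns if c not in required)
        epochs = []
        n_ref = None
        for (subj, cond, trial), g in df.groupby(["subject", "condition", "trial"], sort=True):
            data = g[list(labels)].to_numpy()
            if n_ref is None:
                n_ref = len(data)
            elif len(data) != n_ref:
                raise ValueError(
                    f"trial length mismatch: {len(data)} vs {n_ref} "
                    f"(subject={subj}, condition={cond}, trial={trial})"
                )
            epochs.append(Epoch(str(subj), str(cond), int(trial), data))
        return EpochSet(epochs, fs=float(meta["fs"]), channel_labels=labels,
                        onset_ms=float(meta["onset_ms"]))
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            data = z["data"]
            epochs = [
                Epoch(str(s), str(c), int(t), data[i])
                for i, (s, c, t) in enumerate(zip(z["subject"], z["condition"], z["trial"]))
            ]
            return EpochSet(
                epochs,
                fs=float(z["fs"]),
                channel_labels=tuple(str(x) for x in z["channel_labels"]),
                onset_ms=float(z["onset_ms"]),
            )
    if fmt == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("EDF ingestion requires mne (pip install cfctrack[edf])") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data().T
        return EpochSet(
            [Epoch("S01", "unlabelled", 0, data)],
            fs=float(raw.info["sfreq"]),
            channel_labels=tuple(raw.ch_names),
            onset_ms=0.0,
        )
    raise ValueError(f"unknown epoch format: {fmt!r}")


def write_manifest(path: str | Path, config: AnalysisConfig, seeds: dict | None = None,
                   extra: dict | None = None) -> Path:
    """Write a reproducibility manifest (config hash, seeds, version)."""
    from . import __version__

    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = {
        "package": "cfctrack",
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": seeds or {},
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
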