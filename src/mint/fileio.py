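"""Readers/writers for the package's file formats.

HDF5 is the canonical container; CSV is accepted for small spike-table
fixtures.  Time is integer milliseconds at every interface (sub-ms
timestamps are floored with a warning).  Every output file embeds the
configuration used to produce it and a format version tag that is checked
on load (no silent migration).
"""

from __future__ import annotations

import json
import logging
import warnings

import h5py
import numpy as np
import pandas as pd
import yaml

from .library import TrajectoryLibrary, TrainingConfig

logger = logging.getLogger(__name__)

LIBRARY_FORMAT_VERSION = "1"

__all__ = [
    "save_library",
    "load_library",
    "save_stream",
    "load_stream",
    "load_spike_table_csv",
    "save_spike_table_hdf5",
    "load_spike_table_hdf5",
    "save_decode_result",
    "load_config",
]


# ---------------------------------------------------------------------------
# Library serialization
# ---------------------------------------------------------------------------


def save_library(library: TrajectoryLibrary, path):
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = LIBRARY_FORMAT_VERSION
        f.attrs["tau"] = library.tau
        f.attrs["delta_ms"] = library.delta_ms
        f.attrs["sampling_rate_hz"] = 1000
        f.attrs["behavior_names"] = [str(n) for n in library.behavior_names]
        f.attrs["circular_flags"] = library.circular_flags.astype(np.int8)
        f.attrs["neuron_ids"] = [str(n) for n in library.neuron_ids]
        grp = f.create_group("conditions")
        for c in range(library.n_conditions):
            g = grp.create_group(str(c + 1))  # 1-based on disk
            g.create_dataset("rates", data=library.rates[c].astype(np.float32))
            g.create_dataset("behavior", data=library.behavior[c].astype(np.float64))


def load_library(path) -> TrajectoryLibrary:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != LIBRARY_FORMAT_VERSION:
            raise ValueError(
                f"library format version {version!r} not supported "
                f"(expected {LIBRARY_FORMAT_VERSION!r})"
            )
        for key in ("tau", "delta_ms", "circular_flags", "behavior_names", "neuron_ids"):
            if key not in f.attrs:
                raise ValueError(f"library file missing required attribute {key!r}")
        conds = sorted(f["conditions"], key=int)
        rates = [f["conditions"][c]["rates"][()].astype(np.float64) for c in conds]
        behavior = [f["conditions"][c]["behavior"][()] for c in conds]
        return TrajectoryLibrary(
            rates=rates,
            behavior=behavior,
            tau=int(f.attrs["tau"]),
            delta_ms=int(f.attrs["delta_ms"]),
            circular_flags=np.asarray(f.attrs["circular_flags"], dtype=bool),
            neuron_ids=list(f.attrs["neuron_ids"]),
            behavior_names=list(f.attrs["behavior_names"]),
        )


# ---------------------------------------------------------------------------
# Spike streams / tables
# ---------------------------------------------------------------------------


def save_stream(counts: np.ndarray, path, config: dict | None = None):
    """Save a 1 kHz binned count stream ``(N, T)``."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = LIBRARY_FORMAT_VERSION
        f.attrs["kind"] = "stream"
        f.create_dataset("counts", data=np.asarray(counts, dtype=np.int32))
        if config is not None:
            f.attrs["config"] = json.dumps(config)


def load_stream(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "stream":
            raise ValueError("not a stream file (kind attribute mismatch)")
        return f["counts"][()].astype(np.int64)


def _table_to_counts(df: pd.DataFrame, n_units=None, duration=None):
    required = {"unit_id", "time_ms"}
    if not required <= set(df.columns):
        raise ValueError(f"spike table must have columns {sorted(required)}")
    times = df["time_ms"].to_numpy(dtype=float)
    if np.any(times != np.floor(times)):
        warnings.warn("sub-millisecond timestamps floored to integer ms", stacklevel=2)
    times = np.floor(times).astype(int)
    if not np.all(np.diff(times) >= 0):
        warnings.warn("unsorted timestamps; sorting", stacklevel=2)
        order = np.argsort(times, kind="stable")
        df = df.iloc[order]
        times = times[order]
    units = df["unit_id"].to_numpy(dtype=int)
    N = n_units if n_units is not None else units.max() + 1
    T = duration if duration is not None else times.max() + 1
    counts = np.zeros((N, T), dtype=np.int64)
    np.add.at(counts, (units, times), 1)
    return counts


def load_spike_table_csv(path, n_units=None, duration=None) -> np.ndarray:
    """Load a CSV spike table (unit_id, time_ms[, trial_id]) to counts."""
    df = pd.read_csv(path)
    counts = _table_to_counts(df, n_units, duration)
    logger.info("loaded %d units, %d ms, %d spikes", *counts.shape, counts.sum())
    return counts


def save_spike_table_hdf5(df: pd.DataFrame, path):
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = LIBRARY_FORMAT_VERSION
        f.attrs["kind"] = "spike_table"
        for col in df.columns:
            f.create_dataset(col, data=df[col].to_numpy())


def load_spike_table_hdf5(path) -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "spike_table":
            raise ValueError("not a spike-table file (kind attribute mismatch)")
        return pd.DataFrame({k: f[k][()] for k in f.keys()})


# ---------------------------------------------------------------------------
# Decode output
# ---------------------------------------------------------------------------


def save_decode_result(result, path, config: dict | None = None, include_rates: bool = True):
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = LIBRARY_FORMAT_VERSION
        f.attrs["kind"] = "decode"
        if config is not None:
            f.attrs["config"] = json.dumps(config)
        g = f.create_group("estimates")
        g.create_dataset("behavior", data=result.behavior)
        if include_rates:
            g.create_dataset("rates", data=result.rates.astype(np.float32))
        g.create_dataset("loglik", data=result.log_likelihood)
        g.create_dataset("provenance", data=result.provenance)
        g.create_dataset("valid", data=result.valid.astype(np.int8))
        g.create_dataset("time", data=result.time)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_TRAINING_KEYS = {
    "sigma_ms",
    "start_event",
    "window_start",
    "end_event",
    "window_end",
    "averaging_mode",
    "d_neural",
    "d_condition",
    "soft_norm_constant",
    "circular_flags",
    "warp_mode",
}


def load_config(path) -> dict:
    """Load a YAML/JSON run config, rejecting unknown training keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    train = cfg.get("training", {})
    unknown = set(train) - _TRAINING_KEYS
    if unknown:
        raise ValueError(f"unknown training config keys: {sorted(unknown)}")
    return cfg


def training_config_from_dict(d: dict) -> TrainingConfig:
    d = dict(d)
    if "circular_flags" in d and d["circular_flags"] is not None:
        d["circular_flags"] = np.asarray(d["circular_flags"], dtype=bool)
    return TrainingConfig(**d)
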