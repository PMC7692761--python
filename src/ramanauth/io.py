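"""CSV / YAML input-output.

Spectra travel as a wide CSV whose header row is the numeric wavenumber
grid (first column = spectrum id); sample metadata travels as a plain
CSV keyed by ``spectrum_id``.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import SpectraMatrix


class ConfigError(ValueError):
    """Raised for malformed or inconsistent run configuration."""


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


def write_spectra_csv(m: SpectraMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, columns=[f"{w:g}" for w in m.axis])
    df.insert(0, "spectrum_id", m.ids)
    df.to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> SpectraMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "spectrum_id":
        raise DataError(f"{path}: first column must be 'spectrum_id'")
    try:
        axis = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric wavenumber header") from exc
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise DataError(f"{path}: missing or non-finite intensities")
    return SpectraMatrix(axis, values, df["spectrum_id"].astype(str).tolist())


META_COLUMNS = [
    "spectrum_id",
    "package_id",
    "class",
    "rind_pct",
    "session",
    "replicate_group",
    "point_index",
]


def write_meta_csv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def read_meta_csv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise DataError(f"{path}: missing metadata columns {missing}")
    return meta


def load_config(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
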