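"""CSV/JSON/YAML input-output with strict validation.

Two CSV dialects are used throughout:

* count table: ``station,month,<taxon_1>,...,<taxon_k>`` — integer cells,
  one row per station-month;
* environment table: ``station,month,temperature,discharge_q,ph,do_mgl,ec,
  bod5,tds`` — float cells.

Readers sniff comma vs tab delimiters, validate every cell, and raise
:class:`~riverbio.errors.ParseError` with row/column coordinates on failure.
Missing values are an error, never imputed.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diversity import AbundanceVector, abundance_vectors_from_frame
from .errors import ConfigError, DuplicateSampleError, ParseError
from .gp import GpConfig
from .pipeline import AnalysisConfig, ENV_PREDICTORS

__all__ = [
    "read_counts_csv",
    "read_env_csv",
    "write_counts_csv",
    "write_env_csv",
    "write_indices_csv",
    "load_config",
]

log = logging.getLogger("riverbio")

ENV_COLUMNS = ["station", "month", *ENV_PREDICTORS]


def _sniff_read(path) -> pd.DataFrame:
    text = Path(path).read_text()
    first_line = text.splitlines()[0] if text else ""
    sep = "\t" if first_line.count("\t") > first_line.count(",") else ","
    return pd.read_csv(_io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)


def _numeric(frame: pd.DataFrame, column: str, kind: str) -> pd.Series:
    raw = frame[column]
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ParseError(
            f"non-numeric cell {raw.iloc[row]!r}", row=row + 2, column=column
        )
    if kind == "int":
        if not np.allclose(converted, converted.round()):
            row = int(np.flatnonzero(converted != converted.round())[0])
            raise ParseError("non-integer count", row=row + 2, column=column)
        return converted.astype(int)
    return converted.astype(float)


def _check_duplicates(frame: pd.DataFrame) -> None:
    dup = frame.duplicated(subset=["station", "month"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise DuplicateSampleError(
            f"duplicate sample key ({row['station']}, {row['month']})"
        )


def read_counts_csv(path) -> list[AbundanceVector]:
    """Read a wide count table into per-sample abundance vectors."""
    frame = _sniff_read(path)
    for col in ("station", "month"):
        if col not in frame.columns:
            raise ParseError(f"missing required column {col!r}", column=col)
    frame["month"] = _numeric(frame, "month", "int")
    taxa = [c for c in frame.columns if c not in ("station", "month")]
    if not taxa:
        raise ParseError("count table has no taxon columns")
    for t in taxa:
        frame[t] = _numeric(frame, t, "int")
    _check_duplicates(frame)
    return abundance_vectors_from_frame(frame)


def read_env_csv(path) -> pd.DataFrame:
    """Read and validate an environment table."""
    frame = _sniff_read(path)
    missing = [c for c in ENV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"missing required column {missing[0]!r}", column=missing[0])
    frame["month"] = _numeric(frame, "month", "int")
    for col in ENV_PREDICTORS:
        frame[col] = _numeric(frame, col, "float")
    _check_duplicates(frame)
    return frame[ENV_COLUMNS]


def write_counts_csv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index=False, lineterminator="\r\n")


def write_env_csv(env: pd.DataFrame, path) -> None:
    env.to_csv(path, index=False, float_format="%.6g", lineterminator="\r\n")


def write_indices_csv(indices: pd.DataFrame, path) -> None:
    indices.to_csv(path, index=False, float_format="%.4f", lineterminator="\r\n")


_TOP_LEVEL_KEYS = {
    "counts_csv",
    "env_csv",
    "n_runs",
    "split_fraction",
    "k_clusters",
    "collinearity_threshold",
    "keep_priority",
    "n_components",
    "winter_months",
    "seed",
    "gp",
    "out_dir",
}
_GP_KEYS = {f.name for f in dataclass_fields(GpConfig)}


def load_config(path) -> tuple[AnalysisConfig, dict]:
    """Load a flat YAML analysis config with one nested ``gp`` block.

    Returns the typed config plus a dict of the extra path settings
    (``counts_csv``, ``env_csv``, ``out_dir``). Unknown keys are an error.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    gp_raw = raw.get("gp") or {}
    unknown_gp = set(gp_raw) - _GP_KEYS
    if unknown_gp:
        raise ConfigError(f"unknown gp config key(s): {sorted(unknown_gp)}")
    if "init_depth" in gp_raw:
        gp_raw["init_depth"] = tuple(gp_raw["init_depth"])
    if "constant_range" in gp_raw:
        gp_raw["constant_range"] = tuple(gp_raw["constant_range"])
    if "function_set" in gp_raw:
        gp_raw["function_set"] = tuple(gp_raw["function_set"])
    gp_config = GpConfig(**gp_raw)

    kwargs = {}
    for key in (
        "n_runs",
        "split_fraction",
        "k_clusters",
        "collinearity_threshold",
        "n_components",
        "seed",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "keep_priority" in raw:
        kwargs["keep_priority"] = tuple(raw["keep_priority"])
    if "winter_months" in raw:
        kwargs["winter_months"] = tuple(raw["winter_months"])
    config = AnalysisConfig(gp=gp_config, **kwargs)

    paths = {k: raw.get(k) for k in ("counts_csv", "env_csv", "out_dir")}
    for key in ("counts_csv", "env_csv"):
        if paths[key] is not None and not Path(paths[key]).exists():
            raise ConfigError(f"{key} path does not exist: {paths[key]}")
    log.info("resolved config: %s (paths: %s)", config, paths)
    return config, paths
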