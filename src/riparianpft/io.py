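"""CSV and YAML I/O with embedded metadata headers.

Tables travel as plain CSV. Metadata (config echo, seed, fold partition,
library versions) is embedded as ``# key: value`` comment lines above the
header, so a single file documents how it was produced; readers skip them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import schema

__all__ = [
    "read_environment",
    "read_responses",
    "read_traits",
    "write_table",
    "read_table",
    "load_config",
    "dump_config",
]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a DataFrame as CSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            if isinstance(value, (dict, list, tuple)):
                value = json.dumps(value, sort_keys=True, default=_json_default)
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, lineterminator="\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def read_environment(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read and schema-validate a site x predictor environment table."""
    df = read_table(path)
    df.index.name = "site"
    return schema.validate_environment(df, required=required)


def read_responses(path) -> pd.DataFrame:
    """Read and schema-validate a site x functional-type response table."""
    df = read_table(path)
    df.index.name = "site"
    return schema.validate_responses(df)


def read_traits(path) -> pd.DataFrame:
    """Read and schema-validate a species x leaf-trait table."""
    df = read_table(path)
    df.index.name = "species"
    return schema.validate_traits(df)


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def dump_config(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
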