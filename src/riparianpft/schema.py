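"""Dataset schema: required columns, block tags, and units.

The analysis moves three small tables around: a site x predictor
environment table whose columns belong to one of three blocks (climate,
soil, physical), a site x response table (percent covers and Simpson
diversities per plant functional type), and a species x leaf-trait table.
Validation aggregates every violation into a single error rather than
failing one column at a time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BLOCKS",
    "ENV_COLUMNS",
    "ENV_BLOCK_OF",
    "UNITS",
    "RESPONSE_COLUMNS",
    "TRAIT_COLUMNS",
    "SchemaError",
    "validate_environment",
    "validate_responses",
    "validate_traits",
]

#: Predictor blocks in canonical order; indices (PP_PET, IDM, Q2) belong to
#: climate and C:N to soil, mirroring how the derived columns are used.
BLOCKS: dict[str, list[str]] = {
    "climate": ["PP", "PET", "DaysPP", "Tmean", "Tmin_jan", "Tmax_jul",
                "Trange", "PP_PET", "IDM", "Q2"],
    "soil": ["EC", "pH_w", "CaCO3", "OC", "N", "CN", "P", "CEC", "AW", "BS", "ESP"],
    "physical": ["altitude", "slope", "basin_area", "southern_orientation",
                 "bankfull_width", "active_width", "hard_substrate", "discharge"],
}

ENV_COLUMNS: list[str] = [c for cols in BLOCKS.values() for c in cols]
ENV_BLOCK_OF: dict[str, str] = {c: b for b, cols in BLOCKS.items() for c in cols}

UNITS: dict[str, str] = {
    "PP": "mm", "PET": "mm/y", "DaysPP": "days/y", "Tmean": "degC",
    "Tmin_jan": "degC", "Tmax_jul": "degC", "Trange": "degC",
    "PP_PET": "dimensionless", "IDM": "index", "Q2": "index",
    "EC": "uS/cm", "pH_w": "pH", "CaCO3": "%", "OC": "%", "N": "%",
    "CN": "ratio", "P": "ppm", "CEC": "cmol+/kg", "AW": "%", "BS": "%",
    "ESP": "%",
    "altitude": "m asl", "slope": "%", "basin_area": "ha",
    "southern_orientation": "deg (0-180)", "bankfull_width": "m",
    "active_width": "m", "hard_substrate": "%", "discharge": "L/s",
    "SLA": "mm^2/g", "toughness": "g", "N_mass": "%", "C_mass": "%",
    "lignin": "%", "Si": "%",
}

PFTS = ["GG", "ES", "ET", "DS", "DT"]
RESPONSE_COLUMNS: list[str] = (
    [f"cover_{p}" for p in PFTS] + ["cover_total_canopy"]
    + [f"div_{p}" for p in PFTS] + ["div_total"]
)
TRAIT_COLUMNS = ["SLA", "toughness", "N_mass", "CN", "lignin", "Si"]


class SchemaError(ValueError):
    """Raised with every violation found, aggregated."""

    def __init__(self, table: str, problems: list[str]):
        self.table = table
        self.problems = list(problems)
        super().__init__(f"{table} table: " + "; ".join(self.problems))


def _common_checks(df: pd.DataFrame, required: list[str], table: str) -> list[str]:
    problems = []
    missing = [c for c in required if c not in df.columns]
    for c in missing:
        if table == "environment":
            problems.append(f"missing column {c!r} (block {ENV_BLOCK_OF.get(c, '?')})")
        else:
            problems.append(f"missing column {c!r}")
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        problems.append(f"duplicate row id(s): {dups}")
    for c in (set(required) - set(missing)):
        col = df[c]
        if not np.issubdtype(np.asarray(col).dtype, np.number):
            problems.append(f"non-numeric values in column {c!r}")
        elif col.isna().any():
            problems.append(f"missing values in column {c!r}")
    return problems


def validate_environment(df: pd.DataFrame, required: list[str] | None = None) -> pd.DataFrame:
    problems = _common_checks(df, required or ENV_COLUMNS, "environment")
    if problems:
        raise SchemaError("environment", sorted(problems))
    return df


def validate_responses(df: pd.DataFrame) -> pd.DataFrame:
    problems = _common_checks(df, RESPONSE_COLUMNS, "responses")
    for c in RESPONSE_COLUMNS:
        if c in df.columns and np.issubdtype(np.asarray(df[c]).dtype, np.number):
            vals = df[c].to_numpy(dtype=float)
            if c.startswith("cover") and (np.any(vals < 0) or np.any(vals > 100)):
                problems.append(f"cover column {c!r} outside [0, 100]")
            if c.startswith("div") and (np.any(vals < 0) or np.any(vals >= 1)):
                problems.append(f"diversity column {c!r} outside [0, 1)")
    if problems:
        raise SchemaError("responses", sorted(problems))
    return df


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    problems = []
    if "pft" not in df.columns:
        problems.append("missing column 'pft'")
    else:
        bad = sorted(set(df["pft"]) - set(PFTS))
        if bad:
            problems.append(f"unknown functional type label(s): {bad}")
    problems += _common_checks(df, TRAIT_COLUMNS, "traits")
    for c in TRAIT_COLUMNS:
        if c in df.columns and np.issubdtype(np.asarray(df[c]).dtype, np.number):
            if np.any(df[c].to_numpy(dtype=float) <= 0):
                problems.append(f"nonpositive values in trait column {c!r}")
    if problems:
        raise SchemaError("traits", sorted(problems))
    return df
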