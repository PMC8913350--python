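"""Validated delimited-table I/O.

Every pipeline table is plain tab-separated text with a header row.  Schemas
are small column->kind mappings; reading validates presence and coerces types,
reporting the offending row and column on failure.  Extra columns are
preserved with a warning.  Floats are written at 12 significant digits so a
write/read round trip is lossless at that precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["PEAK_SCHEMA", "ECHO_SCHEMA", "GRID_SCHEMA", "CT_SCHEMA",
           "PROFILE_SCHEMA", "read_table", "write_table"]

PEAK_SCHEMA = {"species_id": "str", "class": "str", "adduct": "str",
               "sample_id": "str", "genotype": "str", "replicate": "int",
               "concentration": "float", "snr": "float", "pq": "float"}

ECHO_SCHEMA = {"animal_id": "str", "genotype": "str", "heart_rate": "float",
               "lvid_s": "float", "lvid_d": "float", "lvpw_s": "float",
               "lvpw_d": "float", "lvaw_s": "float", "lvaw_d": "float",
               "lv_vol_s": "float", "lv_vol_d": "float", "mv_e": "float",
               "mv_a": "float", "body_weight": "float", "heart_weight": "float"}

GRID_SCHEMA = {"field_id": "str", "points_mito": "int", "points_total": "int",
               "grid_spacing": "float"}

CT_SCHEMA = {"sample_id": "str", "genotype": "str", "ct_target": "float",
             "ct_reference": "float"}

PROFILE_SCHEMA = {"species_id": "str", "class": "str", "genotype": "str",
                  "mean_concentration": "float", "n_replicates": "int"}

def _maybe_numeric(series: pd.Series) -> pd.Series:
    try:
        return pd.to_numeric(series)
    except (ValueError, TypeError):
        return series


def read_table(path: str | Path, schema: dict[str, str] | None = None,
               sep: str = "\t") -> pd.DataFrame:
    """Read a delimited table, validating it against ``schema`` if given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=["", "NA", "NaN", "nan"])
    if schema is None:
        return df.apply(_maybe_numeric)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: header missing columns {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(f"{path.name}: unknown columns {extra} preserved", stacklevel=2)
    out = df.copy()
    for col, kind in schema.items():
        if kind == "str":
            continue
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path.name}: column {col!r}, row {row + 2} "  # +2: header + 1-based
                f"has malformed value {out[col].iloc[row]!r}")
        out[col] = coerced.astype(int) if kind == "int" and not coerced.isna().any() \
            else coerced
    for col in extra:
        out[col] = _maybe_numeric(out[col])
    return out


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> Path:
    """Write a table as delimited text with header, floats at 12 sig. digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")
    return path
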