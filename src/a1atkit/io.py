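"""Strict tabular I/O: schema-validated CSV with bit-stable formatting.

All assay data in this package are small tables; CSV (plus JSON sidecars
for ground truth and configuration) is the only on-disk format.  Floats
are written with a fixed 12-significant-digit format so that a
read -> write round trip is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "read_table", "write_table", "write_json", "read_json"]

_FLOAT_FMT = "%.12g"

_DTYPES = {"float": float, "int": np.int64, "str": str}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _validate(df: pd.DataFrame, schema: dict, permissive: bool) -> pd.DataFrame:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        if not permissive:
            raise SchemaError(f"unexpected column(s): {', '.join(extra)}")
        warnings.warn(f"ignoring extra column(s): {', '.join(extra)}", stacklevel=3)
    out = df[list(schema)].copy()
    for col, kind in schema.items():
        if kind not in _DTYPES:
            raise SchemaError(f"unknown dtype {kind!r} for column {col!r}")
        try:
            out[col] = out[col].astype(_DTYPES[kind])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not {kind}: {exc}") from exc
    return out


def read_table(path: "str | Path", schema: dict, permissive: bool = False) -> pd.DataFrame:
    """Read a CSV and validate it against ``{column: 'float'|'int'|'str'}``."""
    df = pd.read_csv(path)
    return _validate(df, schema, permissive)


def write_table(df: pd.DataFrame, path: "str | Path", schema: dict) -> None:
    """Write a schema-validated CSV with fixed float formatting."""
    out = _validate(df, schema, permissive=True)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_json(obj, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: "str | Path"):
    return json.loads(Path(path).read_text())
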