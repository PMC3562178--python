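"""Reading and writing the package's delimited-text interchange formats."""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .descriptives import validate_dyad_table
from .errors import ValidationError


def read_dyad_csv(path, validate: bool = True) -> pd.DataFrame:
    """Read a wide-format dyad table (one row per dyad, role-prefixed
    columns)."""
    df = pd.read_csv(path)
    if "dyad_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'dyad_id'")
    if validate:
        validate_dyad_table(df)
    return df


def write_dyad_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _sanitize(obj):
    """Replace NaN/inf with None so reports are strict JSON."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def write_json_report(report: dict, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, strict values."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_sanitize(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
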