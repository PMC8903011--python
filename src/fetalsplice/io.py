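"""Schema-checked TSV readers and writers for the pipeline tables.

All tables are plain tab-separated text with a header row; numbers are
serialized at full precision (repr round-trip), so write -> read is
bit-identical for floats. Unknown extra columns are preserved with a
warning; missing required columns or unparseable values raise with the file
and line indicated.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd

__all__ = [
    "read_table",
    "write_table",
    "write_matrix",
    "read_matrix",
    "write_junction_counts",
    "read_junction_counts",
]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=None)


def read_table(
    path: str | Path,
    required: Optional[Sequence[str]] = None,
    dtypes: Optional[Dict[str, type]] = None,
) -> pd.DataFrame:
    """Read a TSV, validating required columns and coercing declared dtypes."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: parse error: {exc}") from exc
    if df.columns.size and df.columns[0].startswith("Unnamed"):
        df = df.rename(columns={df.columns[0]: "index"})
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        extra = [c for c in df.columns if c not in required]
        if extra:
            warnings.warn(f"{path}: extra columns preserved: {extra}")
    if dtypes:
        for col, typ in dtypes.items():
            try:
                df[col] = df[col].astype(typ)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: column {col!r} not coercible to {typ}: {exc}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    """Write an id x samples matrix with the index as first column."""
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df


def write_junction_counts(
    inclusion: pd.DataFrame, exclusion: pd.DataFrame, path: str | Path
) -> None:
    """Long-format junction count TSV: event_id, sample_id, inclusion, exclusion."""
    inc = inclusion.stack()
    exc = exclusion.stack()
    long = pd.DataFrame(
        {"inclusion": inc, "exclusion": exc}
    ).reset_index()
    long.columns = ["event_id", "sample_id", "inclusion", "exclusion"]
    long.to_csv(path, sep="\t", index=False)


def read_junction_counts(path: str | Path):
    """Read a long-format junction count TSV back into wide inclusion and
    exclusion tables (events x samples)."""
    long = read_table(
        path,
        required=["event_id", "sample_id", "inclusion", "exclusion"],
        dtypes={"inclusion": int, "exclusion": int},
    )
    inc = long.pivot(index="event_id", columns="sample_id", values="inclusion")
    exc = long.pivot(index="event_id", columns="sample_id", values="exclusion")
    return inc, exc
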