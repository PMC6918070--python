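"""Delimited-text table formats binding the pipeline together.

All files are tab-delimited UTF-8 with '.' decimals; times in minutes,
lengths in μm, volumes in μm³.  Floats are written with 6 significant
digits so identical runs produce byte-identical files; unassigned
cell-cycle fields are empty cells, not zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "GENERATION_COLUMNS",
    "FRAME_COLUMNS",
    "write_generation_table",
    "read_generation_table",
    "write_frame_table",
    "read_frame_table",
    "generation_table_from_records",
]

#: Generation-table schema: one row per cell generation.
GENERATION_COLUMNS = [
    "cell_id", "parent_id", "condition",
    "t_b_min", "t_d_min", "tau_min",
    "L_b_um", "L_d_um", "W_um",
    "lambda_per_min", "septum_position",
    "t_i_min", "L_i_um", "S_i_um3", "n_ori_at_init", "s_i_um3",
    "C_min", "D_min", "n_oc",
]

_GEN_NUMERIC = [c for c in GENERATION_COLUMNS if c not in
                ("cell_id", "parent_id", "condition")]

#: Frame-table schema: one row per sampled frame.
FRAME_COLUMNS = ["time_min", "lineage", "cell_id", "length_um", "width_um",
                 "pair_count", "focus_positions"]

_FRAME_NUMERIC = ["time_min", "length_um", "width_um", "pair_count"]


class TableSchemaError(ValueError):
    """A mandatory column is missing from an input table."""


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write(df: pd.DataFrame, columns, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _read(path, columns, numeric):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableSchemaError(f"missing mandatory column(s): {missing}")
    bad_lines: list[int] = []
    for col in numeric:
        raw = df[col].mask(df[col].astype(str) == "")
        conv = pd.to_numeric(raw, errors="coerce")
        bad = conv.isna() & raw.notna()
        bad_lines.extend((df.index[bad] + 2).tolist())  # 1-based + header
        df[col] = conv
    bad_lines = sorted(set(bad_lines))
    if bad_lines:
        df = df.drop(index=[ln - 2 for ln in bad_lines]).reset_index(drop=True)
    return df, bad_lines


def write_generation_table(records: pd.DataFrame, path) -> None:
    """Write generation records in the canonical schema (deterministic
    column order and float formatting; missing fields as empty cells)."""
    out = pd.DataFrame()
    for col in GENERATION_COLUMNS:
        if col in records.columns:
            out[col] = records[col]
        else:
            out[col] = np.nan if col in _GEN_NUMERIC else ""
    for col in _GEN_NUMERIC:
        out[col] = pd.to_numeric(out[col], errors="coerce").astype(float)
    _write(out, GENERATION_COLUMNS, path)


def read_generation_table(path):
    """Read a generation table; returns ``(records, bad_line_numbers)``.

    Extra columns are tolerated; rows with unparseable numerics are
    dropped and reported by 1-based line number.
    """
    return _read(path, GENERATION_COLUMNS, _GEN_NUMERIC)


def write_frame_table(frames: pd.DataFrame, path) -> None:
    out = pd.DataFrame()
    for col in FRAME_COLUMNS:
        if col in frames.columns:
            out[col] = frames[col]
        else:
            out[col] = np.nan if col in _FRAME_NUMERIC else ""
    _write(out, FRAME_COLUMNS, path)


def read_frame_table(path):
    """Read a frame table; returns ``(frames, bad_line_numbers)``."""
    return _read(path, FRAME_COLUMNS, _FRAME_NUMERIC)


def generation_table_from_records(records: pd.DataFrame,
                                  condition: str = "") -> pd.DataFrame:
    """Project analysis records onto the canonical generation schema."""
    out = records.copy()
    if "condition" not in out.columns:
        out["condition"] = condition
    return out
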