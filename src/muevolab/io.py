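"""Validated CSV input/output for the pipeline's tabular formats.

Four long-format tables flow through the pipeline:

``transfers``
    per-lineage OD600 and antibiotic concentration at each serial transfer;
``growth_curves``
    CFU/ml counts on the fixed drop-plating time grid;
``mic_plates``
    replicate dose-response ODs over an increasing concentration grid;
``colonies``
    per-colony growth flags on the four selective media.

All downstream modules consume only tables that passed validation here.
CSVs are UTF-8 with a mandatory header and dot decimal separator, matching
plate-reader export conventions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ANTIBIOTICS, CULTURE_TYPES, STRAINS, TIME_GRID_H


class SchemaError(ValueError):
    """A table violates its schema; message names the offending row/field."""


MEDIA_COLUMNS = ("mmab", "mmab_trp", "mmab_tyr", "lb")

_SCHEMAS: dict[str, list[str]] = {
    "transfers": ["lineage_id", "culture_type", "antibiotic", "transfer",
                  "od600", "concentration", "alive"],
    "growth_curves": ["replicate_id", "strain", "time_h", "cfu_per_ml"],
    "mic_plates": ["replicate_id", "culture_type", "supplemented",
                   "concentration", "od600"],
    "colonies": ["population_id", "colony_id", *MEDIA_COLUMNS],
}


def table_kinds() -> tuple[str, ...]:
    return tuple(_SCHEMAS)


def _require_columns(df: pd.DataFrame, kind: str) -> None:
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind}: missing column(s) {missing}")


def _check_numeric(df: pd.DataFrame, kind: str, col: str, *,
                   nonneg: bool = True, allow_nan: bool = False) -> None:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"{kind}: non-numeric value in field '{col}' at row {row}")
    if not allow_nan and vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise SchemaError(f"{kind}: missing value in field '{col}' at row {row}")
    if nonneg and (vals.dropna() < 0).any():
        row = int(np.flatnonzero((vals < 0).fillna(False).to_numpy())[0])
        raise SchemaError(f"{kind}: negative value in field '{col}' at row {row}")


def _check_enum(df: pd.DataFrame, kind: str, col: str, allowed) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{kind}: field '{col}' at row {row} not in {sorted(allowed)}")


def _as_bool(df: pd.DataFrame, col: str) -> pd.Series:
    mapping = {True: True, False: False, "True": True, "False": False,
               "true": True, "false": False, 1: True, 0: False, "1": True,
               "0": False}
    out = df[col].map(mapping)
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise SchemaError(f"field '{col}' at row {row} is not boolean")
    return out.astype(bool)


def validate_table(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Validate *df* against the schema *kind*; return a normalised copy.

    Raises :class:`SchemaError` naming the first offending row and field.
    Row order is preserved.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = df.copy()
    _require_columns(df, kind)

    if kind == "transfers":
        _check_enum(df, kind, "culture_type", CULTURE_TYPES)
        _check_enum(df, kind, "antibiotic", (*ANTIBIOTICS, "NONE"))
        _check_numeric(df, kind, "transfer")
        _check_numeric(df, kind, "concentration")
        df["alive"] = _as_bool(df, "alive")
        df["transfer"] = df["transfer"].astype(int)
        # a lost well (empty OD) is only tolerated on a dead lineage's row
        od = pd.to_numeric(df["od600"], errors="coerce")
        bad = od.isna() & df["alive"]
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"transfers: missing od600 at row {row} on a live lineage")
        _check_numeric(df, kind, "od600", allow_nan=True)
        df["od600"] = od
        for lid, sub in df.groupby("lineage_id", sort=False):
            t = np.sort(sub["transfer"].to_numpy())
            if not np.array_equal(t, np.arange(len(t))):
                raise SchemaError(
                    f"transfers: lineage {lid!r} transfers not contiguous from 0")
            alive = sub.sort_values("transfer")["alive"].to_numpy()
            if np.any(alive[:-1] < alive[1:]):
                raise SchemaError(
                    f"transfers: lineage {lid!r} reverts from dead to alive")

    elif kind == "growth_curves":
        _check_enum(df, kind, "strain", STRAINS)
        _check_numeric(df, kind, "time_h")
        _check_numeric(df, kind, "cfu_per_ml")
        off_grid = ~df["time_h"].astype(float).isin([float(t) for t in TIME_GRID_H])
        if off_grid.any():
            row = int(np.flatnonzero(off_grid.to_numpy())[0])
            raise SchemaError(
                f"growth_curves: time_h at row {row} not on the sampling grid")

    elif kind == "mic_plates":
        _check_enum(df, kind, "culture_type", CULTURE_TYPES)
        df["supplemented"] = _as_bool(df, "supplemented")
        _check_numeric(df, kind, "concentration")
        _check_numeric(df, kind, "od600")
        for rid, sub in df.groupby("replicate_id", sort=False):
            conc = sub["concentration"].astype(float).to_numpy()
            grid = np.unique(conc)
            if len(grid) < 2:
                raise SchemaError(
                    f"mic_plates: replicate {rid!r} needs at least 2 concentrations")
            ordered = sub["concentration"].astype(float).to_numpy()
            if np.any(np.diff(ordered) <= 0):
                raise SchemaError(
                    f"mic_plates: replicate {rid!r} concentration grid not increasing")

    elif kind == "colonies":
        for col in MEDIA_COLUMNS:
            df[col] = _as_bool(df, col)

    return df


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate a CSV table of the given kind."""
    df = pd.read_csv(path)
    return validate_table(df, kind)


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    """Validate and write a table as CSV with deterministic column order."""
    df = validate_table(df, kind)
    cols = _SCHEMAS[kind] + [c for c in df.columns if c not in _SCHEMAS[kind]]
    df[cols].to_csv(path, index=False)


def empty_table(kind: str) -> pd.DataFrame:
    return pd.DataFrame(columns=_SCHEMAS[kind])
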