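"""Readers and writers for Ct tables, sample sheets, panels and reports.

Two Ct-table dialects are supported:

* long — columns ``assay,sample[,replicate],ct``; one well per row;
* wide — first column ``assay`` (optionally a second ``replicate`` column),
  one column per sample.

The delimiter is sniffed from the extension (``.csv`` -> comma, anything else
-> tab) and can be overridden.  Cells that are empty or match a non-detection
token (``Undetermined``, ``ND``, ...) become non-detected, as do Ct values at
or above the detection cutoff.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .data import (
    ASSAY_LEVEL,
    DEFAULT_LOD_CT,
    NONDETECT_TOKENS,
    REPLICATE_LEVEL,
    CtMatrix,
    DataError,
    PanelDef,
    SampleSheet,
)

__all__ = [
    "read_ct_table",
    "write_ct_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_panel",
    "write_panel",
    "write_screen_report",
    "read_screen_report",
    "write_validation_report",
    "write_flag_report",
]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _parse_ct_cell(cell, tokens: frozenset, where: str) -> float:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    if isinstance(cell, str):
        if cell.strip().lower() in tokens:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise DataError(f"non-numeric Ct value {cell!r} at {where}") from None
    return float(cell)


def read_ct_table(
    path,
    format: str = "auto",
    sep: str | None = None,
    lod_ct: float = DEFAULT_LOD_CT,
    nondetect_tokens: Iterable[str] = NONDETECT_TOKENS,
) -> CtMatrix:
    """Read a Ct table in the long or wide dialect into a :class:`CtMatrix`.

    ``format='auto'`` treats files whose header contains both ``assay`` and
    ``ct`` columns as long, everything else as wide.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"Ct table not found: {path}")
    tokens = frozenset(t.strip().lower() for t in nondetect_tokens)
    raw = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str,
                      keep_default_na=False)
    raw.columns = [str(c).strip() for c in raw.columns]
    if format == "auto":
        format = "long" if {"assay", "sample", "ct"} <= set(raw.columns) else "wide"
    if format == "long":
        return _ct_from_long(raw, tokens, lod_ct, path)
    if format == "wide":
        return _ct_from_wide(raw, tokens, lod_ct, path)
    raise ValueError(f"unknown Ct table format {format!r}")


def _ct_from_long(raw: pd.DataFrame, tokens, lod_ct: float, path) -> CtMatrix:
    needed = {"assay", "sample", "ct"}
    if not needed <= set(raw.columns):
        raise DataError(f"long Ct table {path} must have columns {sorted(needed)}")
    df = raw.copy()
    if "replicate" not in df.columns:
        df["replicate"] = "1"
    df["replicate"] = df["replicate"].astype(int)
    keys = df[["assay", "sample", "replicate"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise DataError(f"duplicate (assay, sample, replicate) entry {dup} in {path}")
    df["ct"] = [
        _parse_ct_cell(c, tokens, f"({a},{s},{r})")
        for a, s, r, c in df[["assay", "sample", "replicate", "ct"]].itertuples(index=False)
    ]
    # pivot completes the grid: missing wells become non-detected
    wide = df.pivot(index=["assay", "replicate"], columns="sample", values="ct")
    wide = wide.reindex(pd.unique(df["assay"]), level=0)
    wide = wide[pd.unique(df["sample"])]
    wide.columns.name = None
    wide.index = wide.index.set_names([ASSAY_LEVEL, REPLICATE_LEVEL])
    return CtMatrix(wide).censor(lod_ct)


def _ct_from_wide(raw: pd.DataFrame, tokens, lod_ct: float, path) -> CtMatrix:
    if raw.shape[1] < 2 or raw.columns[0] != "assay":
        raise DataError(f"wide Ct table {path} must start with an 'assay' column")
    df = raw.copy()
    if df.shape[1] > 1 and df.columns[1] == "replicate":
        rep = df.pop("replicate").astype(int)
    else:
        rep = pd.Series(np.ones(len(df), dtype=int))
    assay = df.pop("assay")
    parsed = pd.DataFrame(
        {
            s: [_parse_ct_cell(c, tokens, f"({a},{s})") for a, c in zip(assay, df[s])]
            for s in df.columns
        }
    )
    parsed.index = pd.MultiIndex.from_arrays(
        [assay, rep], names=[ASSAY_LEVEL, REPLICATE_LEVEL]
    )
    if parsed.index.duplicated().any():
        raise DataError(f"duplicate (assay, replicate) rows in {path}")
    return CtMatrix(parsed).censor(lod_ct)


def write_ct_table(
    ct: CtMatrix,
    path,
    format: str = "long",
    sep: str | None = None,
    nondetect_token: str = "Undetermined",
) -> None:
    """Write a Ct table; non-detected wells are rendered as the given token."""
    path = Path(path)
    s = _sep_for(path, sep)
    if format == "long":
        long = ct.to_long()
        long["ct"] = long["ct"].map(
            lambda x: nondetect_token if pd.isna(x) else repr(float(x))
        )
        long.to_csv(path, sep=s, index=False)
    elif format == "wide":
        wide = ct.values.reset_index()
        for c in ct.samples:
            wide[c] = wide[c].map(
                lambda x: nondetect_token if pd.isna(x) else repr(float(x))
            )
        if ct.max_replicates == 1:
            wide = wide.drop(columns=[REPLICATE_LEVEL])
        wide.to_csv(path, sep=s, index=False)
    else:
        raise ValueError(f"unknown Ct table format {format!r}")


_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def read_sample_sheet(path, sep: str | None = None) -> SampleSheet:
    path = Path(path)
    if not path.exists():
        raise DataError(f"sample sheet not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    if not {"sample_id", "group", "calibrator"} <= set(df.columns):
        raise DataError(
            f"sample sheet {path} must have columns sample_id,group,calibrator"
        )

    def to_bool(tok: str) -> bool:
        t = tok.strip().lower()
        if t in _TRUE:
            return True
        if t in _FALSE:
            return False
        raise DataError(f"unparseable calibrator flag {tok!r} in {path}")

    df["calibrator"] = df["calibrator"].map(to_bool)
    return SampleSheet(df[["sample_id", "group", "calibrator"]])


def write_sample_sheet(sheet: SampleSheet, path, sep: str | None = None) -> None:
    path = Path(path)
    out = sheet.table.copy()
    out["calibrator"] = out["calibrator"].map(lambda b: "true" if b else "false")
    out.to_csv(path, sep=_sep_for(path, sep), index=False)


def read_panel(path) -> PanelDef:
    path = Path(path)
    if not path.exists():
        raise DataError(f"panel definition not found: {path}")
    spec = json.loads(path.read_text())
    try:
        return PanelDef(
            assays=list(spec["assays"]),
            endogenous_controls=list(spec["endogenous_controls"]),
            replicates=int(spec.get("replicates", 1)),
        )
    except KeyError as e:
        raise DataError(f"panel {path} missing key {e}") from None


def write_panel(panel: PanelDef, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "assays": list(panel.assays),
                "endogenous_controls": list(panel.endogenous_controls),
                "replicates": panel.replicates,
            },
            indent=2,
        )
        + "\n"
    )


def write_screen_report(records: pd.DataFrame, path, precision: int | None = 4) -> None:
    """Write screen records as TSV, one row per assay, Table-style schema.

    ``precision`` rounds float columns for display; ``None`` writes full
    precision (round-trippable through :func:`read_screen_report`).
    """
    if len(records) == 0:
        raise DataError("no screen records to write")
    out = records.copy()
    if precision is not None:
        float_cols = out.select_dtypes(include=[float]).columns
        out[float_cols] = out[float_cols].round(precision)
    out.to_csv(path, sep="\t", index=False)


def read_screen_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("de_call",):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_validation_report(records: pd.DataFrame, path, precision: int | None = 4) -> None:
    if len(records) == 0:
        raise DataError("no validation records to write")
    out = records.copy()
    if precision is not None:
        float_cols = out.select_dtypes(include=[float]).columns
        out[float_cols] = out[float_cols].round(precision)
    out.to_csv(path, sep="\t", index=False)


def write_flag_report(summary: pd.DataFrame, path) -> None:
    summary.reset_index().to_csv(path, sep="\t", index=False)
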