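"""Tabular I/O for every pipeline artifact.

One unambiguous dialect for all tables: tab-separated, UTF-8, header
row mandatory, ``NA`` for missing, protein id in the first column of
protein-indexed tables.  Channel labels are carried verbatim as strings
(iTRAQ reporter masses like ``113`` are names, never numbers).  The MRM
export alone is comma-separated, matching common transition-export
conventions.  Numeric columns are written with 8 significant digits so
round-tripping does not erode the statistics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import DESIGN_COLUMNS, BatchDesign, DesignError
from .normalize import ReporterTable
from .synthdata import MRM_COLUMNS, SyntheticTruth

NA = "NA"
FLOAT_FORMAT = "%.8g"


class ParseError(ValueError):
    """A file failed validation; the message names the file and line."""


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False, **kw
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise ParseError(f"{path}: cannot parse as TSV ({exc})") from exc


def _line(row_pos: int) -> int:
    """1-based file line of a 0-based data row (header occupies line 1)."""
    return row_pos + 2


# -- design ----------------------------------------------------------------

def read_design(path) -> BatchDesign:
    df = _read_tsv(path)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: design lacks columns {missing}")
    for col in DESIGN_COLUMNS:
        blank = df[col].isna()
        if blank.any():
            raise ParseError(f"{path}: line {_line(blank.idxmax())}: empty {col!r}")
    try:
        return BatchDesign(df)
    except DesignError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_design(design: BatchDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# -- reporter tables -------------------------------------------------------

def read_reporter_table(path, batch: str | None = None) -> ReporterTable:
    """Read one batch's raw or normalized reporter-ion table.

    The batch id defaults to the ``reporter_<batch>.tsv`` /
    ``normalized_<batch>.tsv`` file-name convention.
    """
    path = Path(path)
    if batch is None:
        stem = path.stem
        batch = stem.split("_", 1)[1] if "_" in stem else stem
    df = _read_tsv(path)
    if df.shape[1] < 2 or df.columns[0] != "protein_id":
        raise ParseError(f"{path}: expected 'protein_id' plus channel columns")
    dup = df["protein_id"].duplicated()
    if dup.any():
        raise ParseError(
            f"{path}: line {_line(dup.idxmax())}: duplicate protein id "
            f"{df.loc[dup.idxmax(), 'protein_id']!r}"
        )
    df = df.set_index("protein_id")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df.notna()
    if bad.any().any():
        r = int(np.argmax(bad.any(axis=1).to_numpy()))
        raise ParseError(f"{path}: line {_line(r)}: non-numeric intensity")
    neg = values < 0
    if neg.any().any():
        r = int(np.argmax(neg.any(axis=1).to_numpy()))
        raise ParseError(f"{path}: line {_line(r)}: negative intensity")
    partial = values.isna().any(axis=1) & values.notna().any(axis=1)
    if partial.any():
        r = int(np.argmax(partial.to_numpy()))
        raise ParseError(
            f"{path}: line {_line(r)}: protein present in some channels but NA in others"
        )
    values = values.dropna(axis=0, how="all")
    return ReporterTable(str(batch), values.astype(float))


def write_reporter_table(table: ReporterTable, path) -> None:
    table.intensities.to_csv(
        path, sep="\t", na_rep=NA, float_format=FLOAT_FORMAT, index_label="protein_id"
    )


def read_reporter_tables(paths: Iterable) -> list[ReporterTable]:
    return [read_reporter_table(p) for p in paths]


# -- expression matrix and stats tables ------------------------------------

def read_matrix(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "protein_id":
        raise ParseError(f"{path}: expected 'protein_id' as first column")
    df = df.set_index("protein_id")
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.any().any():
        r = int(np.argmax(bad.any(axis=1).to_numpy()))
        raise ParseError(f"{path}: line {_line(r)}: non-numeric value")
    out.columns.name = "sample_id"
    return out


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(
        path, sep="\t", na_rep=NA, float_format=FLOAT_FORMAT, index_label="protein_id"
    )


def write_stats(stats: pd.DataFrame, path) -> None:
    out = stats.copy()
    for col in ("normal_flag", "significant"):
        if col in out:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", na_rep=NA, float_format=FLOAT_FORMAT,
               index_label="protein_id")


def read_stats(path) -> pd.DataFrame:
    df = read_matrix(path)
    for col in ("normal_flag", "significant"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def write_truth(truth: SyntheticTruth, path) -> None:
    out = truth.table.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", na_rep=NA, float_format=FLOAT_FORMAT,
               index_label="protein_id")


# -- MRM -------------------------------------------------------------------

def read_mrm(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, na_values=[NA], keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: cannot parse as CSV ({exc})") from exc
    missing = [c for c in MRM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: MRM table lacks columns {missing}")
    area = pd.to_numeric(df["area"], errors="coerce")
    bad = area.isna()
    if bad.any():
        raise ParseError(f"{path}: line {_line(bad.idxmax())}: non-numeric peak area")
    if (area < 0).any():
        raise ParseError(
            f"{path}: line {_line((area < 0).idxmax())}: negative peak area"
        )
    df["area"] = area
    return df


def write_mrm(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_concordance(detail: pd.DataFrame, path) -> None:
    out = detail.copy()
    out["concordant"] = out["concordant"].astype(int)
    out.to_csv(path, sep="\t", na_rep=NA, float_format=FLOAT_FORMAT,
               index_label="protein_id")
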