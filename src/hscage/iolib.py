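"""Readers and writers for every on-disk format the pipeline touches.

Conventions
-----------
* Single-cell counts: Matrix Market triplet (``matrix.mtx`` + ``features.tsv``
  + ``barcodes.tsv`` in one directory, 1-based indices on disk, 0-based in
  memory) or a dense TSV with genes as rows.
* Peaks: BED-convention TSV (0-based, half-open) with a mandatory header.
* Everything tabular is tab- or comma-delimited with a mandatory header row;
  there is no positional parsing. Schema violations raise, never coerce.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    CellMatrix,
    ClockModel,
    CohortTables,
    FormatError,
    GeneAnnotation,
    MethylationMatrix,
    PeakTable,
    ValidationError,
)

MTX_FILES = ("matrix.mtx", "features.tsv", "barcodes.tsv")

_TABLE_SCHEMAS: dict[str, list[str]] = {
    "annotation": ["gene_id", "is_membrane"],
    "methylation": ["site", "sample", "beta", "coverage"],
    "peaks": ["chrom", "start", "end", "peak_id"],
    "clock": ["site", "weight", "training_mean"],
    "chimerism": ["mouse_id", "group", "day", "donor_fraction", "dose"],
    "lineage": ["mouse_id", "group", "b_pct", "t_pct", "myeloid_pct"],
    "tsubset": ["mouse_id", "group", "compartment", "cd44", "cd62l"],
    "survival": ["mouse_id", "group", "time", "event"],
}

INTERCEPT_SITE = "(intercept)"


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


# ---------------------------------------------------------------- cell matrix


def read_cell_matrix(path: str | Path, format: str = "mtx-triplet") -> CellMatrix:
    """Read a raw count matrix.

    ``mtx-triplet`` expects a directory with matrix.mtx, features.tsv and
    barcodes.tsv; ``dense-tsv`` expects a TSV with a ``gene_id`` first column
    and one column per cell.
    """
    path = Path(path)
    if format == "mtx-triplet":
        if not path.is_dir():
            raise FormatError(f"mtx-triplet path must be a directory: {path}")
        missing = [f for f in MTX_FILES if not (path / f).exists()]
        if missing:
            raise FormatError(f"missing companion file(s) {missing} in {path}")
        try:
            mat = scipy.io.mmread(path / "matrix.mtx")
        except ValueError as exc:
            raise FormatError(f"unreadable matrix.mtx: {exc}") from exc
        counts = sp.csr_matrix(mat)
        genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
        if counts.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix shape {counts.shape} does not match {len(genes)} features "
                f"x {len(cells)} barcodes"
            )
        if counts.nnz == 0:
            raise FormatError(f"no entries in {path / 'matrix.mtx'}")
        if counts.data.size and (np.any(counts.data < 0) or np.any(counts.data != np.round(counts.data))):
            raise ValidationError("matrix entries must be nonnegative integers")
        return CellMatrix(counts, genes, cells, layer="raw")
    if format == "dense-tsv":
        df = _read_delimited(path)
        if df.columns[0] != "gene_id":
            raise FormatError("dense-tsv requires a 'gene_id' first column")
        genes = df["gene_id"].astype(str).tolist()
        cells = [str(c) for c in df.columns[1:]]
        counts = df.iloc[:, 1:].to_numpy()
        if counts.size == 0:
            raise FormatError(f"no entries in {path}")
        return CellMatrix(sp.csr_matrix(counts), genes, cells, layer="raw")
    raise ValueError(f"unknown cell-matrix format {format!r}")


def write_cell_matrix(m: CellMatrix, path: str | Path, format: str = "mtx-triplet") -> None:
    """Write a CellMatrix so that :func:`read_cell_matrix` round-trips it."""
    m.validate()
    path = Path(path)
    if format == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        counts = m.counts if sp.issparse(m.counts) else sp.coo_matrix(m.counts)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(counts), field="integer")
        (path / "features.tsv").write_text("\n".join(m.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
    elif format == "dense-tsv":
        df = pd.DataFrame(m.dense().astype(int), columns=m.cell_ids)
        df.insert(0, "gene_id", m.gene_ids)
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown cell-matrix format {format!r}")


# -------------------------------------------------------------------- tables


def read_tables(path: str | Path, kind: str):
    """Read one of the typed tables; ``kind`` selects schema and return type."""
    if kind not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; one of {sorted(_TABLE_SCHEMAS)}")
    df = _read_delimited(path)
    required = _TABLE_SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{kind} table {path} missing required column(s) {missing}")
    if kind == "annotation":
        df["is_membrane"] = _parse_bool(df["is_membrane"])
        return GeneAnnotation(df)
    if kind == "peaks":
        return PeakTable(df)
    if kind == "methylation":
        return _methylation_from_long(df)
    if kind == "clock":
        return _clock_from_table(df)
    if kind == "chimerism":
        return CohortTables(chimerism=df).chimerism
    if kind == "lineage":
        return CohortTables(lineage=df).lineage
    if kind == "tsubset":
        return CohortTables(tsubset=df).tsubset
    if kind == "survival":
        return CohortTables(survival=df).survival
    raise AssertionError("unreachable")


def _parse_bool(col: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = col.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = col[out.isna()].unique().tolist()[:5]
        raise FormatError(f"unparseable boolean value(s) {bad}")
    return out


def _methylation_from_long(df: pd.DataFrame) -> MethylationMatrix:
    beta = df.pivot(index="site", columns="sample", values="beta")
    cov = df.pivot(index="site", columns="sample", values="coverage").fillna(0).astype(int)
    cov = cov.loc[beta.index, beta.columns]
    return MethylationMatrix(beta=beta, coverage=cov)


def _clock_from_table(df: pd.DataFrame) -> ClockModel:
    inter = df[df["site"] == INTERCEPT_SITE]
    if len(inter) != 1:
        raise FormatError(f"clock table needs exactly one '{INTERCEPT_SITE}' row, found {len(inter)}")
    body = df[df["site"] != INTERCEPT_SITE]
    unit = str(df["age_unit"].iloc[0]) if "age_unit" in df.columns else "months"
    return ClockModel(
        intercept=float(inter["weight"].iloc[0]),
        weights=pd.Series(body["weight"].to_numpy(dtype=float), index=body["site"].astype(str)),
        training_mean=pd.Series(
            body["training_mean"].to_numpy(dtype=float), index=body["site"].astype(str)
        ),
        age_unit=unit,
    )


def write_table(df_or_obj, path: str | Path, kind: str) -> None:
    """Write one of the typed tables in the format read_tables expects."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if kind == "annotation":
        df = df_or_obj.table if isinstance(df_or_obj, GeneAnnotation) else df_or_obj
    elif kind == "peaks":
        df = df_or_obj.table if isinstance(df_or_obj, PeakTable) else df_or_obj
    elif kind == "methylation":
        m: MethylationMatrix = df_or_obj
        df = (
            m.beta.stack(future_stack=True)
            .rename("beta")
            .to_frame()
            .join(m.coverage.stack(future_stack=True).rename("coverage"))
            .reset_index()
        )
        df.columns = ["site", "sample", "beta", "coverage"]
    elif kind == "clock":
        c: ClockModel = df_or_obj
        rows = [{"site": INTERCEPT_SITE, "weight": c.intercept, "training_mean": np.nan}]
        for s in c.sites:
            rows.append(
                {"site": s, "weight": c.weights[s], "training_mean": c.training_mean[s]}
            )
        df = pd.DataFrame(rows)
        df["age_unit"] = c.age_unit
    elif kind in ("chimerism", "lineage", "tsubset", "survival"):
        df = df_or_obj
    else:
        raise ValueError(f"unknown table kind {kind!r}")
    df.to_csv(path, sep=sep, index=False)


def write_cohort(tables: CohortTables, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("chimerism", "lineage", "tsubset", "survival"):
        df = getattr(tables, name)
        if df is not None:
            write_table(df, directory / f"{name}.csv", name)


def read_cohort(directory: str | Path, groups: tuple[str, ...] = ()) -> CohortTables:
    directory = Path(directory)
    parts = {}
    for name in ("chimerism", "lineage", "tsubset", "survival"):
        f = directory / f"{name}.csv"
        if f.exists():
            parts[name] = read_tables(f, name)
    return CohortTables(groups=groups, **parts)
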