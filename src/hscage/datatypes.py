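"""Core in-memory containers shared by every stage of the pipeline.

All containers are plain dataclasses around numpy/pandas objects with a
``validate()`` method enforcing the structural invariants the readers and
generators promise (unique identifiers, value ranges, aligned metadata).
Validation raises :class:`ValidationError`; nothing is silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ValidationError(ValueError):
    """A container violated one of its declared invariants."""


class FormatError(ValueError):
    """An on-disk file does not conform to its declared schema."""


def _check_unique(ids, what: str) -> None:
    arr = np.asarray(ids)
    if arr.size != pd.unique(arr).size:
        dupes = pd.Series(arr).value_counts()
        dupes = dupes[dupes > 1].index.tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class CellMatrix:
    """Genes x cells integer count matrix with aligned metadata.

    ``counts`` may be dense or scipy-sparse; values must be finite,
    nonnegative integers. ``cell_meta`` is indexed by ``cell_ids`` and may
    carry ``condition`` ('young'/'old'), ``cluster`` and QC columns.
    ``layer`` records whether the values are raw counts or log-normalized.
    """

    counts: "sp.spmatrix | np.ndarray"
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = None
    layer: str = "raw"

    def __post_init__(self):
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def validate(self) -> "CellMatrix":
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        data = self.counts.data if sp.issparse(self.counts) else np.asarray(self.counts)
        if data.size:
            is_int = np.issubdtype(data.dtype, np.integer)
            if not is_int and not np.all(np.isfinite(data)):
                raise ValidationError("counts contain non-finite values")
            if self.layer == "raw":
                if np.any(data < 0):
                    raise ValidationError("counts contain negative values")
                if not is_int and not np.array_equal(data, np.round(data)):
                    raise ValidationError("raw counts must be integers")
        if len(self.cell_meta) != len(self.cell_ids) or list(self.cell_meta.index) != list(
            self.cell_ids
        ):
            raise ValidationError("cell_meta rows do not align 1:1 with cell_ids")
        if self.layer not in ("raw", "lognorm"):
            raise ValidationError(f"unknown layer tag {self.layer!r}")
        return self

    def subset_cells(self, mask_or_ids) -> "CellMatrix":
        """New CellMatrix restricted to the given boolean mask or cell-id list."""
        if isinstance(mask_or_ids, (list, pd.Index)):
            keep = np.isin(np.asarray(self.cell_ids), np.asarray(mask_or_ids))
        else:
            keep = np.asarray(mask_or_ids, dtype=bool)
        counts = self.counts.tocsc()[:, keep].tocsr() if sp.issparse(self.counts) else self.counts[:, keep]
        ids = [c for c, k in zip(self.cell_ids, keep) if k]
        return CellMatrix(counts, list(self.gene_ids), ids, self.cell_meta.loc[keep].copy(), self.layer)


@dataclass
class NormalizedMatrix:
    """Log-normalized expression (genes x cells), natural log of 1 + CP-`scale`.

    Zero raw counts stay exactly zero, so sparsity is preserved.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame
    scale: float = 1e4
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("normalized values shape mismatch")
        if np.any(self.values < 0):
            raise ValidationError("log-normalized values must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        idx = pd.Index(self.gene_ids)
        pos = idx.get_indexer(list(genes))
        return pos

    def subset_cells(self, mask) -> "NormalizedMatrix":
        keep = np.asarray(mask, dtype=bool)
        ids = [c for c, k in zip(self.cell_ids, keep) if k]
        return NormalizedMatrix(
            self.values[:, keep], list(self.gene_ids), ids, self.cell_meta.loc[keep].copy(), self.scale, self.source
        )


@dataclass
class GeneAnnotation:
    """Per-gene attributes; minimally a membrane-localization flag."""

    table: pd.DataFrame  # columns: gene_id, is_membrane[, description]

    def __post_init__(self):
        required = {"gene_id", "is_membrane"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"annotation requires columns {sorted(required)}")
        _check_unique(self.table["gene_id"].to_numpy(), "annotation gene ids")
        if self.table["is_membrane"].isna().any():
            raise ValidationError("is_membrane must be defined for every gene")
        self.table = self.table.reset_index(drop=True)
        self.table["is_membrane"] = self.table["is_membrane"].astype(bool)

    @property
    def membrane_genes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["is_membrane"], "gene_id"])

    def is_membrane(self, gene: str) -> bool:
        t = self.table
        hit = t.loc[t["gene_id"] == gene, "is_membrane"]
        return bool(hit.iloc[0]) if len(hit) else False


@dataclass
class PeakTable:
    """BED-convention peak intervals: 0-based half-open [start, end)."""

    table: pd.DataFrame  # chrom, start, end, peak_id [+ per-sample signal columns]

    def __post_init__(self):
        required = ["chrom", "start", "end", "peak_id"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"peak table missing columns {missing}")
        t = self.table
        if (t["start"] < 0).any():
            raise ValidationError("peak coordinates must be nonnegative")
        if (t["start"] >= t["end"]).any():
            bad = t.loc[t["start"] >= t["end"], "peak_id"].tolist()[:5]
            raise ValidationError(f"start >= end for peaks {bad}")
        _check_unique(t["peak_id"].to_numpy(), "peak ids")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def signal_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("chrom", "start", "end", "peak_id")]


@dataclass
class MethylationMatrix:
    """Per-(CpG site, sample) methylation fraction and read coverage.

    ``beta`` and ``coverage`` are sites x samples DataFrames sharing index
    (site ids ``chrom:position``) and columns (sample ids). beta is NaN
    wherever coverage is zero (or has been masked by a coverage filter).
    """

    beta: pd.DataFrame
    coverage: pd.DataFrame

    def __post_init__(self):
        if not self.beta.index.equals(self.coverage.index) or not self.beta.columns.equals(
            self.coverage.columns
        ):
            raise ValidationError("beta and coverage must share index and columns")
        _check_unique(self.beta.index.to_numpy(), "CpG site ids")
        b = self.beta.to_numpy(dtype=float)
        cov = self.coverage.to_numpy()
        if np.any(cov < 0):
            raise ValidationError("coverage must be >= 0")
        observed = ~np.isnan(b)
        if np.any((b[observed] < 0) | (b[observed] > 1)):
            raise ValidationError("beta values must lie in [0, 1]")
        if np.any(observed & (cov == 0)):
            raise ValidationError("beta present where coverage is 0")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def sites(self) -> list[str]:
        return list(self.beta.index)


@dataclass
class ClockModel:
    """Linear DNA-methylation age predictor.

    ``age = intercept + sum_i weight_i * beta_i`` over clock sites; sites
    absent from a sample are imputed with the clock's training-mean beta.
    """

    intercept: float
    weights: pd.Series  # indexed by site id
    training_mean: pd.Series  # indexed by site id, in [0, 1]
    age_unit: str = "months"

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights.to_numpy(dtype=float))):
            raise ValidationError("clock weights must be finite")
        _check_unique(self.weights.index.to_numpy(), "clock site ids")
        if not self.weights.index.equals(self.training_mean.index):
            raise ValidationError("weights and training_mean must share site index")
        tm = self.training_mean.to_numpy(dtype=float)
        if np.any((tm < 0) | (tm > 1)):
            raise ValidationError("training-mean beta must lie in [0, 1]")

    @property
    def sites(self) -> list[str]:
        return list(self.weights.index)


@dataclass
class CohortTables:
    """In-vivo cohort readouts for transplantation analytics.

    chimerism: mouse_id, group, day, donor_fraction, dose
    lineage:   mouse_id, group, b_pct, t_pct, myeloid_pct
    tsubset:   mouse_id, group, compartment (CD4/CD8), cd44, cd62l
    survival:  mouse_id, group, time, event (1 death / 0 censored)
    """

    chimerism: pd.DataFrame = None
    lineage: pd.DataFrame = None
    tsubset: pd.DataFrame = None
    survival: pd.DataFrame = None
    groups: tuple[str, ...] = ()

    _SCHEMAS = {
        "chimerism": ["mouse_id", "group", "day", "donor_fraction", "dose"],
        "lineage": ["mouse_id", "group", "b_pct", "t_pct", "myeloid_pct"],
        "tsubset": ["mouse_id", "group", "compartment", "cd44", "cd62l"],
        "survival": ["mouse_id", "group", "time", "event"],
    }

    def __post_init__(self):
        for name, cols in self._SCHEMAS.items():
            df = getattr(self, name)
            if df is None:
                continue
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValidationError(f"{name} table missing columns {missing}")
            if self.groups and not set(df["group"]).issubset(self.groups):
                extra = sorted(set(df["group"]) - set(self.groups))
                raise ValidationError(f"{name} has undeclared groups {extra}")
        if self.chimerism is not None:
            f = self.chimerism["donor_fraction"].to_numpy(dtype=float)
            if np.any((f < 0) | (f > 1)):
                raise ValidationError("donor fractions must lie in [0, 1]")
            if (self.chimerism["day"] < 0).any():
                raise ValidationError("chimerism days must be >= 0")
        if self.survival is not None:
            if (self.survival["time"] < 0).any():
                raise ValidationError("survival times must be >= 0")
            if not set(self.survival["event"].unique()).issubset({0, 1}):
                raise ValidationError("survival event must be 0 (censored) or 1 (death)")
        if self.lineage is not None:
            s = self.lineage[["b_pct", "t_pct", "myeloid_pct"]].sum(axis=1)
            if np.any(np.abs(s - 100) > 1.0):
                raise ValidationError("lineage percentages must sum to 100 (+- 1)")
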