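"""Cell QC, log-normalization, variable-gene selection and clustering.

The QC defaults are the standard filters for freshly isolated HSCs: cells
with fewer than 800 detected genes or more than 5% mitochondrial transcripts
are removed. "Below 800" is strict — a cell with exactly 800 detected genes
is kept. Normalization is the usual log1p of counts-per-`scale` (natural
log). Clustering is deliberately minimal: PCA on z-scored variable genes
followed by seeded k-means, enough to label quiescent subclusters; external
labels can bypass it entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .datatypes import CellMatrix, NormalizedMatrix, ValidationError


@dataclass
class QCReport:
    n_input: int
    n_removed_low_features: int
    n_removed_high_mito: int
    n_kept: int


def qc_filter(
    m: CellMatrix,
    min_features: int = 800,
    max_mito_pct: float = 5.0,
    mito_prefix: str = "mt-",
    return_report: bool = False,
):
    """Remove low-complexity and high-mitochondrial cells.

    Keeps cells with detected-gene count >= ``min_features`` and
    mitochondrial fraction <= ``max_mito_pct`` percent. Cell order is
    preserved; an empty result raises.
    """
    if m.layer != "raw":
        raise ValidationError("qc_filter requires the raw layer")
    counts = m.counts
    if sp.issparse(counts):
        detected = np.asarray((counts > 0).sum(axis=0)).ravel()
        totals = np.asarray(counts.sum(axis=0)).ravel()
        mito_mask = np.array([g.startswith(mito_prefix) for g in m.gene_ids])
        mito_counts = np.asarray(counts[mito_mask].sum(axis=0)).ravel() if mito_mask.any() else np.zeros_like(totals)
    else:
        arr = np.asarray(counts)
        detected = (arr > 0).sum(axis=0)
        totals = arr.sum(axis=0)
        mito_mask = np.array([g.startswith(mito_prefix) for g in m.gene_ids])
        mito_counts = arr[mito_mask].sum(axis=0) if mito_mask.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * mito_counts / totals, 0.0)

    low = detected < min_features
    himito = mito_pct > max_mito_pct
    keep = ~(low | himito)
    if not keep.any():
        raise ValidationError("empty after QC: all cells removed")
    out = m.subset_cells(keep)
    out.cell_meta = out.cell_meta.assign(
        n_features=detected[keep], pct_mito=mito_pct[keep]
    )
    report = QCReport(
        n_input=m.n_cells,
        n_removed_low_features=int(low.sum()),
        n_removed_high_mito=int((himito & ~low).sum()),
        n_kept=int(keep.sum()),
    )
    return (out, report) if return_report else out


def lognormalize(m: CellMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """value = ln(1 + count / cell_total * scale); zeros stay zero."""
    if m.layer != "raw":
        raise ValidationError("lognormalize requires the raw layer")
    counts = m.dense().astype(float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        bad = [c for c, t in zip(m.cell_ids, totals) if t == 0]
        raise ValidationError(f"cell(s) with zero total counts: {bad[:5]}")
    values = np.log1p(counts / totals[None, :] * scale)
    return NormalizedMatrix(
        values, list(m.gene_ids), list(m.cell_ids), m.cell_meta.copy(), scale=scale
    )


def select_hvg(nm: NormalizedMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-``n`` highly variable genes by binned-dispersion z-score.

    The variance of each gene's log-normalized expression is standardized
    against genes of similar mean (equal-occupancy mean bins), so selection
    is not simply by expression level. Ties break by gene id for
    determinism.
    """
    if n > nm.n_genes:
        raise ValueError(f"requested {n} HVGs but only {nm.n_genes} genes present")
    means = nm.values.mean(axis=1)
    variances = nm.values.var(axis=1, ddof=1) if nm.n_cells > 1 else np.zeros(nm.n_genes)

    order = np.argsort(means, kind="stable")
    bins = np.empty(nm.n_genes, dtype=int)
    bins[order] = np.minimum(np.arange(nm.n_genes) * n_bins // nm.n_genes, n_bins - 1)
    z = np.zeros(nm.n_genes)
    for b in range(n_bins):
        in_b = bins == b
        if not in_b.any():
            continue
        v = variances[in_b]
        sd = v.std()
        z[in_b] = (v - v.mean()) / sd if sd > 0 else 0.0
    # constant genes can never outrank genes with positive variance
    z[variances == 0] = -np.inf

    df = pd.DataFrame({"gene": nm.gene_ids, "z": z, "var": variances})
    df = df.sort_values(["z", "gene"], ascending=[False, True], kind="stable")
    return df["gene"].head(n).tolist()


def cluster_cells(
    nm: NormalizedMatrix,
    k: int,
    n_pcs: int = 20,
    seed: int = 0,
    hvg: list[str] | None = None,
) -> pd.Series:
    """Seeded PCA + k-means labels 0..k-1 for every cell."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > nm.n_cells:
        raise ValueError(f"k={k} exceeds {nm.n_cells} cells")
    if k == 1:
        return pd.Series(np.zeros(nm.n_cells, dtype=int), index=nm.cell_ids, name="cluster")
    genes = hvg if hvg is not None else list(nm.gene_ids)
    idx = nm.gene_index(genes)
    idx = idx[idx >= 0]
    x = nm.values[idx].T  # cells x genes
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    xz = (x - mu) / sd
    n_pcs = min(n_pcs, xz.shape[0] - 1, xz.shape[1])
    pcs = PCA(n_components=n_pcs, random_state=seed, svd_solver="full").fit_transform(xz)
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(pcs)
    return pd.Series(labels, index=nm.cell_ids, name="cluster")
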