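"""Gene-set signature scoring and cell-cycle phase assignment.

The aging score of a cell is the mean, over a set of aging-upregulated
genes, of that gene's z-scored log-normalized expression across all cells.
z-mean scoring is deterministic and bin-free; it ranks cells the same way
as control-bin module scores for the separations this pipeline tests, and
the ``method`` tag on the result leaves room for variants. Genes with zero
variance contribute 0 rather than NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NormalizedMatrix, ValidationError


@dataclass
class SignatureScoreVector:
    scores: pd.Series  # per cell (or sample)
    genes_used: list[str]
    genes_missing: list[str] = field(default_factory=list)
    method: str = "zmean"

    def __len__(self) -> int:
        return len(self.scores)


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    out = np.zeros_like(values, dtype=float)
    np.divide(values - mu, sd, out=out, where=sd > 0)
    return out


def signature_score(nm: NormalizedMatrix, genes) -> SignatureScoreVector:
    """Per-cell mean of across-cell z-scores over the gene set.

    Warns about set members absent from the matrix; errors if none remain.
    Invariant to gene order and to per-cell library-size changes already
    absorbed by normalization.
    """
    genes = sorted(set(genes))
    idx = pd.Index(nm.gene_ids)
    pos = idx.get_indexer(genes)
    missing = [g for g, p in zip(genes, pos) if p < 0]
    present = [g for g, p in zip(genes, pos) if p >= 0]
    if not present:
        raise ValidationError("no gene of the signature is present in the matrix")
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing[:10]}", stacklevel=2)
    z = _zscore_rows(nm.values[pos[pos >= 0]])
    scores = pd.Series(z.mean(axis=0), index=nm.cell_ids, name="score")
    return SignatureScoreVector(scores=scores, genes_used=present, genes_missing=missing)


def relative_cluster_expression(
    nm: NormalizedMatrix,
    marker_sets: dict[str, list[str]],
    group_labels: pd.Series,
    reference_group: str,
) -> pd.DataFrame:
    """Mean set expression per group, normalized to the reference group mean.

    For each named gene set, each cell's set-mean log-normalized expression
    is averaged within groups and divided by the reference group's mean;
    group-vs-reference p-values come from a two-sided Wilcoxon rank-sum on
    the per-cell set means.
    """
    labels = group_labels.reindex(nm.cell_ids)
    if labels.isna().any():
        raise ValidationError("group_labels must cover every cell")
    groups = list(pd.unique(labels))
    if reference_group not in groups:
        raise ValidationError(f"reference group {reference_group!r} is empty or absent")
    idx = pd.Index(nm.gene_ids)
    rows = []
    for set_name, genes in marker_sets.items():
        pos = idx.get_indexer(sorted(set(genes)))
        pos = pos[pos >= 0]
        if pos.size == 0:
            raise ValidationError(f"gene set {set_name!r} has no genes in the matrix")
        per_cell = nm.values[pos].mean(axis=0)
        ref_vals = per_cell[(labels == reference_group).to_numpy()]
        ref_mean = ref_vals.mean()
        for g in groups:
            vals = per_cell[(labels == g).to_numpy()]
            if g == reference_group:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(vals, ref_vals, alternative="two-sided").pvalue)
            rel = vals.mean() / ref_mean if ref_mean != 0 else np.nan
            rows.append(
                {
                    "set": set_name,
                    "group": g,
                    "relative_expression": rel,
                    "mean": vals.mean(),
                    "n_cells": int(vals.size),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def assign_cell_cycle(
    nm: NormalizedMatrix, s_genes, g2m_genes
) -> pd.Series:
    """Assign each cell a phase in {S, G2M, G0G1}.

    S and G2/M signature scores are computed; a cell is assigned the
    higher-scoring phase when that score exceeds 0 (i.e., the phase genes
    are expressed above the dataset average), otherwise G0/G1. An exact
    positive tie also yields G0G1 — the documented conservative rule.
    """
    s_score = signature_score(nm, s_genes).scores.to_numpy()
    g2m_score = signature_score(nm, g2m_genes).scores.to_numpy()
    phase = np.full(nm.n_cells, "G0G1", dtype=object)
    s_wins = (s_score > 0) & (s_score > g2m_score)
    g2m_wins = (g2m_score > 0) & (g2m_score > s_score)
    phase[s_wins] = "S"
    phase[g2m_wins] = "G2M"
    return pd.Series(phase, index=nm.cell_ids, name="phase")
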