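"""Surface-marker prioritization cascade and marker feature-gene scores.

The cascade mirrors the staged search for a sortable marker of aging
heterogeneity in old HSCs:

1. rank all genes by Pearson correlation of their log-normalized
   expression with the per-cell aging score and keep the top K (default
   150);
2. intersect with the aging-upregulated gene set;
3. require membrane localization (sortability);
4. require lower expression in the "younger" target cluster (q3-like)
   than in EACH aged cluster, backed by a one-sided rank-sum test against
   the pooled aged clusters.

Stage sets are strictly nested; final candidates are ranked by their
aging-score correlation. The downstream feature-gene derivation correlates
bulk expression across marker-level quartile samples with the marker's
protein level and splits genes into positively / negatively tracking sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneAnnotation, NormalizedMatrix, ValidationError
from .signatures import SignatureScoreVector, signature_score


@dataclass
class CandidateReport:
    correlations: pd.Series  # per gene r with the aging score
    stage1: list[str]
    stage2: list[str]
    stage3: list[str]
    stage4: list[str]
    final: list[str]  # stage4 ranked by r descending
    stage4_pvalues: pd.Series = None
    params: dict = field(default_factory=dict)

    def stage_sizes(self) -> dict[str, int]:
        return {
            "stage1_top_corr": len(self.stage1),
            "stage2_aging_up": len(self.stage2),
            "stage3_membrane": len(self.stage3),
            "stage4_low_in_target": len(self.stage4),
            "final": len(self.final),
        }

    def check_nesting(self) -> bool:
        return (
            set(self.stage2) <= set(self.stage1)
            and set(self.stage3) <= set(self.stage2)
            and set(self.stage4) <= set(self.stage3)
            and set(self.final) <= set(self.stage4)
        )


@dataclass
class FeatureGeneSets:
    positive: list[str]
    negative: list[str]
    correlations: pd.Series
    threshold: float

    def __post_init__(self):
        if set(self.positive) & set(self.negative):
            raise ValidationError("positive and negative feature sets must be disjoint")


def pearson_matrix(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of ``values`` (features x obs) with ``y``.

    Constant rows get r = 0 (flagged by callers); computed by direct
    summation in float64.
    """
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    ysd = np.sqrt(np.sum(yc**2))
    if ysd == 0:
        raise ValidationError("score/level has zero variance")
    xc = values - values.mean(axis=1, keepdims=True)
    xsd = np.sqrt(np.sum(xc**2, axis=1))
    num = xc @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (xsd * ysd)
    r[xsd == 0] = 0.0
    return r


def correlate_genes_with_score(
    nm: NormalizedMatrix,
    score: "SignatureScoreVector | pd.Series",
    cells_subset=None,
    min_cells: int = 10,
) -> pd.Series:
    """Pearson r of every gene's expression with the score across cells."""
    s = score.scores if isinstance(score, SignatureScoreVector) else score
    if cells_subset is not None:
        keep = pd.Index(nm.cell_ids).isin(pd.Index(cells_subset))
    else:
        keep = np.ones(nm.n_cells, dtype=bool)
    if keep.sum() < min_cells:
        raise ValidationError(f"need at least {min_cells} cells for gene-score correlation")
    y = s.reindex(np.asarray(nm.cell_ids)[keep]).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("score does not cover all requested cells")
    r = pearson_matrix(nm.values[:, keep], y)
    return pd.Series(r, index=nm.gene_ids, name="r")


def run_cascade(
    nm: NormalizedMatrix,
    cluster_labels: pd.Series,
    aging_up_genes,
    annotation: GeneAnnotation,
    target_cluster,
    aged_clusters,
    K: int = 150,
    stage4_alpha: float = 0.05,
    rank_by: str = "signed",
    cells_subset=None,
    aging_score: pd.Series | None = None,
) -> CandidateReport:
    """Run the four-stage marker-prioritization cascade.

    ``aging_up_genes`` is the externally derived aging-upregulated set
    (both stage-2 filter and, by default, the gene set behind the aging
    score). ``rank_by`` is 'signed' (default: most positively correlated)
    or 'absolute'.
    """
    if K > nm.n_genes:
        raise ValidationError(f"K={K} exceeds {nm.n_genes} genes")
    labels = cluster_labels.reindex(nm.cell_ids)
    aged_clusters = list(aged_clusters)
    in_target = (labels == target_cluster).to_numpy()
    if not in_target.any():
        raise ValidationError(f"target cluster {target_cluster!r} is empty")
    for c in aged_clusters:
        if not (labels == c).any():
            raise ValidationError(f"aged cluster {c!r} is empty")

    if aging_score is None:
        aging_score = signature_score(nm, aging_up_genes).scores
    r = correlate_genes_with_score(nm, aging_score, cells_subset=cells_subset)

    key = r.abs() if rank_by == "absolute" else r
    ranked = key.sort_values(ascending=False, kind="stable")
    # deterministic tie handling at the K boundary: sort by (-key, gene id)
    order = sorted(ranked.index, key=lambda g: (-key[g], g))
    stage1 = order[:K]

    aging_up = set(aging_up_genes)
    stage2 = [g for g in stage1 if g in aging_up]
    membrane = annotation.membrane_genes
    stage3 = [g for g in stage2 if g in membrane]

    aged_mask = labels.isin(aged_clusters).to_numpy()
    gidx = pd.Index(nm.gene_ids)
    stage4, pvals = [], {}
    for g in stage3:
        x = nm.values[gidx.get_loc(g)]
        tgt = x[in_target]
        lower_than_each = all(
            tgt.mean() < x[(labels == c).to_numpy()].mean() for c in aged_clusters
        )
        p = float(stats.mannwhitneyu(tgt, x[aged_mask], alternative="less").pvalue)
        pvals[g] = p
        if lower_than_each and p < stage4_alpha:
            stage4.append(g)

    final = sorted(stage4, key=lambda g: (-key[g], g))
    return CandidateReport(
        correlations=r,
        stage1=stage1,
        stage2=stage2,
        stage3=stage3,
        stage4=stage4,
        final=final,
        stage4_pvalues=pd.Series(pvals, dtype=float),
        params={
            "K": K,
            "target_cluster": target_cluster,
            "aged_clusters": aged_clusters,
            "stage4_alpha": stage4_alpha,
            "rank_by": rank_by,
        },
    )


def quartile_bins(marker_levels, n_bins: int = 4) -> pd.Series:
    """Equal-frequency bins G1..G<n> by ascending marker level.

    Ties resolve by stable input order; bin sizes differ by at most 1.
    """
    levels = pd.Series(marker_levels)
    if len(levels) < n_bins:
        raise ValidationError(f"need at least {n_bins} values for {n_bins} bins")
    if levels.nunique() == 1:
        warnings.warn("all marker levels equal; binning by input order", stacklevel=2)
    order = np.argsort(levels.to_numpy(), kind="stable")
    n = len(levels)
    # split positions so bin sizes differ by <= 1 (earlier bins get extras)
    sizes = [n // n_bins + (1 if i < n % n_bins else 0) for i in range(n_bins)]
    labels = np.empty(n, dtype=object)
    start = 0
    for b, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = f"G{b}"
        start += size
    return pd.Series(labels, index=levels.index, name="bin")


def marker_correlated_sets(
    bulk_counts: pd.DataFrame,
    marker_levels,
    r_threshold: float = 0.7,
) -> FeatureGeneSets:
    """Genes whose bulk log2(CPM+1) expression strongly tracks marker level.

    Pearson r per gene across samples; positive set = {r >= threshold},
    negative set = {r <= -threshold}.
    """
    levels = pd.Series(marker_levels).reindex(bulk_counts.columns)
    if levels.isna().any():
        raise ValidationError("marker level missing for some samples")
    if len(levels) < 8 or levels.nunique() < 3:
        raise ValidationError("need >= 8 samples spanning >= 3 distinct marker levels")
    if levels.nunique() == 1:
        raise ValidationError("marker level is constant")
    mat = bulk_counts.to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    if np.any(totals == 0):
        raise ValidationError("sample with zero total counts")
    log_cpm = np.log2(mat / totals[None, :] * 1e6 + 1.0)
    r = pearson_matrix(log_cpm, levels.to_numpy(dtype=float))
    rs = pd.Series(r, index=bulk_counts.index, name="r")
    positive = rs.index[rs >= r_threshold].tolist()
    negative = rs.index[rs <= -r_threshold].tolist()
    return FeatureGeneSets(positive=positive, negative=negative, correlations=rs, threshold=r_threshold)


def feature_score_correlation(
    nm: NormalizedMatrix,
    feature_genes,
    aging_genes,
    cells_subset=None,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson R (with two-sided p) between the marker feature score and the
    aging score across cells; also returns the per-cell scatter table."""
    fs = signature_score(nm, feature_genes).scores
    ag = signature_score(nm, aging_genes).scores
    if cells_subset is not None:
        fs = fs.loc[fs.index.isin(pd.Index(cells_subset))]
        ag = ag.reindex(fs.index)
    res = stats.pearsonr(fs.to_numpy(), ag.to_numpy())
    scatter = pd.DataFrame({"feature_score": fs, "aging_score": ag})
    return float(res.statistic), float(res.pvalue), scatter
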