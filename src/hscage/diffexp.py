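"""Differential expression / accessibility testing and peak utilities.

Two testing routes:

* single-cell: two-sided Wilcoxon rank-sum on log-normalized expression,
  pre-filtered by detection fraction (min.pct) and natural-log fold change,
  BH-adjusted over the tested genes. The rank-sum p-value uses the normal
  approximation with tie correction and continuity correction, switching to
  exact enumeration of all label assignments when both groups have <= 10
  observations (ties handled via midranks in both routes).
* bulk / ATAC: per-feature Welch t-test on log2(CPM+1). RNA calls use the
  BH-adjusted p with a fold-change-of-2 gate; ATAC peak calls use the raw p
  with a fold-change-of-1.5 gate — the raw-p criterion for peaks is an
  intentional asymmetry carried over from the upstream protocol and is
  flagged in the record's ``p_criterion`` tag.

Peak intervals follow the BED convention (0-based half-open); "overlap"
means at least one shared base.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import PeakTable, ValidationError

EXACT_MAX_N = 10

DE_COLUMNS = [
    "feature",
    "log_fc",
    "fold_change",
    "p_value",
    "p_adjusted",
    "pct_a",
    "pct_b",
    "direction",
    "significant",
    "convention",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------ rank-sum test


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = EXACT_MAX_N) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; returns (rank-sum W of x, p-value).

    Exact route (both groups <= ``exact_max_n``): enumerate all
    C(n+m, n) label assignments of the midranks and report the fraction
    with |W - E[W]| at least as large as observed. Otherwise: normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n].sum())
    mu = n * (n + m + 1) / 2.0
    if n <= exact_max_n and m <= exact_max_n:
        obs = abs(w - mu)
        total = comb(n + m, n)
        hits = 0
        for idx in combinations(range(n + m), n):
            if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
                hits += 1
        return w, hits / total
    N = n + m
    tie = _tie_term(pooled)
    var = n * m / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)  # continuity-corrected
    z = max(z, 0.0)
    return w, float(2.0 * stats.norm.sf(z))


def _resolve_groups(nm, group_a, group_b) -> tuple[np.ndarray, np.ndarray]:
    ids = pd.Index(nm.cell_ids)

    def to_mask(g):
        g = np.asarray(g)
        if g.dtype == bool:
            return g
        return ids.isin(g)

    return to_mask(group_a), to_mask(group_b)


def wilcoxon_de(
    nm,
    group_a,
    group_b,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    min_pct_mode: str = "either",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between two cell groups on log-normalized data.

    Genes enter testing when detected in at least ``min_pct`` of cells in
    one group (``min_pct_mode='either'``, the standard reading; 'both'
    requires both groups) and their |lnFC| >= ``logfc_threshold``, where
    lnFC = ln((mean(expm1(x_A)) + 1) / (mean(expm1(x_B)) + 1)). BH
    adjustment runs over the tested genes only.
    """
    mask_a, mask_b = _resolve_groups(nm, group_a, group_b)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValidationError("each group needs at least 3 cells")
    A = nm.values[:, mask_a]
    B = nm.values[:, mask_b]
    pct_a = (A > 0).mean(axis=1)
    pct_b = (B > 0).mean(axis=1)
    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(B).mean(axis=1)
    lnfc = np.log((mean_a + 1.0) / (mean_b + 1.0))

    if min_pct_mode == "either":
        pct_ok = (pct_a >= min_pct) | (pct_b >= min_pct)
    elif min_pct_mode == "both":
        pct_ok = (pct_a >= min_pct) & (pct_b >= min_pct)
    else:
        raise ValueError("min_pct_mode must be 'either' or 'both'")
    tested = pct_ok & (np.abs(lnfc) >= logfc_threshold)
    if not tested.any():
        warnings.warn("no genes pass the min.pct / logfc prefilters", stacklevel=2)
        return pd.DataFrame(columns=DE_COLUMNS)

    idx = np.flatnonzero(tested)
    n_a, n_b = A.shape[1], B.shape[1]
    if n_a <= EXACT_MAX_N and n_b <= EXACT_MAX_N:
        pvals = np.array([rank_sum_test(A[i], B[i])[1] for i in idx])
    else:
        pvals = _rank_sum_p_asymptotic(A[idx], B[idx])
    padj = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "feature": np.asarray(nm.gene_ids)[idx],
            "log_fc": lnfc[idx],
            "fold_change": np.exp(lnfc[idx]),
            "p_value": pvals,
            "p_adjusted": padj,
            "pct_a": pct_a[idx],
            "pct_b": pct_b[idx],
            "direction": np.where(lnfc[idx] > 0, "up", "down"),
            "significant": padj < alpha,
            "convention": "ln-sc",
        }
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def _rank_sum_p_asymptotic(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation rank-sum p per row."""
    n, m = A.shape[1], B.shape[1]
    N = n + m
    pooled = np.concatenate([A, B], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    w = ranks[:, :n].sum(axis=1)
    mu = n * (N + 1) / 2.0
    ties = np.array([_tie_term(row) for row in pooled])
    var = n * m / 12.0 * ((N + 1) - ties / (N * (N - 1)))
    z = np.zeros_like(w, dtype=float)
    ok = var > 0
    z[ok] = np.maximum(np.abs(w[ok] - mu) - 0.5, 0.0) / np.sqrt(var[ok])
    p = 2.0 * stats.norm.sf(z)
    p[~ok] = 1.0
    return np.minimum(p, 1.0)


# ------------------------------------------------------------------ bulk DE


def _welch_de(
    counts: pd.DataFrame,
    groups,
    group_a: str,
    group_b: str,
    fc_threshold: float,
    alpha: float,
    p_criterion: str,
    convention: str,
) -> pd.DataFrame:
    groups = pd.Series(groups, index=counts.columns) if not isinstance(groups, pd.Series) else groups
    mask_a = (groups == group_a).to_numpy()
    mask_b = (groups == group_b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValidationError("each group needs at least 2 replicates")
    mat = counts.to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    if np.any(totals == 0):
        raise ValidationError("sample with zero total counts")
    cpm = mat / totals[None, :] * 1e6
    log_cpm = np.log2(cpm + 1.0)
    A, B = log_cpm[:, mask_a], log_cpm[:, mask_b]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_ind(A, B, axis=1, equal_var=False)
    pvals = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)
    padj = bh_adjust(pvals)
    mean_a = cpm[:, mask_a].mean(axis=1)
    mean_b = cpm[:, mask_b].mean(axis=1)
    fc = (mean_a + 1.0) / (mean_b + 1.0)
    p_for_call = padj if p_criterion == "adjusted" else pvals
    significant = (p_for_call < alpha) & ((fc > fc_threshold) | (fc < 1.0 / fc_threshold))
    out = pd.DataFrame(
        {
            "feature": counts.index,
            "log_fc": np.log2(fc),
            "fold_change": fc,
            "p_value": pvals,
            "p_adjusted": padj,
            "pct_a": np.nan,
            "pct_b": np.nan,
            "direction": np.where(fc > 1, "up", "down"),
            "significant": significant,
            "convention": convention,
        }
    )
    out["p_criterion"] = p_criterion
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def bulk_de(
    counts: pd.DataFrame,
    groups,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bulk RNA DE: Welch t on log2(CPM+1); called significant iff
    BH-adjusted p < alpha and fold change > ``fc_threshold`` or <
    1/``fc_threshold``."""
    return _welch_de(counts, groups, group_a, group_b, fc_threshold, alpha,
                     p_criterion="adjusted", convention="log2-bulk")


def differential_peaks(
    peak_counts: pd.DataFrame,
    groups,
    group_a: str,
    group_b: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential accessibility on peak counts; significance uses the RAW
    p-value (p < alpha) with fold change > 1.5 or < 1/1.5 — note the
    asymmetry with :func:`bulk_de`, which uses the adjusted p."""
    return _welch_de(peak_counts, groups, group_a, group_b, fc_threshold, alpha,
                     p_criterion="raw", convention="log2-atac")


# ------------------------------------------------------------------- peaks


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; touching intervals stay separate."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlaps_any(s: int, e: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s < ie and is_ < e for is_, ie in intervals)


def consensus_peaks(
    replicate_peak_sets: list[PeakTable],
    min_fraction: float = 0.6,
    reference: str = "union",
) -> PeakTable:
    """Consensus peaks supported by MORE than ``min_fraction`` of replicates.

    The reference peak universe is the interval union of all replicate
    peaks (``reference='union'``) or the first replicate's peaks
    (``reference='first'``). A universe interval is kept when it overlaps
    (>= 1 bp) a peak in strictly more than ``min_fraction`` of the
    replicate sets — with 5 replicates, support in exactly 3/5 = 0.6 is
    dropped.
    """
    if not replicate_peak_sets:
        raise ValidationError("empty replicate list")
    if len(replicate_peak_sets) < 2:
        raise ValidationError("need at least 2 replicate peak sets")
    by_chrom_rep: list[dict[str, list[tuple[int, int]]]] = []
    for pt in replicate_peak_sets:
        d: dict[str, list[tuple[int, int]]] = {}
        for row in pt.table.itertuples(index=False):
            d.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
        by_chrom_rep.append({c: sorted(v) for c, v in d.items()})

    if reference == "union":
        universe: dict[str, list[tuple[int, int]]] = {}
        for d in by_chrom_rep:
            for c, ivals in d.items():
                universe.setdefault(c, []).extend(ivals)
        universe = {c: _merge_intervals(v) for c, v in universe.items()}
    elif reference == "first":
        universe = {c: sorted(v) for c, v in by_chrom_rep[0].items()}
    else:
        raise ValueError("reference must be 'union' or 'first'")

    n_rep = len(replicate_peak_sets)
    rows = []
    i = 0
    for chrom in sorted(universe):
        for s, e in universe[chrom]:
            support = sum(
                1 for d in by_chrom_rep if _overlaps_any(s, e, d.get(chrom, []))
            )
            if support / n_rep > min_fraction:
                i += 1
                rows.append((chrom, s, e, f"consensus_{i}", support))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id", "n_support"])
    return PeakTable(df)


def peak_to_genes(
    peaks: PeakTable, gene_coords: PeakTable, window: int = 5000
) -> pd.DataFrame:
    """Associate each peak with genes within ``window`` bp (overlap = 0 bp).

    Distance between half-open intervals is the gap between them; a gene at
    exactly ``window`` bp is assigned (inclusive bound).
    """
    rows = []
    genes_by_chrom: dict[str, list] = {}
    for g in gene_coords.table.itertuples(index=False):
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for p in peaks.table.itertuples(index=False):
        for g in genes_by_chrom.get(p.chrom, []):
            if p.start < g.end and g.start < p.end:
                dist = 0
            elif p.end <= g.start:
                dist = g.start - p.end
            else:
                dist = p.start - g.end
            if dist <= window:
                rows.append((p.peak_id, g.peak_id, dist))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])


def region_set_signal(
    universe: PeakTable,
    region_sets: dict[str, PeakTable],
    sample_groups,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Mean RPM-normalized signal per region set and sample group.

    ``universe`` carries per-sample count columns; counts are normalized to
    reads-per-million over the peak universe, then averaged over the
    universe peaks overlapping each region set's intervals. Regions with no
    overlapping universe peak are excluded with a warning; an empty region
    set is an error. Also returns the per-region matrices for heatmaps.
    """
    signal_cols = universe.signal_columns
    if not signal_cols:
        raise ValidationError("universe peak table carries no signal columns")
    sample_groups = pd.Series(sample_groups)
    counts = universe.table[signal_cols].to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValidationError("sample with zero total peak counts")
    rpm = counts / totals[None, :] * 1e6

    uni_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, row in enumerate(universe.table.itertuples(index=False)):
        uni_by_chrom.setdefault(row.chrom, []).append((int(row.start), int(row.end), i))

    summaries = []
    matrices: dict[str, pd.DataFrame] = {}
    for name, regions in region_sets.items():
        if len(regions) == 0:
            raise ValidationError(f"region set {name!r} is empty")
        region_rows = []
        region_ids = []
        for r in regions.table.itertuples(index=False):
            hit = [
                i
                for (s, e, i) in uni_by_chrom.get(r.chrom, [])
                if s < r.end and r.start < e
            ]
            if not hit:
                warnings.warn(
                    f"region {r.peak_id} in set {name!r} overlaps no universe peak; excluded",
                    stacklevel=2,
                )
                continue
            region_rows.append(rpm[hit].mean(axis=0))
            region_ids.append(r.peak_id)
        if not region_rows:
            raise ValidationError(f"region set {name!r} has no overlap with the peak universe")
        mat = pd.DataFrame(region_rows, index=region_ids, columns=signal_cols)
        matrices[name] = mat
        for grp in pd.unique(sample_groups):
            cols = sample_groups.index[sample_groups == grp]
            summaries.append(
                {
                    "region_set": name,
                    "group": grp,
                    "mean_signal": float(mat[cols].to_numpy().mean()),
                    "n_regions": len(region_ids),
                }
            )
    return pd.DataFrame(summaries), matrices
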