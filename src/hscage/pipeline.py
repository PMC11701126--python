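"""End-to-end orchestration: simulate -> QC -> score -> DE -> cascade ->
feature sets -> clock -> cohort, from a single seeded configuration.

The pipeline is deliberately truth-blind: clusters come from its own
clustering (old cells split into quiescent subclusters ranked by aging
score), the aging-up gene set from its own young-vs-old differential
expression, and the cascade from those. Planted truth is consulted only in
the report's ``recovery`` section. Reports carry no timestamps, so two
runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_analytics as ca
from . import diffexp, iolib, marker_cascade, methylclock, qc_norm, signatures
from .synthgen import SimConfig, generate_bulk_quartiles, generate_cohort, generate_methylation, generate_sc


@dataclass
class RunConfig:
    """All pipeline parameters, with the standard defaults.

    QC (800 features, 5% mito), 2000 HVGs (clamped to the gene count),
    min.pct/logfc 0.25, bulk padj<0.05 & FC 2, peak p<0.05 & FC 1.5,
    >60% consensus, cascade K=150, 4 quartiles, clock min coverage 3x,
    5 kb peak-gene window.
    """

    seed: int = 0
    sim: SimConfig = None
    outdir: str | None = None
    # QC / normalization / clustering
    min_features: int = 800
    max_mito_pct: float = 5.0
    mito_prefix: str = "mt-"
    n_hvg: int = 2000
    n_old_subclusters: int = 3
    n_pcs: int = 20
    # differential expression
    min_pct: float = 0.25
    logfc_threshold: float = 0.25
    de_alpha: float = 0.05
    bulk_fc_threshold: float = 2.0
    peak_fc_threshold: float = 1.5
    consensus_min_fraction: float = 0.6
    peak_gene_window: int = 5000
    # cascade / feature sets
    run_cascade: bool = True
    cascade_K: int = 150
    stage4_alpha: float = 0.05
    n_quartiles: int = 4
    feature_r_threshold: float = 0.7
    # clock
    min_coverage: int = 3
    min_site_fraction: float = 0.8
    # cohort
    tsubset_threshold: float = 100.0
    retention_reference: str = "young"
    survival_groups: tuple[str, ...] = ("CD150low", "whole", "CD150high")

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        errors = []
        if self.min_features < 0:
            errors.append("min_features must be >= 0")
        if not 0 <= self.max_mito_pct <= 100:
            errors.append("max_mito_pct must be in [0, 100]")
        if self.n_hvg < 1:
            errors.append("n_hvg must be >= 1")
        if not 0 < self.consensus_min_fraction < 1:
            errors.append("consensus_min_fraction must be in (0, 1)")
        if self.n_quartiles < 2:
            errors.append("n_quartiles must be >= 2")
        if not 0 < self.feature_r_threshold <= 1:
            errors.append("feature_r_threshold must be in (0, 1]")
        if errors:
            raise ValueError("invalid RunConfig: " + "; ".join(errors))


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    recovery: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (set, tuple)):
                return sorted(o) if isinstance(o, set) else list(o)
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=default)


def _adjusted_rand(a, b) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(list(a), list(b)))


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in dependency order and return the run report."""
    report = RunReport(
        params={
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("sim", "outdir")  # outdir is a location, not a parameter
        }
    )
    caught: list[str] = []

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # ---- simulate ------------------------------------------------
        matrix, annotation, truth = _stage("simulate")(lambda: generate_sc(config.sim))
        report.stages["simulate"] = {
            "n_genes": matrix.n_genes,
            "n_cells": matrix.n_cells,
            "n_young": int((matrix.cell_meta["condition"] == "young").sum()),
            "n_old": int((matrix.cell_meta["condition"] == "old").sum()),
        }

        # ---- QC + normalization -------------------------------------
        filtered, qc_report = _stage("qc")(
            lambda: qc_norm.qc_filter(
                matrix,
                min_features=config.min_features,
                max_mito_pct=config.max_mito_pct,
                mito_prefix=config.mito_prefix,
                return_report=True,
            )
        )
        report.stages["qc"] = dataclasses.asdict(qc_report)
        nm = _stage("normalize")(lambda: qc_norm.lognormalize(filtered))

        n_hvg = min(config.n_hvg, nm.n_genes)
        hvg = _stage("hvg")(lambda: qc_norm.select_hvg(nm, n=n_hvg))
        report.stages["hvg"] = {"n_requested": config.n_hvg, "n_selected": len(hvg)}

        # ---- aging-up genes from young-vs-old DE --------------------
        old_mask = (nm.cell_meta["condition"] == "old").to_numpy()
        de = _stage("de_old_vs_young")(
            lambda: diffexp.wilcoxon_de(
                nm,
                old_mask,
                ~old_mask,
                min_pct=config.min_pct,
                logfc_threshold=config.logfc_threshold,
                alpha=config.de_alpha,
            )
        )
        aging_up = de.loc[de["significant"] & (de["direction"] == "up"), "feature"].tolist()
        report.stages["de_old_vs_young"] = {
            "n_tested": len(de),
            "n_significant": int(de["significant"].sum()),
            "n_aging_up": len(aging_up),
        }

        # ---- cluster old cells into quiescent subclusters -----------
        nm_old = nm.subset_cells(old_mask)
        labels_old = _stage("cluster")(
            lambda: qc_norm.cluster_cells(
                nm_old, k=config.n_old_subclusters, n_pcs=config.n_pcs, seed=config.seed, hvg=hvg
            )
        )
        aging_score = _stage("aging_score")(lambda: signatures.signature_score(nm, aging_up))
        score_old = aging_score.scores.loc[labels_old.index]
        cluster_order = (
            score_old.groupby(labels_old).mean().sort_values(ascending=False).index.tolist()
        )
        # most aged first; the least-aged old cluster is the cascade target
        aged_clusters = cluster_order[:-1]
        target_cluster = cluster_order[-1]
        report.stages["cluster"] = {
            "k": config.n_old_subclusters,
            "cluster_sizes": labels_old.value_counts().sort_index().to_dict(),
            "target_cluster": int(target_cluster),
            "aged_clusters": [int(c) for c in aged_clusters],
        }

        # ---- cascade -------------------------------------------------
        if config.run_cascade:
            cascade = _stage("cascade")(
                lambda: marker_cascade.run_cascade(
                    nm_old,
                    labels_old,
                    aging_up,
                    annotation,
                    target_cluster=target_cluster,
                    aged_clusters=aged_clusters,
                    K=config.cascade_K,
                    stage4_alpha=config.stage4_alpha,
                    aging_score=aging_score.scores.loc[labels_old.index],
                )
            )
            report.stages["cascade"] = {
                "stage_sizes": cascade.stage_sizes(),
                "final_candidates": cascade.final[:20],
                "nesting_ok": cascade.check_nesting(),
            }

        # ---- bulk quartiles + feature sets --------------------------
        bulk, marker_levels, bulk_truth = _stage("bulk")(
            lambda: generate_bulk_quartiles(config.sim)
        )
        bins = marker_cascade.quartile_bins(marker_levels, n_bins=config.n_quartiles)
        feature_sets = _stage("feature_sets")(
            lambda: marker_cascade.marker_correlated_sets(
                bulk, marker_levels, r_threshold=config.feature_r_threshold
            )
        )
        report.stages["feature_sets"] = {
            "n_positive": len(feature_sets.positive),
            "n_negative": len(feature_sets.negative),
            "bin_sizes": bins.value_counts().sort_index().to_dict(),
        }
        if feature_sets.positive:
            R, p, _ = _stage("feature_score")(
                lambda: marker_cascade.feature_score_correlation(
                    nm, feature_sets.positive, aging_up
                )
            )
            report.stages["feature_score"] = {"pearson_R": R, "p_value": p}

        # ---- methylation clock --------------------------------------
        meth, clock, true_ages = _stage("clock_data")(lambda: generate_methylation(config.sim))
        meth_f = methylclock.coverage_filter(meth, min_cov=config.min_coverage)
        ages = _stage("clock_predict")(
            lambda: methylclock.predict_age(meth_f, clock, min_site_fraction=config.min_site_fraction)
        )
        report.stages["clock"] = {
            "n_samples": len(ages),
            "n_flagged": int(ages["flagged"].sum()),
            "predicted_ages": {s: float(a) for s, a in ages["age"].items()},
        }

        # ---- cohort --------------------------------------------------
        cohort, cohort_truth = _stage("cohort")(lambda: generate_cohort(config.sim))
        last_day = max(config.sim.cohort.days)
        chim = {
            g: ca.chimerism_summary(cohort.chimerism, g, last_day)
            for g in config.sim.cohort.groups
        }
        report.stages["chimerism"] = {g: {"mean": c["mean"], "sd": c["sd"], "n": c["n"]} for g, c in chim.items()}

        ref = config.retention_reference
        retention = {}
        for g in config.sim.cohort.groups:
            if g == ref:
                continue
            test = [
                ca.chimerism_summary(cohort.chimerism, g, d)["mean"] for d in config.sim.cohort.days
            ]
            refc = [
                ca.chimerism_summary(cohort.chimerism, ref, d)["mean"] for d in config.sim.cohort.days
            ]
            res = ca.functionality_retention(
                test, refc, config.sim.cohort.doses[g], config.sim.cohort.doses[ref]
            )
            retention[g] = res.retention_pct
        report.stages["retention_vs_" + ref] = retention

        tsub = ca.tcell_subsets(
            cohort.tsubset, config.tsubset_threshold, config.tsubset_threshold
        )
        report.stages["tcell_subsets"] = {
            f"{r.group}:{r.subset}": round(float(r.fraction), 4) for r in tsub.itertuples()
        }

        kms = {g: ca.km_estimate(cohort.survival, g) for g in config.survival_groups}
        lr = ca.logrank_test(
            cohort.survival[cohort.survival["group"].isin(config.survival_groups)]
        )
        deltas = {}
        for other in config.survival_groups:
            if other == "CD150low" or "CD150low" not in kms:
                continue
            deltas[f"CD150low_vs_{other}"] = ca.lifespan_deltas(kms["CD150low"], kms[other])
        report.stages["survival"] = {
            "logrank": lr,
            "median_lifespan": {g: ca._median_survival(k) for g, k in kms.items()},
            "lifespan_deltas": deltas,
        }

        # ---- recovery metrics (the only place truth is read) --------
        marker = truth.marker_gene
        rec = {
            "marker_gene": marker,
            "marker_in_aging_up": marker in set(aging_up),
            "aging_up_recall": len(set(aging_up) & truth.aging_genes) / len(truth.aging_genes),
            "cluster_ari_old": _adjusted_rand(
                truth.cluster_labels.loc[labels_old.index], labels_old
            ),
        }
        if config.run_cascade:
            rec["marker_in_final"] = marker in set(cascade.final)
            rec["marker_rank"] = (cascade.final.index(marker) + 1) if marker in cascade.final else None
        pred = ages["age"].reindex(true_ages.index)
        rec["clock_rmse"] = float(np.sqrt(np.mean((pred.to_numpy() - true_ages.to_numpy()) ** 2)))
        rec["bulk_positive_recall"] = (
            len(set(feature_sets.positive) & bulk_truth.bulk_positive_genes)
            / len(bulk_truth.bulk_positive_genes)
        )
        report.recovery = rec

        report.warnings = sorted({str(w.message) for w in wrec})

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        iolib.write_cell_matrix(filtered, out / "filtered_matrix", format="mtx-triplet")
        de.to_csv(out / "de_old_vs_young.tsv", sep="\t", index=False)
        if config.run_cascade:
            pd.DataFrame({"candidate": cascade.final}).to_csv(
                out / "cascade_candidates.tsv", sep="\t", index=False
            )
        iolib.write_cohort(cohort, out / "cohort")
    return report
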