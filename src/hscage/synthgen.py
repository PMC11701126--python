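"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: a young/old
single-cell count matrix with quiescent-cluster substructure, membrane
annotation, marker-sorted bulk quartile samples, clock-bearing methylation
profiles and transplantation cohort tables. All generators are fully
deterministic under a fixed seed, and every planted effect is recorded in a
:class:`TruthBundle` so recovery can be scored.

The central device is a per-cell latent aging axis ``a`` in [0, 1]:
young cells sit at 0, the most aged old cells near 1, and the "younger"
old cluster (q3) near 0. Aging genes and the surface marker both load on
this axis (mean multiplied by ``2**(loading * a)``), which creates the
marker/aging-score correlation the cascade must detect without hard-coding
the answer anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CellMatrix, CohortTables, ClockModel, GeneAnnotation, MethylationMatrix

# fixed substream tags so one generator's draw count never perturbs another
_STREAM_GENEMODEL = 0
_STREAM_SC = 1
_STREAM_BULK = 2
_STREAM_METH = 3
_STREAM_COHORT = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass
class ScConfig:
    """Single-cell generator settings (counts are negative binomial)."""

    n_genes: int = 1000
    n_mito_genes: int = 10
    n_young_cells: int = 400
    n_old_cells: int = 600
    # old quiescent clusters q1-q3; young cells are cluster q4
    old_cluster_proportions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    n_aging_genes: int = 50
    aging_log2fc: float = 1.5
    n_young_genes: int = 30
    marker_gene: str = "Slamf1"
    marker_log2fc: float = 2.0
    marker_is_membrane: bool = True
    n_membrane_decoys: int = 30
    n_cluster_marker_genes: int = 40
    cluster_marker_log2fc: float = 1.5
    dispersion: float = 0.3
    base_mean_log: float = 1.5  # lognormal location of per-gene baseline means
    base_mean_sd: float = 0.8
    library_size_range: tuple[float, float] = (0.7, 1.3)
    mito_fraction: float = 0.02
    n_low_feature_cells: int = 0
    n_high_mito_cells: int = 0


@dataclass
class BulkConfig:
    """Marker-level quartile bulk samples G1..G4 (FACS-sorted emulation)."""

    n_replicates: int = 3  # per quartile group
    n_groups: int = 4
    dispersion: float = 0.02
    depth_factor: float = 50.0  # multiplies per-gene baseline means
    protein_noise_sd: float = 0.04  # marker protein level around group axis


@dataclass
class ClockConfig:
    """Methylation clock data: beta = mu_i + s_i * age + noise, clipped."""

    n_clock_sites: int = 80
    n_extra_sites: int = 20
    slope_low: float = 0.004  # per-month beta change, |s_i| range
    slope_high: float = 0.010
    baseline_low: float = 0.30
    baseline_high: float = 0.60
    noise_sd: float = 0.08
    ages: tuple[float, ...] = tuple(float(a) for a in np.linspace(3, 24, 12))
    mean_coverage: float = 12.0
    low_coverage_fraction: float = 0.0  # fraction of entries forced under 3x


@dataclass
class CohortConfig:
    """Transplantation cohorts: chimerism, lineage, T subsets, survival."""

    groups: tuple[str, ...] = ("young", "CD150low", "whole", "CD150high")
    n_mice: int = 17  # per group
    doses: dict = field(
        default_factory=lambda: {"young": 2000, "CD150low": 2000, "whole": 2000, "CD150high": 2000}
    )
    days: tuple[int, ...] = (28, 56, 84, 112)
    # per-group mean donor fraction at each day (logit-normal around these)
    chimerism_means: dict = field(
        default_factory=lambda: {
            "young": (0.300, 0.450, 0.550, 0.600),
            "CD150low": (0.238, 0.374, 0.471, 0.522),
            "whole": (0.176, 0.290, 0.379, 0.429),
            "CD150high": (0.025, 0.046, 0.067, 0.081),
        }
    )
    chimerism_logit_sd: float = 0.30
    lineage_proportions: dict = field(
        default_factory=lambda: {
            "young": (0.55, 0.25, 0.20),
            "CD150low": (0.52, 0.26, 0.22),
            "whole": (0.45, 0.30, 0.25),
            "CD150high": (0.35, 0.33, 0.32),
        }
    )
    lineage_cells: int = 1000
    tsubset_mixing: dict = field(
        default_factory=lambda: {  # naive, Tcm, Tem, other
            "young": (0.55, 0.25, 0.15, 0.05),
            "CD150low": (0.45, 0.30, 0.20, 0.05),
            "whole": (0.35, 0.35, 0.25, 0.05),
            "CD150high": (0.25, 0.40, 0.30, 0.05),
        }
    )
    tsubset_events_per_mouse: int = 300
    tsubset_threshold: float = 100.0  # FACS intensity gate for CD44 and CD62L
    tsubset_high_mean: float = 400.0
    tsubset_low_mean: float = 25.0
    tsubset_log_sd: float = 0.40
    # Gompertz survival since transplantation (months): h(t) = a*HR*exp(b*t)
    gompertz_a: float = 0.002593
    gompertz_b: float = 0.35
    hazard_ratios: dict = field(
        default_factory=lambda: {"young": 0.65, "CD150low": 0.65, "whole": 1.0, "CD150high": 1.09}
    )
    censor_horizon: float = 36.0


@dataclass
class SimConfig:
    """Master configuration; ``seed`` makes every generator reproducible."""

    seed: int = 0
    sc: ScConfig = field(default_factory=ScConfig)
    bulk: BulkConfig = field(default_factory=BulkConfig)
    clock: ClockConfig = field(default_factory=ClockConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self):
        props = np.asarray(self.sc.old_cluster_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("old cluster proportions must sum to 1")
        special = self.sc.n_aging_genes + self.sc.n_young_genes + 4 * self.sc.n_cluster_marker_genes
        if special + self.sc.n_mito_genes + 1 > self.sc.n_genes:
            raise ValueError("n_genes too small for the requested planted structure")


@dataclass
class TruthBundle:
    """Planted ground truth for scoring recovery; filled per generator."""

    cluster_labels: pd.Series | None = None  # per cell: q1/q2/q3/q4
    aging_axis: pd.Series | None = None  # per cell latent a in [0, 1]
    aging_genes: set[str] | None = None
    young_genes: set[str] | None = None
    marker_gene: str | None = None
    cluster_marker_genes: dict | None = None
    low_feature_cells: list[str] | None = None
    high_mito_cells: list[str] | None = None
    bulk_positive_genes: set[str] | None = None
    bulk_negative_genes: set[str] | None = None
    marker_levels: pd.Series | None = None  # per bulk sample protein level
    true_ages: pd.Series | None = None
    hazard_ratios: dict | None = None
    tsubset_mixing: dict | None = None
    chimerism_means: dict | None = None


# ------------------------------------------------------------- gene model


@dataclass
class _GeneModel:
    """Shared per-gene parameters so sc and bulk data agree on which genes
    track the aging axis."""

    gene_ids: list[str]
    base_mean: np.ndarray
    axis_loading: np.ndarray  # log2-fold change per unit of aging axis
    aging_genes: list[str]
    young_genes: list[str]
    marker_gene: str
    marker_idx: int
    mito_idx: np.ndarray
    cluster_marker_genes: dict[str, list[str]]
    cluster_bonus: dict[str, np.ndarray]  # per-cluster additive log2 bumps
    membrane_genes: list[str]


def build_gene_model(config: SimConfig) -> _GeneModel:
    sc = config.sc
    rng = _rng(config.seed, _STREAM_GENEMODEL)
    n = sc.n_genes
    n_mito = sc.n_mito_genes
    gene_ids = [f"mt-{i + 1:02d}" for i in range(n_mito)]
    gene_ids += [f"gene{i + 1:04d}" for i in range(n - n_mito)]

    base = np.exp(rng.normal(sc.base_mean_log, sc.base_mean_sd, size=n))
    # mito genes get a fixed share of the library
    non_mito_total = base[n_mito:].sum()
    if n_mito:
        base[:n_mito] = sc.mito_fraction * non_mito_total / ((1 - sc.mito_fraction) * n_mito)

    ordinary = np.arange(n_mito, n)
    picks = rng.choice(ordinary, size=sc.n_aging_genes + sc.n_young_genes
                       + 4 * sc.n_cluster_marker_genes + 1, replace=False)
    cursor = 0

    def take(k):
        nonlocal cursor
        out = picks[cursor:cursor + k]
        cursor += k
        return out

    aging_idx = take(sc.n_aging_genes)
    young_idx = take(sc.n_young_genes)
    cluster_idx = {c: take(sc.n_cluster_marker_genes) for c in ("q1", "q2", "q3", "q4")}
    marker_idx = int(take(1)[0])
    gene_ids[marker_idx] = sc.marker_gene

    loading = np.zeros(n)
    loading[aging_idx] = sc.aging_log2fc
    loading[young_idx] = -sc.aging_log2fc
    loading[marker_idx] = sc.marker_log2fc

    bonus = {}
    for c, idx in cluster_idx.items():
        b = np.zeros(n)
        b[idx] = sc.cluster_marker_log2fc
        bonus[c] = b

    aging_names = [gene_ids[i] for i in aging_idx]
    decoy_pool = [g for g in gene_ids[n_mito:]
                  if g not in aging_names and g != sc.marker_gene]
    decoys = list(rng.choice(decoy_pool, size=sc.n_membrane_decoys, replace=False))
    membrane = decoys + ([sc.marker_gene] if sc.marker_is_membrane else [])

    return _GeneModel(
        gene_ids=gene_ids,
        base_mean=base,
        axis_loading=loading,
        aging_genes=aging_names,
        young_genes=[gene_ids[i] for i in young_idx],
        marker_gene=sc.marker_gene,
        marker_idx=marker_idx,
        mito_idx=np.arange(n_mito),
        cluster_marker_genes={c: [gene_ids[i] for i in idx] for c, idx in cluster_idx.items()},
        cluster_bonus=bonus,
        membrane_genes=membrane,
    )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    # gamma-Poisson mixture == NB; much faster than rng.negative_binomial
    return rng.poisson(rng.gamma(r, mean / r))


# Latent-axis ranges per cluster: q1/q2 strongly aged, q3 young-like, q4 young.
_AXIS_RANGES = {"q1": (0.90, 1.00), "q2": (0.75, 0.95), "q3": (0.05, 0.25), "q4": (0.0, 0.0)}


def generate_sc(config: SimConfig) -> tuple[CellMatrix, GeneAnnotation, TruthBundle]:
    """Young/old single-cell counts with planted clusters, aging genes and marker."""
    sc = config.sc
    gm = build_gene_model(config)
    rng = _rng(config.seed, _STREAM_SC)

    n_old_each = rng.multinomial(sc.n_old_cells, np.asarray(sc.old_cluster_proportions))
    clusters = (
        ["q4"] * sc.n_young_cells
        + ["q1"] * int(n_old_each[0])
        + ["q2"] * int(n_old_each[1])
        + ["q3"] * int(n_old_each[2])
    )
    condition = ["young"] * sc.n_young_cells + ["old"] * sc.n_old_cells
    n_cells = len(clusters)
    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells)]

    axis = np.array([rng.uniform(*_AXIS_RANGES[c]) for c in clusters])
    lib = rng.uniform(*sc.library_size_range, size=n_cells)

    log2mu = (
        np.log2(gm.base_mean)[:, None]
        + gm.axis_loading[:, None] * axis[None, :]
    )
    for c in ("q1", "q2", "q3", "q4"):
        in_c = np.asarray([ci == c for ci in clusters])
        if in_c.any():
            log2mu[:, in_c] += gm.cluster_bonus[c][:, None]
    mu = (2.0 ** log2mu) * lib[None, :]

    counts = _nb_sample(rng, mu, sc.dispersion)

    # planted low-quality cells (appended, condition 'old', cluster q3-like)
    low_feature_ids, high_mito_ids = [], []
    extras = []
    for j in range(sc.n_low_feature_cells):
        cid = f"lowfeat{j + 1:03d}"
        low_feature_ids.append(cid)
        m = gm.base_mean * 0.05  # tiny library -> few detected genes
        extras.append((cid, _nb_sample(rng, m, sc.dispersion)))
    for j in range(sc.n_high_mito_cells):
        cid = f"himito{j + 1:03d}"
        high_mito_ids.append(cid)
        m = gm.base_mean.copy()
        m[gm.mito_idx] *= 10.0  # mito fraction well above 5%
        extras.append((cid, _nb_sample(rng, m, sc.dispersion)))
    if extras:
        counts = np.column_stack([counts] + [e[1] for e in extras])
        cell_ids = cell_ids + [e[0] for e in extras]
        clusters = clusters + ["q3"] * len(extras)
        condition = condition + ["old"] * len(extras)
        axis = np.concatenate([axis, np.full(len(extras), 0.15)])

    meta = pd.DataFrame(
        {"condition": condition, "true_cluster": clusters},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    matrix = CellMatrix(counts, gm.gene_ids, cell_ids, meta, layer="raw")

    ann = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": gm.gene_ids,
                "is_membrane": [g in set(gm.membrane_genes) for g in gm.gene_ids],
            }
        )
    )
    truth = TruthBundle(
        cluster_labels=pd.Series(clusters, index=cell_ids, name="true_cluster"),
        aging_axis=pd.Series(axis, index=cell_ids, name="aging_axis"),
        aging_genes=set(gm.aging_genes) | {gm.marker_gene},
        young_genes=set(gm.young_genes),
        marker_gene=gm.marker_gene,
        cluster_marker_genes=dict(gm.cluster_marker_genes),
        low_feature_cells=low_feature_ids,
        high_mito_cells=high_mito_ids,
    )
    return matrix, ann, truth


def generate_bulk_quartiles(config: SimConfig) -> tuple[pd.DataFrame, pd.Series, TruthBundle]:
    """Bulk counts for marker-level quartile groups G1..G4.

    Returns (counts table genes x samples, per-sample marker protein level,
    truth). Sample names are ``G<g>_r<i>``; group axis levels ascend G1->G4
    so genes loading positively on the aging axis rise with marker level.
    """
    bulk = config.bulk
    if bulk.n_replicates < 2:
        raise ValueError("need at least 2 replicates per quartile group")
    gm = build_gene_model(config)
    rng = _rng(config.seed, _STREAM_BULK)

    sample_names, group_axis = [], []
    for g in range(1, bulk.n_groups + 1):
        a_g = (g - 0.5) / bulk.n_groups  # quartile mid-level of the aging axis
        for r in range(1, bulk.n_replicates + 1):
            sample_names.append(f"G{g}_r{r}")
            group_axis.append(a_g)
    group_axis = np.asarray(group_axis)

    log2mu = np.log2(gm.base_mean * bulk.depth_factor)[:, None] + gm.axis_loading[:, None] * group_axis[None, :]
    counts = _nb_sample(rng, 2.0 ** log2mu, bulk.dispersion)
    table = pd.DataFrame(counts, index=gm.gene_ids, columns=sample_names)

    protein = group_axis + rng.normal(0.0, bulk.protein_noise_sd, size=len(sample_names))
    marker_levels = pd.Series(protein, index=sample_names, name="marker_level")

    truth = TruthBundle(
        marker_gene=gm.marker_gene,
        bulk_positive_genes=set(gm.aging_genes) | {gm.marker_gene},
        bulk_negative_genes=set(gm.young_genes),
        marker_levels=marker_levels,
    )
    return table, marker_levels, truth


def generate_methylation(config: SimConfig) -> tuple[MethylationMatrix, ClockModel, pd.Series]:
    """Clock-bearing methylation profiles.

    beta_i(sample) = clip(mu_i + s_i * age + noise, 0, 1). The returned
    ClockModel is exact by construction: weights w_i = s_i / sum(s^2) and
    intercept -sum(w_i mu_i), so at zero noise the linear predictor returns
    the true age to float precision. Extra non-clock sites are included to
    exercise site matching.
    """
    ck = config.clock
    rng = _rng(config.seed, _STREAM_METH)
    ages = np.asarray(ck.ages, dtype=float)
    n_samples = ages.size
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]

    n_sites = ck.n_clock_sites + ck.n_extra_sites
    pos = np.sort(rng.choice(np.arange(3_000_000, 4_000_000), size=n_sites, replace=False))
    site_ids = [f"chr1:{p}" for p in pos]
    clock_sites = site_ids[: ck.n_clock_sites]

    mu = rng.uniform(ck.baseline_low, ck.baseline_high, size=n_sites)
    slope = rng.uniform(ck.slope_low, ck.slope_high, size=n_sites) * rng.choice(
        [-1.0, 1.0], size=n_sites
    )
    slope[ck.n_clock_sites:] = 0.0  # extra sites carry no age signal

    beta = mu[:, None] + slope[:, None] * ages[None, :]
    if ck.noise_sd > 0:
        beta = beta + rng.normal(0.0, ck.noise_sd, size=beta.shape)
    beta = np.clip(beta, 0.0, 1.0)

    coverage = rng.poisson(ck.mean_coverage, size=beta.shape)
    coverage = np.maximum(coverage, 3)  # baseline: everything well covered
    if ck.low_coverage_fraction > 0:
        mask = rng.random(beta.shape) < ck.low_coverage_fraction
        coverage = np.where(mask, rng.integers(0, 3, size=beta.shape), coverage)
    beta = np.where(coverage == 0, np.nan, beta)

    meth = MethylationMatrix(
        beta=pd.DataFrame(beta, index=site_ids, columns=samples),
        coverage=pd.DataFrame(coverage, index=site_ids, columns=samples),
    )

    s = slope[: ck.n_clock_sites]
    w = s / np.sum(s**2)
    mean_age = float(ages.mean())
    training_mean = np.clip(mu[: ck.n_clock_sites] + s * mean_age, 0.0, 1.0)
    clock = ClockModel(
        intercept=float(-np.sum(w * mu[: ck.n_clock_sites])),
        weights=pd.Series(w, index=clock_sites),
        training_mean=pd.Series(training_mean, index=clock_sites),
        age_unit="months",
    )
    true_ages = pd.Series(ages, index=samples, name="age")
    return meth, clock, true_ages


def generate_cohort(config: SimConfig) -> tuple[CohortTables, TruthBundle]:
    """Transplantation cohort tables with group-structured planted effects."""
    co = config.cohort
    rng = _rng(config.seed, _STREAM_COHORT)

    chim_rows, lin_rows, tsub_rows, surv_rows = [], [], [], []
    for group in co.groups:
        means = np.asarray(co.chimerism_means[group], dtype=float)
        dose = co.doses[group]
        hr = co.hazard_ratios[group]
        props = np.asarray(co.lineage_proportions[group], dtype=float)
        mix = np.asarray(co.tsubset_mixing[group], dtype=float)
        for m in range(co.n_mice):
            mouse = f"{group}_m{m + 1:02d}"
            # chimerism: logit-normal around the group mean trajectory
            for day, mu in zip(co.days, means):
                logit = np.log(mu / (1 - mu)) + rng.normal(0.0, co.chimerism_logit_sd)
                frac = 1.0 / (1.0 + np.exp(-logit))
                chim_rows.append((mouse, group, day, frac, dose))
            # lineage: multinomial cell counts -> percentages
            counts = rng.multinomial(co.lineage_cells, props / props.sum())
            pct = 100.0 * counts / counts.sum()
            lin_rows.append((mouse, group, pct[0], pct[1], pct[2]))
            # T subsets: mixture of bivariate lognormal CD44/CD62L clusters
            n_ev = co.tsubset_events_per_mouse
            comp = rng.choice(4, size=n_ev, p=mix / mix.sum())
            hi, lo, sd = np.log(co.tsubset_high_mean), np.log(co.tsubset_low_mean), co.tsubset_log_sd
            # quadrant means: naive (CD44 lo, CD62L hi), Tcm (hi, hi),
            # Tem (hi, lo), other (lo, lo)
            cd44_mu = np.array([lo, hi, hi, lo])[comp]
            cd62l_mu = np.array([hi, hi, lo, lo])[comp]
            cd44 = np.exp(rng.normal(cd44_mu, sd))
            cd62l = np.exp(rng.normal(cd62l_mu, sd))
            for v44, v62 in zip(cd44, cd62l):
                tsub_rows.append((mouse, group, "CD8", v44, v62))
            # survival: Gompertz with proportional hazard, admin censoring
            u = rng.random()
            a, b = co.gompertz_a * hr, co.gompertz_b
            t = np.log(1.0 - b * np.log(u) / a) / b
            event = 1 if t <= co.censor_horizon else 0
            surv_rows.append((mouse, group, min(t, co.censor_horizon), event))

    tables = CohortTables(
        chimerism=pd.DataFrame(
            chim_rows, columns=["mouse_id", "group", "day", "donor_fraction", "dose"]
        ),
        lineage=pd.DataFrame(
            lin_rows, columns=["mouse_id", "group", "b_pct", "t_pct", "myeloid_pct"]
        ),
        tsubset=pd.DataFrame(
            tsub_rows, columns=["mouse_id", "group", "compartment", "cd44", "cd62l"]
        ),
        survival=pd.DataFrame(surv_rows, columns=["mouse_id", "group", "time", "event"]),
        groups=tuple(co.groups),
    )
    truth = TruthBundle(
        hazard_ratios=dict(co.hazard_ratios),
        tsubset_mixing={g: tuple(v) for g, v in co.tsubset_mixing.items()},
        chimerism_means={g: tuple(v) for g, v in co.chimerism_means.items()},
    )
    return tables, truth
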