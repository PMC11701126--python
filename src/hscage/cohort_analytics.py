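"""Transplantation-cohort analytics: chimerism, lineage output, T-cell
subsets, dose-normalized functionality retention and lifespan comparison.

Functionality retention quantifies how much repopulation capability a test
HSC population keeps relative to a reference population in competitive
transplantation. The default operationalization is the donor-vs-competitor
odds per transplanted cell:

    retention% = 100 * [(C_t/(1-C_t))/dose_t] / [(C_r/(1-C_r))/dose_r]

averaged over the supplied timepoints (a plain chimerism ratio C_t/C_r is
available via ``method='ratio'``). Survival uses the Kaplan-Meier
product-limit estimator and the Mantel-Cox log-rank test, with deaths
processed before censorings at tied times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .datatypes import CohortTables, ValidationError


@dataclass
class KMEstimate:
    """Product-limit survival curve for one group."""

    group: str
    times: np.ndarray  # ordered distinct event/censor times
    survival: np.ndarray  # S(t) immediately after each time
    at_risk: np.ndarray
    events: np.ndarray
    max_death_time: float | None
    death_times: np.ndarray = field(default=None)

    def s_at(self, t: float) -> float:
        """S(t), right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class RetentionResult:
    retention_pct: float
    per_timepoint: np.ndarray
    test_chimerism: np.ndarray
    ref_chimerism: np.ndarray
    test_dose: float
    ref_dose: float
    method: str


def chimerism_summary(
    chimerism: pd.DataFrame, group: str, day
) -> dict:
    """Mean and sd of donor fraction at (group, day); sd=0 flagged at n=1."""
    sel = chimerism[(chimerism["group"] == group) & (chimerism["day"] == day)]
    if len(sel) == 0:
        raise ValidationError(f"no chimerism records for group {group!r} at day {day}")
    f = sel["donor_fraction"].to_numpy(dtype=float)
    return {
        "group": group,
        "day": day,
        "mean": float(f.mean()),
        "sd": float(f.std(ddof=1)) if f.size > 1 else 0.0,
        "n": int(f.size),
        "single_mouse": f.size == 1,
    }


def lineage_composition(counts_or_table) -> pd.DataFrame:
    """Per-mouse B/T/myeloid percentages summing to exactly 100.

    Accepts either a lineage table already in percent (mouse_id, group,
    b_pct, t_pct, myeloid_pct) or a counts table (mouse_id, group, b, t,
    myeloid); in both cases values are renormalized to the three-lineage
    total.
    """
    df = counts_or_table.copy()
    if {"b", "t", "myeloid"}.issubset(df.columns):
        cols = ["b", "t", "myeloid"]
    elif {"b_pct", "t_pct", "myeloid_pct"}.issubset(df.columns):
        cols = ["b_pct", "t_pct", "myeloid_pct"]
    else:
        raise ValidationError("lineage input needs b/t/myeloid or *_pct columns")
    vals = df[cols].to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    if np.any(totals == 0):
        raise ValidationError("mouse with zero total lineage count")
    pct = 100.0 * vals / totals[:, None]
    out = df[["mouse_id", "group"]].copy()
    out[["b_pct", "t_pct", "myeloid_pct"]] = pct
    return out


def tcell_subsets(
    events: pd.DataFrame,
    cd44_threshold: float,
    cd62l_threshold: float,
) -> pd.DataFrame:
    """Quadrant fractions of naive / Tcm / Tem / other per (group, compartment).

    naive = CD62L>thr & CD44<=thr; Tcm = both above; Tem = CD62L<=thr &
    CD44>thr; the remaining quadrant is 'other'. Fractions sum to 1.
    """
    if len(events) == 0:
        raise ValidationError("empty T-cell event set")
    cd44 = events["cd44"].to_numpy(dtype=float)
    cd62l = events["cd62l"].to_numpy(dtype=float)
    hi44, hi62 = cd44 > cd44_threshold, cd62l > cd62l_threshold
    subset = np.select(
        [~hi44 & hi62, hi44 & hi62, hi44 & ~hi62], ["naive", "Tcm", "Tem"], default="other"
    )
    df = events.assign(subset=subset)
    group_cols = [c for c in ("group", "compartment") if c in df.columns]
    frac = (
        df.groupby(group_cols)["subset"]
        .value_counts(normalize=True)
        .rename("fraction")
        .reset_index()
    )
    return frac


def functionality_retention(
    test_chimerism,
    ref_chimerism,
    test_dose: float,
    ref_dose: float,
    method: str = "odds_per_cell",
) -> RetentionResult:
    """Repopulation functionality of a test population relative to a
    reference, normalized per transplanted cell; averaged over timepoints."""
    c_t = np.atleast_1d(np.asarray(test_chimerism, dtype=float))
    c_r = np.atleast_1d(np.asarray(ref_chimerism, dtype=float))
    if c_t.shape != c_r.shape:
        raise ValidationError("test and reference chimerism must align per timepoint")
    if test_dose <= 0 or ref_dose <= 0:
        raise ValidationError("doses must be > 0")
    if np.any((c_t <= 0) | (c_t >= 1)) or np.any((c_r <= 0) | (c_r >= 1)):
        raise ValidationError("chimerism at 0 or 1: odds undefined")
    if method == "odds_per_cell":
        per_tp = 100.0 * ((c_t / (1 - c_t)) / test_dose) / ((c_r / (1 - c_r)) / ref_dose)
    elif method == "ratio":
        per_tp = 100.0 * (c_t / test_dose) / (c_r / ref_dose)
    else:
        raise ValueError("method must be 'odds_per_cell' or 'ratio'")
    return RetentionResult(
        retention_pct=float(per_tp.mean()),
        per_timepoint=per_tp,
        test_chimerism=c_t,
        ref_chimerism=c_r,
        test_dose=float(test_dose),
        ref_dose=float(ref_dose),
        method=method,
    )


def _group_records(survival: pd.DataFrame, group: str) -> pd.DataFrame:
    sel = survival[survival["group"] == group]
    if len(sel) == 0:
        raise ValidationError(f"no survival records for group {group!r}")
    if (sel["time"] < 0).any():
        raise ValidationError("negative survival times")
    return sel


def km_estimate(survival: pd.DataFrame, group: str) -> KMEstimate:
    """Kaplan-Meier curve for one group (right censoring; deaths first at ties)."""
    sel = _group_records(survival, group)
    kmf = KaplanMeierFitter()
    kmf.fit(sel["time"], event_observed=sel["event"])
    et = kmf.event_table.iloc[1:] if 0.0 not in sel["time"].values and kmf.event_table.index[0] == 0.0 else kmf.event_table
    times = et.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy(dtype=float)
    deaths = sel.loc[sel["event"] == 1, "time"].to_numpy(dtype=float)
    return KMEstimate(
        group=group,
        times=times,
        survival=surv,
        at_risk=et["at_risk"].to_numpy(dtype=int),
        events=et["observed"].to_numpy(dtype=int),
        max_death_time=float(deaths.max()) if deaths.size else None,
        death_times=np.sort(deaths),
    )


def _median_survival(km: KMEstimate) -> float | None:
    hit = np.flatnonzero(km.survival <= 0.5)
    return float(km.times[hit[0]]) if hit.size else None


def _max_lifespan(km: KMEstimate, definition: str) -> float | None:
    if km.death_times is None or km.death_times.size == 0:
        return None
    if definition == "longest_death":
        return float(km.death_times[-1])
    if definition == "top_decile_mean":
        k = max(1, int(np.ceil(0.1 * km.death_times.size)))
        return float(km.death_times[-k:].mean())
    raise ValueError("definition must be 'longest_death' or 'top_decile_mean'")


def lifespan_deltas(
    km_a: KMEstimate,
    km_b: KMEstimate,
    max_definition: str = "longest_death",
) -> dict:
    """Percent change of group A vs group B in median and maximum lifespan.

    median = smallest t with S(t) <= 0.5; maximum defaults to the longest
    observed death time ('top_decile_mean' gives the mean of the top decile
    of death times). delta% = 100*(m_a - m_b)/m_b; undefined medians are
    reported as None with a flag.
    """
    med_a, med_b = _median_survival(km_a), _median_survival(km_b)
    max_a = _max_lifespan(km_a, max_definition)
    max_b = _max_lifespan(km_b, max_definition)
    out = {
        "median_a": med_a,
        "median_b": med_b,
        "median_delta_pct": None,
        "median_undefined": med_a is None or med_b is None,
        "max_a": max_a,
        "max_b": max_b,
        "max_delta_pct": None,
        "max_definition": max_definition,
    }
    if med_a is not None and med_b is not None and med_b != 0:
        out["median_delta_pct"] = 100.0 * (med_a - med_b) / med_b
    if max_a is not None and max_b is not None and max_b != 0:
        out["max_delta_pct"] = 100.0 * (max_a - max_b) / max_b
    return out


def logrank_test(survival: pd.DataFrame, groups=None) -> dict:
    """Mantel-Cox log-rank test across groups.

    Returns chi-square statistic, degrees of freedom (groups-1) and p.
    """
    df = survival if groups is None else survival[survival["group"].isin(groups)]
    present = pd.unique(df["group"])
    if len(present) < 2:
        raise ValidationError("log-rank needs at least 2 non-empty groups")
    if groups is not None:
        missing = [g for g in groups if g not in set(present)]
        if missing:
            raise ValidationError(f"group(s) with zero subjects: {missing}")
    if int(df["event"].sum()) == 0:
        raise ValidationError("log-rank needs at least one event")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return {
        "statistic": float(res.test_statistic),
        "df": int(len(present) - 1),
        "p_value": float(res.p_value),
    }
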