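from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_nm
from hscage import diffexp
from hscage.datatypes import PeakTable, ValidationError


def permutation_oracle(x, y):
    """Two-sided rank-sum p by exhaustive enumeration, computing the
    Mann-Whitney U from pairwise comparisons (independent of ranking code)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_stat(a_idx):
        a_idx = set(a_idx)
        a = np.array([pooled[i] for i in sorted(a_idx)])
        b = np.array([pooled[i] for i in range(n + m) if i not in a_idx])
        return (a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum()

    obs = abs(u_stat(range(n)) - n * m / 2)
    hits = total = 0
    for comb in combinations(range(n + m), n):
        total += 1
        if abs(u_stat(comb) - n * m / 2) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    @pytest.mark.parametrize("n,m", [(3, 3), (4, 4), (5, 3), (6, 6), (8, 5)])
    def test_exact_p_equals_permutation_oracle(self, n, m):
        rng = np.random.default_rng(n * 100 + m)
        for _ in range(3):
            x = rng.integers(0, 6, n).astype(float)  # ties guaranteed
            y = rng.integers(0, 6, m).astype(float)
            _, p = diffexp.rank_sum_test(x, y)
            assert p == pytest.approx(permutation_oracle(x, y), abs=1e-12)

    def test_four_vs_four_all_seventy_assignments(self):
        x = np.array([1.2, 3.4, 2.2, 5.1])
        y = np.array([0.5, 1.1, 0.9, 2.0])
        _, p = diffexp.rank_sum_test(x, y)
        oracle = permutation_oracle(x, y)
        assert p == pytest.approx(oracle, abs=1e-12)
        # oracle really enumerated C(8,4)=70 assignments: p is k/70
        assert (p * 70) == pytest.approx(round(p * 70))

    def test_asymptotic_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        _, p = diffexp.rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestBH:
    def test_hand_computed_five_value_example(self):
        p = np.array([0.005, 0.04, 0.03, 0.01, 0.20])
        # step-up by hand: sorted (.005,.01,.03,.04,.20) ->
        # (.025, .025, .05, .05, .20)
        expected = [0.025, 0.05, 0.05, 0.025, 0.20]
        assert diffexp.bh_adjust(p) == pytest.approx(expected)

    def test_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        adj = diffexp.bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestWilcoxonDE:
    def _two_group_nm(self, seed=0, n_genes=100, n_per=30, shift_genes=()):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(4, size=(n_genes, 2 * n_per)).astype(float)
        for g in shift_genes:
            counts[g, :n_per] = rng.poisson(20, n_per)
        vals = np.log1p(counts)
        return make_nm(vals), np.arange(2 * n_per) < n_per

    def test_planted_genes_found_and_ranked(self):
        nm, mask = self._two_group_nm(seed=2, shift_genes=(0, 1, 2))
        res = diffexp.wilcoxon_de(nm, mask, ~mask)
        sig_up = set(res.loc[res["significant"] & (res["direction"] == "up"), "feature"])
        assert {"g1", "g2", "g3"} <= sig_up

    def test_label_swap_antisymmetry(self):
        nm, mask = self._two_group_nm(seed=3, shift_genes=(5,))
        a = diffexp.wilcoxon_de(nm, mask, ~mask).set_index("feature")
        b = diffexp.wilcoxon_de(nm, ~mask, mask).set_index("feature")
        common = a.index.intersection(b.index)
        assert np.allclose(a.loc[common, "log_fc"], -b.loc[common, "log_fc"])
        assert np.allclose(a.loc[common, "p_value"], b.loc[common, "p_value"])

    def test_prefilters_restrict_tested_genes(self):
        nm, mask = self._two_group_nm(seed=4, shift_genes=(7,))
        res = diffexp.wilcoxon_de(nm, mask, ~mask, min_pct=0.25, logfc_threshold=0.25)
        assert np.all(np.abs(res["log_fc"]) >= 0.25)
        assert np.all((res["pct_a"] >= 0.25) | (res["pct_b"] >= 0.25))

    def test_small_group_errors(self):
        nm, _ = self._two_group_nm()
        mask = np.zeros(60, dtype=bool)
        mask[:2] = True
        with pytest.raises(ValidationError, match="3 cells"):
            diffexp.wilcoxon_de(nm, mask, ~mask)

    def test_empty_postfilter_warns(self):
        nm = make_nm(np.ones((5, 20)))
        mask = np.arange(20) < 10
        with pytest.warns(UserWarning, match="prefilter"):
            res = diffexp.wilcoxon_de(nm, mask, ~mask)
        assert len(res) == 0


class TestBulkDE:
    def _counts(self, seed, n_genes=200, n_per=3, planted=(), log2fc=2.0):
        # deep sorted-population bulk libraries: NB dispersion 0.01
        rng = np.random.default_rng(seed)
        means = np.exp(rng.normal(6, 1, n_genes))
        mu = np.tile(means[:, None], (1, 2 * n_per))
        for g in planted:
            mu[g, :n_per] *= 2.0**log2fc
        counts = rng.poisson(rng.gamma(100.0, mu / 100.0))
        cols = [f"s{i}" for i in range(2 * n_per)]
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)], columns=cols)
        groups = pd.Series(["A"] * n_per + ["B"] * n_per, index=cols)
        return df, groups

    def test_identical_gene_not_significant(self):
        df, groups = self._counts(seed=0)
        df.loc["g0"] = 100  # identical in every sample
        res = diffexp.bulk_de(df, groups, "A", "B").set_index("feature")
        assert not res.loc["g0", "significant"]

    def test_planted_power_and_fdr(self):
        """Planted log2FC=2 at n=3 vs 3: power >= 0.7 and FDR <= 0.1."""
        tp = fp = n_planted = n_called = 0
        for seed in range(20):
            planted = tuple(range(20))
            df, groups = self._counts(900 + seed, planted=planted)
            res = diffexp.bulk_de(df, groups, "A", "B")
            called = set(res.loc[res["significant"], "feature"])
            truth = {f"g{i}" for i in planted}
            tp += len(called & truth)
            fp += len(called - truth)
            n_planted += len(truth)
            n_called += len(called)
        assert tp / n_planted >= 0.7
        assert fp / max(n_called, 1) <= 0.1

    def test_fold_change_gate_applied_as_stated(self):
        """padj tiny but FC inside (0.5, 2): not called; FC outside: called."""
        rng = np.random.default_rng(5)
        n_per = 10
        means = np.full(50, 200.0)
        mu = np.tile(means[:, None], (1, 2 * n_per))
        mu[0, :n_per] *= 1.8  # strong p, FC < 2 -> must not be called
        mu[1, :n_per] *= 3.0  # strong p, FC > 2 -> called
        counts = rng.poisson(rng.gamma(200.0, mu / 200.0))
        cols = [f"s{i}" for i in range(2 * n_per)]
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(50)], columns=cols)
        groups = pd.Series(["A"] * n_per + ["B"] * n_per, index=cols)
        res = diffexp.bulk_de(df, groups, "A", "B").set_index("feature")
        assert res.loc["g0", "p_adjusted"] < 0.05 and not res.loc["g0", "significant"]
        assert res.loc["g1", "significant"]

    def test_single_replicate_errors(self):
        df, groups = self._counts(seed=1, n_per=2)
        groups.iloc[0] = "C"
        with pytest.raises(ValidationError, match="2 replicates"):
            diffexp.bulk_de(df, groups, "A", "B")

    def test_peaks_use_raw_p_criterion(self):
        df, groups = self._counts(seed=6, planted=(0,), log2fc=1.0)
        res = diffexp.differential_peaks(df, groups, "A", "B").set_index("feature")
        assert (res["p_criterion"] == "raw").all()
        # FC ~2 > 1.5 and raw p small -> called even if padj misses
        assert res.loc["g0", "significant"] == (
            (res.loc["g0", "p_value"] < 0.05)
            and (res.loc["g0", "fold_change"] > 1.5 or res.loc["g0", "fold_change"] < 1 / 1.5)
        )


def _pt(rows):
    return PeakTable(pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"]))


def consensus_bruteforce(replicate_sets, min_fraction):
    """Base-pair bitmap oracle for consensus peaks (small coordinates)."""
    limit = 3000
    cover = np.zeros(limit, dtype=bool)
    for pt in replicate_sets:
        for r in pt.table.itertuples():
            cover[r.start : r.end] = True
    # merged union intervals from the bitmap
    merged, start = [], None
    for i in range(limit + 1):
        on = cover[i] if i < limit else False
        if on and start is None:
            start = i
        elif not on and start is not None:
            merged.append((start, i))
            start = None
    kept = []
    for s, e in merged:
        support = 0
        for pt in replicate_sets:
            if any(r.start < e and s < r.end for r in pt.table.itertuples()):
                support += 1
        if support / len(replicate_sets) > min_fraction:
            kept.append((s, e))
    return kept


class TestConsensusPeaks:
    def test_quoted_rule_all_vs_one_of_three(self):
        reps = [
            _pt([("chr1", 100, 200, "a"), ("chr1", 500, 600, "b")]),
            _pt([("chr1", 150, 250, "c")]),
            _pt([("chr1", 120, 180, "d")]),
        ]
        res = consensus_peaks_table = diffexp.consensus_peaks(reps)
        intervals = list(zip(res.table["start"], res.table["end"]))
        assert (100, 250) in intervals  # present in all 3
        assert not any(s == 500 for s, _ in intervals)  # 1/3 <= 0.6 dropped

    def test_exact_60_percent_dropped(self):
        base = [("chr1", 100, 200, "p")]
        reps = [_pt([(c, s, e, f"p{i}") for c, s, e, _ in base]) for i in range(3)]
        reps += [_pt([("chr2", 5, 10, f"q{i}")]) for i in range(2)]
        res = diffexp.consensus_peaks(reps, min_fraction=0.6)
        # 3 of 5 replicates = exactly 0.6, strict "more than" drops it
        assert not any(res.table["chrom"] == "chr1")

    def test_matches_bitmap_bruteforce_on_random_intervals(self):
        rng = np.random.default_rng(17)
        reps = []
        for i in range(4):
            starts = rng.integers(0, 2500, 30)
            rows = [
                ("chr1", int(s), int(s + rng.integers(20, 150)), f"r{i}_{j}")
                for j, s in enumerate(starts)
            ]
            reps.append(_pt(rows))
        res = diffexp.consensus_peaks(reps, min_fraction=0.6)
        got = sorted(zip(res.table["start"], res.table["end"]))
        expected = sorted(consensus_bruteforce(reps, 0.6))
        assert got == expected

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            diffexp.consensus_peaks([])


class TestPeakToGenes:
    def test_boundary_5kb_inclusive(self):
        peaks = _pt([("chr1", 100, 200, "p1")])
        genes = _pt([("chr1", 5200, 6000, "gA"), ("chr1", 5201, 6000, "gB")])
        res = diffexp.peak_to_genes(peaks, genes, window=5000)
        assert set(res["gene_id"]) == {"gA"}  # distance exactly 5000 assigned
        assert res.loc[res["gene_id"] == "gA", "distance"].iloc[0] == 5000

    def test_overlap_distance_zero(self):
        peaks = _pt([("chr1", 100, 200, "p1")])
        genes = _pt([("chr1", 150, 300, "g1")])
        res = diffexp.peak_to_genes(peaks, genes)
        assert res["distance"].iloc[0] == 0

    def test_matches_bruteforce_on_random_intervals(self):
        rng = np.random.default_rng(23)
        peaks = _pt(
            [("chr1", int(s), int(s + 50), f"p{j}") for j, s in enumerate(rng.integers(0, 50_000, 60))]
        )
        genes = _pt(
            [("chr1", int(s), int(s + 400), f"g{j}") for j, s in enumerate(rng.integers(0, 50_000, 60))]
        )
        res = diffexp.peak_to_genes(peaks, genes, window=5000)
        got = set(zip(res["peak_id"], res["gene_id"]))
        expected = set()
        for p in peaks.table.itertuples():
            for g in genes.table.itertuples():
                gap = max(0, max(p.start, g.start) - min(p.end, g.end))
                if gap <= 5000:
                    expected.add((p.peak_id, g.peak_id))
        assert got == expected


class TestRegionSetSignal:
    def _universe(self, counts_a=100, counts_b=100, n_bg=100, n_open=3, open_scale=2.0):
        rows = []
        for i in range(n_bg + n_open):
            scale = open_scale if i < n_open else 1.0
            rows.append(
                {
                    "chrom": "chr1",
                    "start": i * 1000,
                    "end": i * 1000 + 500,
                    "peak_id": f"u{i}",
                    "sA1": counts_a * scale,
                    "sA2": counts_a * scale,
                    "sB1": counts_b,
                    "sB2": counts_b,
                }
            )
        return PeakTable(pd.DataFrame(rows))

    def test_identical_counts_identical_profiles(self):
        uni = self._universe(open_scale=1.0)
        regions = {"set1": _pt([("chr1", 0, 2500, "r1")])}
        groups = pd.Series({"sA1": "A", "sA2": "A", "sB1": "B", "sB2": "B"})
        summary, _ = diffexp.region_set_signal(uni, regions, groups)
        vals = summary.set_index("group")["mean_signal"]
        assert vals["A"] == pytest.approx(vals["B"])

    def test_planted_twofold_open_regions(self):
        uni = self._universe(open_scale=2.0)
        open_regions = _pt([("chr1", 0, 2500, "open")])  # covers the 3 open peaks
        groups = pd.Series({"sA1": "A", "sA2": "A", "sB1": "B", "sB2": "B"})
        summary, _ = diffexp.region_set_signal(uni, {"aging_open": open_regions}, groups)
        vals = summary.set_index("group")["mean_signal"]
        ratio = vals["A"] / vals["B"]
        assert 1.6 <= ratio <= 2.4  # ~2x within 20%

    def test_empty_region_set_errors(self):
        uni = self._universe()
        groups = pd.Series({"sA1": "A", "sA2": "A", "sB1": "B", "sB2": "B"})
        with pytest.raises(ValidationError, match="empty"):
            diffexp.region_set_signal(uni, {"bad": PeakTable(pd.DataFrame(columns=["chrom", "start", "end", "peak_id"]))}, groups)

    def test_nonoverlapping_region_warns_and_excluded(self):
        uni = self._universe()
        regions = _pt([("chr2", 0, 100, "off"), ("chr1", 0, 600, "on")])
        groups = pd.Series({"sA1": "A", "sA2": "A", "sB1": "B", "sB2": "B"})
        with pytest.warns(UserWarning, match="overlaps no universe peak"):
            summary, mats = diffexp.region_set_signal(uni, {"s": regions}, groups)
        assert list(mats["s"].index) == ["on"]
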