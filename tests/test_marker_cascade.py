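import numpy as np
import pandas as pd
import pytest

from conftest import make_nm, small_sim
from hscage.datatypes import GeneAnnotation, ValidationError
from hscage.marker_cascade import (
    correlate_genes_with_score,
    feature_score_correlation,
    marker_correlated_sets,
    pearson_matrix,
    quartile_bins,
    run_cascade,
)
from hscage.qc_norm import lognormalize
from hscage.signatures import signature_score
from hscage.synthgen import generate_bulk_quartiles, generate_sc


def pearson_oracle(x, y):
    """Direct-summation Pearson r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())


class TestCorrelation:
    def test_affine_gene_r_one(self):
        rng = np.random.default_rng(0)
        score = pd.Series(rng.normal(0, 1, 50), index=[f"c{i+1}" for i in range(50)])
        vals = rng.gamma(2, 1, size=(5, 50))
        vals[2] = 3 * score.to_numpy() + 7  # affine in the score
        nm = make_nm(np.abs(vals) if vals.min() < 0 else vals)
        nm.values[2] = 3 * score.to_numpy() + 17  # keep nonnegative
        r = correlate_genes_with_score(nm, score)
        assert r["g3"] == pytest.approx(1.0)

    def test_five_cell_worked_example(self):
        # x=(1,2,3,4,5), score=(2,4,5,4,5): hand Pearson = 6/sqrt(60)
        nm = make_nm(np.array([[1.0, 2, 3, 4, 5]]))
        score = pd.Series([2.0, 4, 5, 4, 5], index=nm.cell_ids)
        r = correlate_genes_with_score(nm, score, min_cells=5)
        assert r["g1"] == pytest.approx(0.774596669, abs=1e-8)

    def test_independent_gene_small_r(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            nm = make_nm(rng.gamma(2, 1, size=(3, 1000)))
            score = pd.Series(rng.normal(0, 1, 1000), index=nm.cell_ids)
            vals.append(abs(correlate_genes_with_score(nm, score)["g1"]))
        assert max(vals) < 0.15

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(2, 1, size=(20, 40))
        y = rng.normal(0, 1, 40)
        r = pearson_matrix(vals, y)
        for i in range(20):
            assert abs(r[i] - pearson_oracle(vals[i], y)) < 1e-12

    def test_constant_gene_flagged_zero(self):
        vals = np.ones((2, 30))
        vals[1] = np.arange(30)
        nm = make_nm(vals)
        score = pd.Series(np.arange(30, dtype=float), index=nm.cell_ids)
        r = correlate_genes_with_score(nm, score)
        assert r["g1"] == 0.0

    def test_zero_variance_score_errors(self):
        nm = make_nm(np.random.default_rng(0).gamma(2, 1, (3, 20)))
        score = pd.Series(np.ones(20), index=nm.cell_ids)
        with pytest.raises(ValidationError, match="zero variance"):
            correlate_genes_with_score(nm, score)


def _cascade_inputs(seed):
    m, ann, truth = generate_sc(small_sim(seed=seed))
    nm = lognormalize(m)
    old = (m.cell_meta["condition"] == "old").to_numpy()
    nm_old = nm.subset_cells(old)
    labels = truth.cluster_labels.loc[nm_old.cell_ids]
    return nm_old, labels, truth, ann


class TestCascade:
    def test_planted_marker_reaches_final_at_rank_one(self):
        hits = rank1 = 0
        n_seeds = 8
        for seed in range(n_seeds):
            nm_old, labels, truth, ann = _cascade_inputs(1100 + seed)
            rep = run_cascade(
                nm_old, labels, truth.aging_genes, ann,
                target_cluster="q3", aged_clusters=["q1", "q2"],
            )
            assert rep.check_nesting()
            hits += truth.marker_gene in rep.final
            rank1 += bool(rep.final) and rep.final[0] == truth.marker_gene
        assert hits == n_seeds
        assert rank1 >= round(0.95 * n_seeds)

    def test_membrane_decoys_eliminated_at_stage2(self):
        nm_old, labels, truth, ann = _cascade_inputs(1200)
        rep = run_cascade(
            nm_old, labels, truth.aging_genes, ann,
            target_cluster="q3", aged_clusters=["q1", "q2"],
        )
        decoys = ann.membrane_genes - {truth.marker_gene}
        assert not decoys & set(rep.stage2)
        # decoys did not survive past the aging-up intersection
        assert set(rep.stage3) <= truth.aging_genes

    def test_removing_membrane_flag_eliminates_at_stage3(self):
        nm_old, labels, truth, ann = _cascade_inputs(1300)
        t = ann.table.copy()
        t.loc[t["gene_id"] == truth.marker_gene, "is_membrane"] = False
        rep = run_cascade(
            nm_old, labels, truth.aging_genes, GeneAnnotation(t),
            target_cluster="q3", aged_clusters=["q1", "q2"],
        )
        assert truth.marker_gene in rep.stage2
        assert truth.marker_gene not in rep.stage3

    def test_gene_high_in_target_cluster_eliminated_at_stage4(self):
        nm_old, labels, truth, ann = _cascade_inputs(1400)
        # construct: overwrite one aging gene so q3 expresses it MOST
        g = sorted(truth.aging_genes - {truth.marker_gene})[0]
        gi = nm_old.gene_ids.index(g)
        boosted = nm_old.values.copy()
        in_q3 = (labels == "q3").to_numpy()
        boosted[gi, in_q3] = boosted[gi].max() + 5.0
        nm2 = make_nm(boosted, gene_ids=list(nm_old.gene_ids), cell_ids=list(nm_old.cell_ids))
        t = ann.table.copy()
        t.loc[t["gene_id"] == g, "is_membrane"] = True  # let it reach stage 4
        rep = run_cascade(
            nm2, labels, truth.aging_genes, GeneAnnotation(t),
            target_cluster="q3", aged_clusters=["q1", "q2"],
        )
        if g in rep.stage3:  # only meaningful if it survives stages 1-3
            assert g not in rep.stage4

    def test_empty_target_cluster_errors(self):
        nm_old, labels, truth, ann = _cascade_inputs(1500)
        with pytest.raises(ValidationError, match="target cluster"):
            run_cascade(
                nm_old, labels, truth.aging_genes, ann,
                target_cluster="zz", aged_clusters=["q1", "q2"],
            )

    def test_k_exceeding_gene_count_errors(self):
        nm_old, labels, truth, ann = _cascade_inputs(1600)
        with pytest.raises(ValidationError, match="K="):
            run_cascade(
                nm_old, labels, truth.aging_genes, ann,
                target_cluster="q3", aged_clusters=["q1", "q2"], K=10_000,
            )


class TestQuartileBins:
    def test_eight_values(self):
        bins = quartile_bins(pd.Series([1, 2, 3, 4, 5, 6, 7, 8.0]))
        assert bins.tolist() == ["G1", "G1", "G2", "G2", "G3", "G3", "G4", "G4"]

    def test_all_equal_warns_and_splits_stably(self):
        with pytest.warns(UserWarning, match="equal"):
            bins = quartile_bins(pd.Series([2.0] * 8))
        assert bins.tolist() == ["G1", "G1", "G2", "G2", "G3", "G3", "G4", "G4"]

    def test_matches_sorted_quartile_oracle(self):
        rng = np.random.default_rng(7)
        vals = pd.Series(rng.normal(0, 1, 100))
        bins = quartile_bins(vals)
        order = np.argsort(vals.to_numpy(), kind="stable")
        expected = np.empty(100, dtype=object)
        for b in range(4):
            expected[order[b * 25 : (b + 1) * 25]] = f"G{b+1}"
        assert bins.tolist() == expected.tolist()

    def test_too_few_values_errors(self):
        with pytest.raises(ValidationError):
            quartile_bins([1, 2, 3], n_bins=4)


class TestMarkerCorrelatedSets:
    def test_planted_genes_recovered(self):
        hit = miss = 0
        for seed in range(20):
            bulk, levels, truth = generate_bulk_quartiles(small_sim(seed=1700 + seed))
            fs = marker_correlated_sets(bulk, levels)
            hit += len(set(fs.positive) & truth.bulk_positive_genes)
            miss += len(truth.bulk_positive_genes - set(fs.positive))
        assert hit / (hit + miss) >= 0.9

    def test_permuted_levels_land_in_neither_set(self):
        neither = total = 0
        for seed in range(20):
            rng = np.random.default_rng(1800 + seed)
            bulk, levels, truth = generate_bulk_quartiles(small_sim(seed=1800 + seed))
            permuted = pd.Series(
                rng.permutation(levels.to_numpy()), index=levels.index
            )
            fs = marker_correlated_sets(bulk, permuted)
            flat = [g for g in bulk.index if g not in truth.bulk_positive_genes
                    and g not in truth.bulk_negative_genes][:20]
            neither += sum(1 for g in flat if g not in fs.positive and g not in fs.negative)
            total += len(flat)
        assert neither / total >= 0.9

    def test_threshold_one_keeps_only_affine_genes(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.integers(50, 200, size=(30, 12)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(12)],
        )
        # define marker level AS g0's transformed expression -> r exactly 1
        cpm = counts / counts.sum(axis=0) * 1e6
        levels = np.log2(cpm.loc["g0"] + 1)
        fs = marker_correlated_sets(counts, levels, r_threshold=1.0 - 1e-12)
        assert fs.positive == ["g0"]
        assert fs.negative == []

    def test_constant_marker_level_errors(self):
        bulk, levels, _ = generate_bulk_quartiles(small_sim(seed=1))
        with pytest.raises(ValidationError):
            marker_correlated_sets(bulk, pd.Series(1.0, index=levels.index))


class TestFeatureScoreCorrelation:
    def test_identity_sets_r_one(self, sc_small):
        _, _, truth, nm = sc_small
        genes = sorted(truth.aging_genes)
        R, p, _ = feature_score_correlation(nm, genes, genes)
        assert R == pytest.approx(1.0)

    def test_disjoint_null_sets_uncorrelated(self):
        Rs = []
        for seed in range(10):
            rng = np.random.default_rng(1900 + seed)
            nm = make_nm(rng.gamma(2, 1, size=(50, 2000)))
            R, _, _ = feature_score_correlation(
                nm, [f"g{i}" for i in range(1, 16)], [f"g{i}" for i in range(16, 31)]
            )
            Rs.append(abs(R))
        assert np.mean(Rs) < 0.1

    def test_bulk_derived_features_track_aging_score(self):
        """Feature genes from marker-level quartile bulk correlate with the
        aging score on single cells (the cross-modality consistency the
        marker is chosen for)."""
        Rs = []
        for seed in range(10):
            cfg = small_sim(seed=2000 + seed)
            m, _, truth = generate_sc(cfg)
            nm = lognormalize(m)
            bulk, levels, _ = generate_bulk_quartiles(cfg)
            fs = marker_correlated_sets(bulk, levels)
            R, _, _ = feature_score_correlation(nm, fs.positive, sorted(truth.aging_genes))
            Rs.append(R)
        assert np.mean(Rs) >= 0.6
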