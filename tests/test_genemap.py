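"""Correlation map, density threshold, Fisher enrichment, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from morphomap import genemap
from morphomap.errors import DegenerateInputError, MorphomapError
from morphomap.io import PLATE, REPLICATE, TREATMENT, WELL, ProfileMatrix


def _collapsed(vectors: dict) -> ProfileMatrix:
    recs = []
    for t, v in vectors.items():
        rec = {TREATMENT: t}
        rec.update({f"PC{i:03d}": float(x) for i, x in enumerate(v)})
        recs.append(rec)
    return ProfileMatrix(pd.DataFrame(recs), stage="collapsed")


class TestCorrelationMatrix:
    def test_proportional_profiles_correlate_at_one(self):
        corr = genemap.correlation_matrix(
            _collapsed({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        )
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert (np.diag(corr) == 1.0).all()

    def test_negated_profile_correlates_at_minus_one(self):
        corr = genemap.correlation_matrix(
            _collapsed({"a": [1.0, -2.0, 3.0], "b": [-1.0, 2.0, -3.0]})
        )
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_random_profiles_decorrelate_with_dimension(self):
        rng = np.random.default_rng(0)
        corr = genemap.correlation_matrix(
            _collapsed({f"g{i}": rng.normal(size=100) for i in range(6)})
        )
        off = corr.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 4 / np.sqrt(100)

    def test_constant_profile_is_named_in_the_error(self):
        with pytest.raises(DegenerateInputError, match="flatliner"):
            genemap.correlation_matrix(
                _collapsed({"ok": [1.0, 2.0, 3.0], "flatliner": [5.0, 5.0, 5.0]})
            )


class TestDensityIntersection:
    def test_symmetric_unit_gaussians_cross_at_the_midpoint(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, size=20000)
        b = rng.normal(1.0, 1.0, size=20000)
        thr = genemap.density_intersection_threshold(b, a)
        assert thr == pytest.approx(0.5, abs=0.05)

    def test_unequal_variances_match_the_closed_form_root(self):
        # densities of N(0,1) and N(1, 0.25): solve the quadratic from the
        # log-density difference for the root between the means
        s1, s2, m1, m2 = 1.0, 0.5, 0.0, 1.0
        A = 1 / (2 * s2**2) - 1 / (2 * s1**2)
        B = -m2 / s2**2 + m1 / s1**2
        C = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + np.log(s2 / s1)
        roots = np.roots([A, B, C])
        root = float([r for r in roots if m1 < r < m2][0])
        rng = np.random.default_rng(2)
        a = rng.normal(m1, s1, size=40000)
        b = rng.normal(m2, s2, size=40000)
        thr = genemap.density_intersection_threshold(b, a)
        assert thr == pytest.approx(root, abs=0.05)

    def test_threshold_is_scale_equivariant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, size=8000)
        b = rng.normal(2.0, 1.0, size=8000)
        thr = genemap.density_intersection_threshold(b, a)
        thr_scaled = genemap.density_intersection_threshold(3 * b, 3 * a)
        assert thr_scaled == pytest.approx(3 * thr, abs=0.1)

    def test_misordered_samples_are_rejected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(1.0, 1.0, size=100)
        b = rng.normal(0.0, 1.0, size=100)
        with pytest.raises(MorphomapError, match="manual threshold"):
            genemap.density_intersection_threshold(b, a)


class TestFisher:
    def test_interaction_table_reproduces_printed_p_value(self):
        # 13/143 highly correlated pairs annotated vs 128/2485 others
        res = genemap.fisher_test([[13, 130], [128, 2357]])
        assert res.p_value == pytest.approx(0.04, abs=0.005)

    def test_pathway_table_reproduces_printed_p_value(self):
        res = genemap.fisher_test([[29, 114], [139, 2346]])
        assert res.p_value == pytest.approx(7.53e-9, rel=0.05)

    def test_identical_row_proportions_are_not_enriched(self):
        res = genemap.fisher_test([[10, 90], [20, 180]])
        assert res.p_value >= 0.5

    def test_matches_brute_force_hypergeometric_tail(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            t = rng.integers(0, 30, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            res = genemap.fisher_test(t)
            a, b, c, d = t.ravel()
            expected = float(
                hypergeom.sf(a - 1, a + b + c + d, a + c, a + b)
            )
            assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_degenerate_margins_return_one_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = genemap.fisher_test([[0, 0], [5, 7]])
        assert res.p_value == 1.0

    def test_enrichment_from_matrix_and_relation(self):
        rng = np.random.default_rng(6)
        # two tight pairs + noise genes; relation annotates the tight pairs
        base1, base2 = rng.normal(size=20), rng.normal(size=20)
        vecs = {
            "a1": base1, "a2": base1 + 0.01 * rng.normal(size=20),
            "b1": base2, "b2": base2 + 0.01 * rng.normal(size=20),
        }
        for i in range(6):
            vecs[f"n{i}"] = rng.normal(size=20)
        corr = genemap.correlation_matrix(_collapsed(vecs))
        relation = {frozenset(("a1", "a2")), frozenset(("b1", "b2"))}
        res = genemap.fisher_enrichment(corr, 0.8, relation)
        assert res.table[0, 0] == 2  # both annotated pairs are correlated
        assert res.p_value < 0.05


class TestDendrogram:
    def test_nearest_pair_merges_first_at_its_distance(self):
        corr = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        dendro = genemap.build_dendrogram(corr)
        first = dendro.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.1)

    def test_duplicate_profiles_merge_at_height_zero(self):
        v = [1.0, 2.0, 3.0, 1.5]
        corr = genemap.correlation_matrix(
            _collapsed({"a": v, "b": v, "c": [3.0, -1.0, 0.0, 2.0]})
        )
        dendro = genemap.build_dendrogram(corr)
        assert dendro.heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_heights_match_reference_average_linkage(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            X = np.random.default_rng(seed).normal(size=(8, 30))
            corr = genemap.correlation_matrix(
                _collapsed({f"g{i}": X[i] for i in range(8)})
            )
            mine = genemap.build_dendrogram(corr).linkage
            D = squareform(1 - corr.to_numpy(), checks=False)
            ref = linkage(D, method="average")
            np.testing.assert_allclose(mine[:, 2], ref[:, 2], atol=1e-12)
        assert (np.diff(mine[:, 2]) >= -1e-12).all()  # monotone merges


def _random_dendrogram(seed: int, n: int = 12) -> genemap.Dendrogram:
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 20))
    corr = genemap.correlation_matrix(
        _collapsed({f"g{i:02d}": X[i] for i in range(n)})
    )
    return genemap.build_dendrogram(corr)


class TestStability:
    def test_no_heights_near_the_grid_means_all_scores_one(self):
        # three tight groups merging far outside the cutoff grid
        rng = np.random.default_rng(8)
        base = rng.normal(size=(3, 50))
        vecs = {}
        for g in range(3):
            for j in range(3):
                vecs[f"g{g}_{j}"] = base[g] + 0.01 * rng.normal(size=50)
        dendro = genemap.build_dendrogram(
            genemap.correlation_matrix(_collapsed(vecs))
        )
        curve = genemap.stability_curve(dendro)
        assert (curve.scores == 1.0).all()
        assert (curve.smoothed == 1.0).all()

    def test_scores_match_brute_force_cut_tree_comparison(self):
        cfg = genemap.ClusteringConfig()
        for seed in range(4):
            dendro = _random_dendrogram(seed)
            curve = genemap.stability_curve(dendro, cfg)
            for k in range(0, len(curve.cutoffs), 17):
                c = curve.cutoffs[k]
                # independent route: scipy cut_tree at the two heights
                lo = cut_tree(dendro.linkage, height=1 - (c - cfg.epsilon)).ravel()
                hi = cut_tree(dendro.linkage, height=1 - (c + cfg.epsilon)).ravel()
                stable = 0
                for i in range(len(lo)):
                    m_lo = set(np.flatnonzero(lo == lo[i]))
                    m_hi = set(np.flatnonzero(hi == hi[i]))
                    stable += m_lo == m_hi
                assert curve.scores[k] == pytest.approx(stable / len(lo))

    def test_constant_curve_argmax_takes_the_smallest_cutoff(self):
        curve = genemap.StabilityCurve(
            cutoffs=np.array([0.43, 0.45, 0.47]),
            scores=np.ones(3),
            smoothed=np.ones(3),
        )
        assert curve.choose_cutoff() == pytest.approx(0.43)

    def test_scores_stay_in_unit_interval_after_smoothing(self):
        curve = genemap.stability_curve(_random_dendrogram(9))
        assert ((curve.scores >= 0) & (curve.scores <= 1)).all()
        assert ((curve.smoothed >= 0) & (curve.smoothed <= 1)).all()


class TestClusters:
    def test_cutoff_above_all_merges_gives_singletons(self):
        dendro = _random_dendrogram(10)
        # correlation level above every merge's 1 - height
        clusters = genemap.cut_clusters(dendro, corr_cutoff=0.9999)
        assert len(clusters) == len(dendro.labels)

    def test_cutoff_below_all_merges_gives_one_cluster(self):
        dendro = _random_dendrogram(11)
        clusters = genemap.cut_clusters(dendro, corr_cutoff=-1.0)
        assert len(clusters) == 1

    def test_clusters_partition_the_treatments(self):
        dendro = _random_dendrogram(12)
        clusters = genemap.cut_clusters(dendro, corr_cutoff=0.2)
        members = sorted(m for ms in clusters.values() for m in ms)
        assert members == sorted(dendro.labels)

    def test_planted_groups_recovered_with_high_ari(self, hit_result,
                                                    small_experiment):
        from sklearn.metrics import adjusted_rand_score

        _, truth = small_experiment
        effects = [t for t in hit_result.final_hits if not truth.is_null[t]]
        collapsed = ProfileMatrix(
            hit_result.collapsed.data[
                hit_result.collapsed.data[TREATMENT].isin(effects)
            ].reset_index(drop=True),
            stage="collapsed",
        )
        gmap = genemap.build_gene_map(collapsed)
        ari = adjusted_rand_score(
            [truth.group_of[t] for t in gmap.correlations.index],
            [gmap.cluster_of(t) for t in gmap.correlations.index],
        )
        assert ari >= 0.8

    def test_summaries_separate_within_from_cross_correlation(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=(2, 40))
        vecs = {}
        for g in range(2):
            for j in range(3):
                vecs[f"g{g}_{j}"] = base[g] + 0.05 * rng.normal(size=40)
        corr = genemap.correlation_matrix(_collapsed(vecs))
        clusters = {1: [f"g0_{j}" for j in range(3)],
                    2: [f"g1_{j}" for j in range(3)]}
        summaries = genemap.cluster_summaries(clusters, corr)
        for cid in (1, 2):
            s = summaries[cid]
            assert s.within_correlation > s.cross_correlation.max()
            assert not s.is_singleton
        # top-negative lists rank outsiders by average correlation
        s1 = summaries[1]
        assert set(s1.top_negative.index) <= set(clusters[2])

    def test_singletons_are_flagged(self):
        rng = np.random.default_rng(14)
        vecs = {f"g{i}": rng.normal(size=30) for i in range(4)}
        corr = genemap.correlation_matrix(_collapsed(vecs))
        clusters = genemap.cut_clusters(
            genemap.build_dendrogram(corr), corr_cutoff=0.9999
        )
        summaries = genemap.cluster_summaries(clusters, corr)
        assert all(s.is_singleton for s in summaries.values())
        assert all(np.isnan(s.within_correlation) for s in summaries.values())
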