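"""Hit calling: centering, statistic, nulls, distance check, comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from morphomap import hits, simulate, profiling, selection
from morphomap.errors import DegenerateInputError
from morphomap.io import (
    NEGATIVE_CONTROL,
    PLATE,
    REPLICATE,
    TREATMENT,
    WELL,
    ProfileMatrix,
)


def _pm(rows, stage="reduced"):
    """rows: list of (plate, well, treatment, replicate, vector)."""
    recs = []
    for plate, well, t, rep, vec in rows:
        rec = {PLATE: plate, WELL: well, TREATMENT: t, REPLICATE: rep}
        rec.update({f"PC{i:03d}": float(v) for i, v in enumerate(vec)})
        recs.append(rec)
    return ProfileMatrix(pd.DataFrame(recs), stage=stage)


class TestCentering:
    def test_control_rows_center_at_zero_per_plate(self, reduced_centered):
        centered, _ = reduced_centered
        for _, sub in centered.controls().groupby(PLATE, observed=True):
            med = sub[centered.value_columns].median()
            np.testing.assert_allclose(med, 0.0, atol=1e-10)

    def test_plate_without_controls_raises(self):
        pm = _pm([("P1", "A01", "g1", 1, [1.0, 2.0])])
        with pytest.raises(DegenerateInputError, match="P1"):
            hits.center_to_controls(pm)


class TestStatistic:
    def test_identical_replicates_score_one(self):
        rows = [(f"P{r}", "A01", "g", r, [1.0, 0.5, -2.0]) for r in range(1, 6)]
        stats = hits.treatment_replicate_correlation(_pm(rows))
        assert stats.loc["g", "statistic"] == pytest.approx(1.0)

    def test_anticorrelated_pair_scores_minus_one(self):
        rows = [("P1", "A01", "g", 1, [1.0, 0.0, -1.0]),
                ("P2", "A01", "g", 2, [-1.0, 0.0, 1.0])]
        stats = hits.treatment_replicate_correlation(_pm(rows))
        assert stats.loc["g", "statistic"] == pytest.approx(-1.0)

    def test_isotropic_noise_stays_near_zero(self):
        rng = np.random.default_rng(0)
        d = 50
        rows = [(f"P{r}", "A01", "g", r, rng.normal(size=d)) for r in (1, 2, 3)]
        stats = hits.treatment_replicate_correlation(_pm(rows))
        assert abs(stats.loc["g", "statistic"]) < 3 / np.sqrt(d)

    def test_single_replicate_is_flagged_undefined(self):
        rows = [("P1", "A01", "g", 1, [1.0, 2.0, 3.0]),
                ("P1", "A02", "h", 1, [1.0, 2.0, 3.0]),
                ("P2", "A02", "h", 2, [1.0, 2.0, 4.0])]
        stats = hits.treatment_replicate_correlation(_pm(rows))
        assert not stats.loc["g", "defined"]
        assert np.isnan(stats.loc["g", "statistic"])
        assert stats.loc["h", "defined"]


class TestNullThreshold:
    def test_pairwise_pool_matches_brute_force(self):
        rng = np.random.default_rng(1)
        rows = []
        for t in range(6):
            for r in (1, 2):
                rows.append((f"P{r}", f"A{t+1:02d}", f"g{t}", r,
                             rng.normal(size=12)))
        pm = _pm(rows)
        thr = hits.null_threshold(pm, group_size=1)
        # brute force over all cross-treatment pairs
        df = pm.data
        X = df[pm.value_columns].to_numpy()
        pool = []
        for i, j in itertools.combinations(range(len(df)), 2):
            if df[TREATMENT].iloc[i] != df[TREATMENT].iloc[j]:
                pool.append(np.corrcoef(X[i], X[j])[0, 1])
        assert thr == pytest.approx(np.percentile(pool, 95.0))

    def test_identical_treatments_give_degenerate_threshold_one(self):
        vec = [1.0, 2.0, 3.0]
        rows = [("P1", "A01", "g1", 1, vec), ("P1", "A02", "g2", 1, vec)]
        with pytest.warns(UserWarning, match="degenerate"):
            thr = hits.null_threshold(_pm(rows), group_size=1)
        assert thr == pytest.approx(1.0)

    def test_median_percentile_of_symmetric_null_is_near_zero(self):
        rng = np.random.default_rng(2)
        rows = [("P1", f"A{t:02d}", f"g{t}", 1, rng.normal(size=40))
                for t in range(40)]
        cfg = hits.HitCallConfig(null_percentile=50.0001)
        thr = hits.null_threshold(_pm(rows), cfg, group_size=1)
        assert abs(thr) < 3 / np.sqrt(40)

    def test_group_matched_null_calibrates_the_hit_rate(self):
        """Under a global null the group-matched threshold yields ~5% hits."""
        rng = np.random.default_rng(3)
        n_t, n_rep, d = 150, 5, 30
        rows = []
        for t in range(n_t):
            for r in range(1, n_rep + 1):
                rows.append((f"P{r}", f"W{t}", f"g{t:03d}", r, rng.normal(size=d)))
        pm = _pm(rows)
        thr = hits.null_threshold(pm, group_size=n_rep, seed=7)
        stats = hits.treatment_replicate_correlation(pm)
        rate = float((stats["statistic"] > thr).mean())
        # 99% binomial CI around 5% with n = 150
        assert abs(rate - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / n_t)


class TestPessimisticNull:
    def _experiment(self, polish: bool):
        cfg = simulate.SimulationConfig(
            n_treatments=10, n_negative_control_wells=14, plate_rows=4,
            plate_cols=6, n_features=15, cells_per_well_mean=80, seed=11,
            effect_magnitude=0.0, fraction_null=1.0,
            row_artifact_sd=0.6, col_artifact_sd=0.6, n_constant_features=0,
        )
        cells, _ = simulate.simulate_experiment(cfg)
        norm = profiling.normalize_cells(cells)
        prof = profiling.zscore_cell_count(profiling.aggregate_well(norm))
        if polish:
            prof = profiling.median_polish(prof, max_iter=300)
        return prof

    def test_unpolished_artifacts_inflate_the_pessimistic_null(self):
        prof = self._experiment(polish=False)
        pess = hits.pessimistic_null_threshold(prof, plate_shape=(4, 6))
        std = hits.null_threshold(prof, group_size=1)
        assert pess >= std

    def test_all_edge_controls_is_an_error(self):
        rows = [("P1", "A01", NEGATIVE_CONTROL, 1, [1.0, 2.0]),
                ("P2", "A01", NEGATIVE_CONTROL, 2, [2.0, 1.0]),
                ("P1", "B02", "g1", 1, [0.0, 1.0])]
        with pytest.raises(DegenerateInputError, match="position-matched"):
            hits.pessimistic_null_threshold(_pm(rows), plate_shape=(2, 2))


class TestCollapseAndDistance:
    def test_collapse_is_the_replicate_mean(self):
        rows = [("P1", "A01", "g", 1, [0.0, 0.0]),
                ("P2", "A01", "g", 2, [2.0, 2.0])]
        coll = hits.collapse_replicates(_pm(rows))
        np.testing.assert_allclose(coll.matrix()[0], [1.0, 1.0])

    def test_collapse_single_replicate_is_identity_and_permutation_invariant(self):
        rows = [("P1", "A01", "g", 1, [3.0, -1.0]),
                ("P2", "A01", "h", 1, [1.0, 5.0]),
                ("P3", "A01", "h", 2, [3.0, 7.0])]
        coll = hits.collapse_replicates(_pm(rows))
        coll_rev = hits.collapse_replicates(_pm(rows[::-1]))
        pd.testing.assert_frame_equal(
            coll.data.sort_values(TREATMENT).reset_index(drop=True),
            coll_rev.data.sort_values(TREATMENT).reset_index(drop=True),
        )
        assert coll.data.set_index(TREATMENT).loc["g", "PC000"] == 3.0

    def test_profile_at_control_centroid_fails_far_profile_passes(self):
        rng = np.random.default_rng(4)
        ctrl_rows = [("P1", f"A{i:02d}", NEGATIVE_CONTROL, 1,
                      rng.normal(size=10)) for i in range(20)]
        pm = _pm(ctrl_rows)
        near = hits.collapse_replicates(
            _pm([("P1", "B01", "near", 1, np.zeros(10))]))
        far = hits.collapse_replicates(
            _pm([("P1", "B02", "far", 1, 30.0 * np.ones(10))]))
        assert not hits.distance_check(near, pm).loc["near"]
        assert hits.distance_check(far, pm).loc["far"]

    def test_controls_against_themselves_pass_at_about_five_percent(self):
        rng = np.random.default_rng(5)
        n = 200
        ctrl_rows = [("P1", f"A{i}", NEGATIVE_CONTROL, 1, rng.normal(size=8))
                     for i in range(n)]
        pm = _pm(ctrl_rows)
        # treat each control as a pseudo-treatment
        pseudo = _pm([("P1", f"A{i}", f"c{i}", 1, vec)
                      for i, (_, _, _, _, vec) in enumerate(ctrl_rows)])
        coll = hits.collapse_replicates(pseudo)
        passed = hits.distance_check(coll, pm)
        assert abs(passed.mean() - 0.05) < 0.05


class TestCallHits:
    def test_planted_effects_are_recovered_and_nulls_filtered(
        self, hit_result, small_experiment
    ):
        _, truth = small_experiment
        effects = {t for t in truth.treatments if not truth.is_null[t]}
        assert effects <= set(hit_result.hits)
        # the control-similarity exclusion removes null treatments
        assert set(hit_result.final_hits) <= set(hit_result.hits)
        assert effects <= set(hit_result.final_hits)

    def test_hit_statistics_exceed_threshold(self, hit_result):
        st = hit_result.statistics
        for t in hit_result.hits:
            assert st.loc[t, "statistic"] > hit_result.threshold

    def test_hit_probability_is_monotone_in_effect_size(self):
        """Sweep the planted effect upward: hit counts never decrease."""
        import warnings

        rates = []
        for mag in (0.0, 1.0, 2.5):
            cfg = simulate.SimulationConfig(
                n_treatments=12, n_negative_control_wells=4, plate_rows=4,
                plate_cols=4, n_features=15, cells_per_well_mean=80, seed=21,
                effect_magnitude=mag, fraction_null=0.0, n_groups=12,
            )
            cells, _ = simulate.simulate_experiment(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                norm = profiling.normalize_cells(cells)
                # no polish: no artifacts planted, and a 4x4 grid is too
                # small for row/column medians to be meaningful
                prof = profiling.zscore_cell_count(profiling.aggregate_well(norm))
                red = selection.pca_reduce(prof)
                cen = hits.center_to_controls(red.profiles)
                res = hits.call_hits(cen, seed=5)
            rates.append(len(res.hits))
        assert rates == sorted(rates)
        assert rates[-1] == 12  # very large effects: all hits


class TestClonePairs:
    def test_identical_constructs_correlate_above_any_threshold(self):
        rng = np.random.default_rng(6)
        vecs = {f"g{i}": rng.normal(size=12) for i in range(8)}
        vecs["g0_clone"] = vecs["g0"]
        rows = [("P1", f"A{i}", t, 1, v) for i, (t, v) in enumerate(vecs.items())]
        coll = hits.collapse_replicates(_pm(rows))
        table, thr, frac = hits.clone_pair_consistency(
            coll, [("g0", "g0_clone")]
        )
        assert table["correlation"].iloc[0] == pytest.approx(1.0)
        assert frac == 1.0

    def test_unrelated_pairs_beat_threshold_about_five_percent(self):
        rng = np.random.default_rng(7)
        rows = [("P1", f"A{i}", f"g{i}", 1, rng.normal(size=25))
                for i in range(40)]
        coll = hits.collapse_replicates(_pm(rows))
        pairs = [(f"g{2*i}", f"g{2*i+1}") for i in range(20)]
        # threshold from all *other* pairs; planted pairs are just noise
        _, thr, frac = hits.clone_pair_consistency(coll, pairs)
        assert frac <= 0.25  # 5% expected; generous bound at n = 20

    def test_pairs_with_missing_member_are_excluded_with_warning(self):
        rng = np.random.default_rng(8)
        rows = [("P1", f"A{i}", f"g{i}", 1, rng.normal(size=10))
                for i in range(5)]
        coll = hits.collapse_replicates(_pm(rows))
        with pytest.warns(UserWarning, match="excluded"):
            table, _, _ = hits.clone_pair_consistency(
                coll, [("g0", "not_a_hit"), ("g1", "g2")]
            )
        assert len(table) == 1


class TestAlleleStrength:
    def test_equal_pairs_give_half(self):
        stats = {"a1": 0.5, "w1": 0.5, "a2": 0.7, "w2": 0.7}
        p = hits.compare_allele_strength(stats, [("a1", "w1"), ("a2", "w2")])
        assert p == pytest.approx(0.5)

    def test_strong_consistent_advantage_is_significant(self):
        stats = {}
        pairs = []
        for i in range(5):
            stats[f"a{i}"] = 0.9 + 0.001 * i
            stats[f"w{i}"] = 0.1 + 0.003 * i  # differences vary across pairs
            pairs.append((f"a{i}", f"w{i}"))
        p = hits.compare_allele_strength(stats, pairs)
        assert p < 0.01
        # verified against the closed-form t CDF: d = 0.8 exactly, sd = 0
        # is avoided by the per-pair offsets; compute the reference
        import scipy.stats as sps

        d = np.array([stats[a] - stats[w] for a, w in pairs])
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert p == pytest.approx(float(sps.t.sf(t, df=len(d) - 1)))

    def test_sign_flip_complements_the_p_value(self):
        stats = {"a1": 0.6, "w1": 0.3, "a2": 0.8, "w2": 0.5, "a3": 0.4,
                 "w3": 0.45}
        pairs = [("a1", "w1"), ("a2", "w2"), ("a3", "w3")]
        p = hits.compare_allele_strength(stats, pairs)
        flipped = hits.compare_allele_strength(stats, [(w, a) for a, w in pairs])
        assert p + flipped == pytest.approx(1.0)

    def test_fewer_than_two_pairs_is_an_error(self):
        with pytest.raises(DegenerateInputError):
            hits.compare_allele_strength({"a": 1.0, "w": 0.0}, [("a", "w")])


class TestPathwayStrength:
    def test_single_member_pathway(self):
        out = hits.pathway_strength_summary(
            {"g1": 0.42}, {"hippo": ["g1"]}
        )
        assert out.loc["hippo", "mean_strength"] == pytest.approx(0.42)
        assert out.loc["hippo", "sd_strength"] == 0.0

    def test_two_member_mean(self):
        out = hits.pathway_strength_summary(
            {"g1": 0.2, "g2": 0.4}, {"pw": ["g1", "g2"]}
        )
        assert out.loc["pw", "mean_strength"] == pytest.approx(0.3)

    def test_wild_type_clones_counted_once(self):
        out = hits.pathway_strength_summary(
            {"g1_c1": 0.2, "g1_c2": 0.4, "g2": 0.6},
            {"pw": ["g1", "g2"]},
            gene_of={"g1_c1": "g1", "g1_c2": "g1"},
        )
        assert out.loc["pw", "n_genes"] == 2
        assert out.loc["pw", "mean_strength"] == pytest.approx((0.3 + 0.6) / 2)

    def test_planted_strong_pathway_outranks_null_pathway(self, hit_result,
                                                          small_experiment):
        _, truth = small_experiment
        effects = [t for t in truth.treatments if not truth.is_null[t]]
        nulls = [t for t in truth.treatments if truth.is_null[t]]
        stats = hit_result.statistics["statistic"]
        out = hits.pathway_strength_summary(
            stats.to_dict(), {"strong": effects, "weak": nulls}
        )
        assert out.loc["strong", "mean_strength"] > out.loc["weak", "mean_strength"]

    def test_empty_pathway_omitted_with_warning(self):
        with pytest.warns(UserWarning, match="no members"):
            out = hits.pathway_strength_summary({"g1": 0.2}, {"empty": ["zz"]})
        assert len(out) == 0
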