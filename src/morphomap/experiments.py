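"""Canned synthetic study-condition experiments.

These functions run the full pipeline on fixed synthetic designs with
known ground truth and measure how well each stage recovers it:
null-calibration of the hit rate, detection power at a
three-sigma-calibrated planted effect, clustering recovery of planted
gene groups, and subpopulation-enrichment consistency (positive and
control-split negative).  They serve as reproducible end-to-end
benchmarks for the package; seeds control every source of randomness.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from . import genemap, hits, profiling, selection, simulate, subpop
from .io import NEGATIVE_CONTROL, TREATMENT, WELL, ProfileMatrix
from .names import CELL_COUNT, MAD_PREFIX


def profile_cells(cells, polish: bool = True) -> ProfileMatrix:
    """normalize -> aggregate -> count z-score -> (optional) median polish."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = profiling.normalize_cells(cells)
        prof = profiling.zscore_cell_count(profiling.aggregate_well(norm))
        if polish:
            prof = profiling.median_polish(prof)
    return prof


def run_screen(cfg: simulate.SimulationConfig, seed: int,
               select: bool = True):
    """Simulate and carry one experiment to hit calls.

    Returns (truth, hit result); when ``select`` is off the
    replicate-correlation selection stages are skipped (pure-null data
    retains no reproducible feature by construction) and PCA runs on the
    polished profiles directly.
    """
    cells, truth = simulate.simulate_experiment(cfg)
    prof = profile_cells(cells)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if select:
            filtered = selection.filter_features(prof)
            prof = selection.select_features(filtered).profiles
        reduced = selection.pca_reduce(prof)
        centered = hits.center_to_controls(reduced.profiles)
        result = hits.call_hits(centered, seed=seed)
    return truth, result, centered


# ---------------------------------------------------------------------------
# null calibration

NULL_CALIBRATION_CONFIG = simulate.SimulationConfig(
    n_treatments=200,
    n_negative_control_wells=40,
    plate_rows=16,
    plate_cols=15,
    n_features=30,
    cells_per_well_mean=50,
    effect_magnitude=0.0,
    fraction_null=1.0,
    n_constant_features=0,
)


def null_calibration(seed: int) -> dict:
    """Hit rate of a pure-null screen (200 treatments, 5 replicates).

    With the group-matched empirical null, the rate should sit near the
    nominal 5% false-call level.
    """
    cfg = replace(NULL_CALIBRATION_CONFIG, seed=seed)
    _, result, _ = run_screen(cfg, seed=seed + 1, select=False)
    n = len(result.statistics)
    return {"hit_rate": len(result.hits) / n, "n_treatments": n}


# ---------------------------------------------------------------------------
# effect recovery power

POWER_BASE_CONFIG = simulate.SimulationConfig(
    n_treatments=18,
    n_negative_control_wells=6,
    plate_rows=4,
    plate_cols=6,
    n_features=20,
    cells_per_well_mean=100,
    fraction_null=0.2,
    n_groups=15,  # every planted treatment carries its own direction
    within_group_noise=0.0,
)


def three_sigma_magnitude(seed: int,
                          cfg: simulate.SimulationConfig = POWER_BASE_CONFIG,
                          factor: float = 3.0) -> float:
    """Effect magnitude whose per-feature profile shift equals ``factor``
    times the per-feature replicate noise of a matched null screen.

    A null pilot (all effects off) measures (a) the median per-feature
    replicate scatter of polished profiles in normalized units and
    (b) the raw control MAD that the normalization divides by; a unit
    effect magnitude spreads 1/sqrt(F) per feature in raw units.
    """
    null_cfg = replace(simulate.null_config(cfg), seed=seed)
    cells, _ = simulate.simulate_experiment(null_cfg)
    prof = profile_cells(cells)
    median_cols = [
        c for c in prof.value_columns
        if c != CELL_COUNT and not c.startswith(f"{MAD_PREFIX}_")
    ]
    scatter = (
        prof.non_controls()
        .groupby(TREATMENT, observed=True)[median_cols]
        .std(ddof=1)
    )
    noise = float(scatter.median().median())
    ctrl = cells.data[cells.data[TREATMENT] == NEGATIVE_CONTROL]
    raw = ctrl[cells.feature_names]
    mad_raw = float((raw - raw.median()).abs().median().median())
    per_unit_shift = 1.0 / (
        np.sqrt(cfg.n_features) * profiling.MAD_SCALE * mad_raw
    )
    return factor * noise / per_unit_shift


def effect_power(n_repeats: int, seed: int,
                 magnitude: float | None = None) -> dict:
    """Fraction of planted-effect treatments called hits, over seeded
    repeats of the base design at a three-sigma planted effect."""
    if magnitude is None:
        magnitude = three_sigma_magnitude(seed)
    called = total = 0
    for r in range(n_repeats):
        cfg = replace(POWER_BASE_CONFIG, seed=seed + r,
                      effect_magnitude=magnitude)
        truth, result, _ = run_screen(cfg, seed=seed + 10_000 + r)
        effects = [t for t in result.statistics.index
                   if not truth.is_null[t]]
        called += sum(t in set(result.hits) for t in effects)
        total += len(effects)
    return {"power": called / total, "n_effect_treatments": total,
            "magnitude": magnitude}


# ---------------------------------------------------------------------------
# clustering recovery

CLUSTERING_CONFIG = simulate.SimulationConfig(
    n_treatments=20,  # 4 planted groups x 5 treatments
    n_negative_control_wells=8,
    plate_rows=4,
    plate_cols=7,
    n_features=24,
    cells_per_well_mean=150,
    effect_magnitude=4.0,  # strong: an order of magnitude above profile noise
    fraction_null=0.0,
    n_groups=4,
    within_group_noise=0.10,
)


def clustering_recovery(seed: int) -> dict:
    """Adjusted Rand index between the planted gene groups and the
    clusters cut at the stability-selected cutoff."""
    from sklearn.metrics import adjusted_rand_score

    cfg = replace(CLUSTERING_CONFIG, seed=seed)
    truth, result, centered = run_screen(cfg, seed=seed + 1)
    collapsed = hits.collapse_replicates(centered, treatments=result.hits)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gmap = genemap.build_gene_map(collapsed)
    labels = list(gmap.correlations.index)
    ari = adjusted_rand_score(
        [truth.group_of[t] for t in labels],
        [gmap.cluster_of(t) for t in labels],
    )
    return {"ari": float(ari), "cutoff": gmap.cutoff,
            "n_clustered": len(labels)}


# ---------------------------------------------------------------------------
# subpopulation enrichment consistency

SUBPOP_CONFIG = simulate.SimulationConfig(
    n_treatments=16,  # 2 groups x 8 genes
    n_negative_control_wells=64,  # 32/32 control split for the negative test
    plate_rows=8,
    plate_cols=10,
    n_features=20,
    cells_per_well_mean=200,
    n_subpopulations=4,
    effect_magnitude=0.5,
    proportion_shift_magnitude=0.05,
    fraction_null=0.0,
    n_groups=2,
    within_group_noise=0.2,
)

_SUBPOP_FIT = subpop.SubpopConfig(k=4, max_iterations=300)


def _planted_component(cells, truth) -> np.ndarray:
    """Per-cell planted mixture component by nearest raw-space center."""
    n_feat = truth.subpop_centers.shape[1]
    X = cells.data[truth.feature_names[:n_feat]].to_numpy()
    d = np.stack([
        np.linalg.norm(X - ctr, axis=1) for ctr in truth.subpop_centers
    ])
    return d.argmin(axis=0)


def subpop_consistency_once(seed: int) -> dict:
    """One repeat of the positive and negative enrichment checks.

    Positive: a +5 percentage-point shift of one subpopulation, shared by
    a planted group of 8 genes, must be flagged consistent (inverse
    CV > 1) with positive direction on the subpopulation that matches the
    planted component.  Negative: a random split of the 32 control well
    positions into 16 pseudo-genes vs 16 controls must flag nothing.
    """
    cfg = replace(SUBPOP_CONFIG, seed=seed)
    cells, truth = simulate.simulate_experiment(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = profiling.normalize_cells(cells)

        group = sorted(truth.groups())[0]
        members = truth.groups()[group]
        target = int(np.argmax(truth.group_proportion_shift[group]))
        model = subpop.fit_subpopulations(norm, members, _SUBPOP_FIT,
                                          seed=seed)
        props = subpop.subpop_proportions(model)
        verdicts = subpop.enrichment_consistency(props, members, _SUBPOP_FIT)
        # map fitted subpopulations to planted components via their cells
        comp = _planted_component(cells, truth)
        mask = cells.data[TREATMENT].isin(
            set(members) | {NEGATIVE_CONTROL}
        ).to_numpy()
        comp = comp[mask]
        majority = {}
        for s in range(len(model.centers)):
            inside = comp[model.assignments == s]
            if inside.size:
                majority[f"subpop_{s}"] = int(np.bincount(inside).argmax())
        flagged = verdicts[(verdicts["consistent"]) & (verdicts["direction"] > 0)]
        positive_ok = any(majority.get(s) == target for s in flagged.index)

        # negative: control-split pseudo-genes
        d = norm.data.copy()
        ctrl_wells = sorted(
            d.loc[d[TREATMENT] == NEGATIVE_CONTROL, WELL].unique()
        )
        rng = np.random.default_rng(seed + 77)
        half = rng.permutation(ctrl_wells)[: len(ctrl_wells) // 2]
        pseudo = []
        for i, w in enumerate(half):
            label = f"CTRLSPLIT{i:02d}"
            d.loc[(d[WELL] == w) & (d[TREATMENT] == NEGATIVE_CONTROL),
                  TREATMENT] = label
            pseudo.append(label)
        norm_split = norm.with_data(d)
        model2 = subpop.fit_subpopulations(norm_split, pseudo, _SUBPOP_FIT,
                                           seed=seed)
        props2 = subpop.subpop_proportions(model2)
        verdicts2 = subpop.enrichment_consistency(props2, pseudo, _SUBPOP_FIT)
        negative_ok = int(verdicts2["consistent"].sum()) == 0
    return {"positive_ok": bool(positive_ok), "negative_ok": bool(negative_ok)}


def subpop_consistency(n_repeats: int, seed: int) -> dict:
    """Repeat the positive/negative enrichment checks and report rates."""
    pos = neg = 0
    for r in range(n_repeats):
        out = subpop_consistency_once(seed + r)
        pos += out["positive_ok"]
        neg += out["negative_ok"]
    return {
        "positive_rate": pos / n_repeats,
        "negative_rate": neg / n_repeats,
        "n_repeats": n_repeats,
    }
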