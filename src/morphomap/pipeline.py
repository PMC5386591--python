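"""End-to-end pipeline runner.

Chains simulate -> profile -> select -> hits -> map -> subpop ->
interpret -> targets under one config and one global seed.  Per-stage
seeds are derived from the global seed by stable hashing of the stage
name, so any stage can be rerun independently yet reproducibly.  Every
intermediate table is persisted as delimited text with a schema sidecar
and the serialized config is written alongside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genemap, hits, interpret, profiling, selection, simulate, subpop, targets
from .errors import MorphomapError
from .io import (
    NEGATIVE_CONTROL,
    TREATMENT,
    CellTable,
    ProfileMatrix,
    read_cell_table,
    write_annotations,
    write_cell_table,
    write_profiles,
)

log = logging.getLogger("morphomap")


@dataclass
class PipelineConfig:
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    normalization: profiling.NormalizationConfig = field(
        default_factory=profiling.NormalizationConfig
    )
    feature_selection: selection.FeatureSelectionConfig = field(
        default_factory=selection.FeatureSelectionConfig
    )
    hit_calling: hits.HitCallConfig = field(default_factory=hits.HitCallConfig)
    clustering: genemap.ClusteringConfig = field(
        default_factory=genemap.ClusteringConfig
    )
    subpopulations: subpop.SubpopConfig = field(
        default_factory=lambda: subpop.SubpopConfig(k=5)
    )
    target_derivation: targets.TargetConfig = field(
        default_factory=targets.TargetConfig
    )
    seed: int = 0
    out_dir: str = "morphomap_run"
    cells_path: str | None = None  # skip simulation, read cells from here
    stages: tuple[str, ...] = (
        "simulate",
        "profile",
        "select",
        "hits",
        "map",
        "subpop",
        "interpret",
        "targets",
    )
    annotation_noise_rate: float = 0.1


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived stably from the global seed (< 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _asdict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class PipelineResult:
    out_dir: Path
    artifacts: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the enabled stages in order, persisting every intermediate.

    Identical config (including seed) produces byte-identical outputs.
    A stage failure aborts with the stage name; tables written so far
    remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(_asdict(config), indent=1))
    res = PipelineResult(out_dir=out)
    art = res.artifacts
    enabled = set(config.stages)
    try:
        _run_stages(config, enabled, out, art)
    except MorphomapError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise MorphomapError(f"pipeline stage failed: {exc}") from exc
    return res


def _run_stages(config: PipelineConfig, enabled: set, out: Path, art: dict) -> None:
    truth = None
    cells: CellTable | None = None
    if "simulate" in enabled and config.cells_path is None:
        sim_cfg = dataclasses.replace(
            config.simulation, seed=stage_seed(config.seed, "simulate")
        )
        cells, truth = simulate.simulate_experiment(sim_cfg)
        write_cell_table(cells, out / "cells.csv")
        annotations = simulate.make_annotations(
            truth, config.annotation_noise_rate, stage_seed(config.seed, "annotate")
        )
        write_annotations(
            annotations, out / "interactions.tsv", out / "pathways.gmt"
        )
        art["cells"] = cells
        art["truth"] = truth
        art["annotations"] = annotations
    elif config.cells_path is not None:
        cells = read_cell_table(config.cells_path)
        art["cells"] = cells

    if "profile" in enabled:
        if cells is None:
            raise MorphomapError("stage 'profile': no cell table available")
        normalized = profiling.normalize_cells(cells, config.normalization)
        n_dropped = len(cells.feature_names) - len(normalized.feature_names)
        log.info("normalize: dropped %d zero-MAD features", n_dropped)
        raw = profiling.zscore_cell_count(
            profiling.aggregate_well(normalized), config.normalization
        )
        polished = profiling.median_polish(raw)
        write_profiles(polished, out / "profiles_polished.csv")
        art["normalized_cells"] = normalized
        art["profiles"] = polished

    if "select" in enabled:
        polished = art.get("profiles")
        if polished is None:
            raise MorphomapError("stage 'select': no profiles available")
        filtered = selection.filter_features(polished, config.feature_selection)
        log.info(
            "filter: retained %d of %d profile components",
            len(filtered.value_columns), len(polished.value_columns),
        )
        sel = selection.select_features(filtered, config.feature_selection)
        reduced = selection.pca_reduce(sel.profiles, config.feature_selection)
        sel.trace.to_csv(out / "selection_trace.csv", index=False)
        write_profiles(sel.profiles, out / "profiles_selected.csv")
        write_profiles(reduced.profiles, out / "profiles_reduced.csv")
        art["filtered"] = filtered
        art["selection"] = sel
        art["reduced"] = reduced

    if "hits" in enabled:
        reduced = art.get("reduced")
        if reduced is None:
            raise MorphomapError("stage 'hits': no reduced profiles available")
        centered = hits.center_to_controls(reduced.profiles)
        result = hits.call_hits(
            centered, config.hit_calling, seed=stage_seed(config.seed, "hits")
        )
        result.statistics.assign(
            hit=result.statistics.index.isin(result.hits),
            final_hit=result.statistics.index.isin(result.final_hits),
        ).to_csv(out / "hit_calls.csv")
        write_profiles(result.collapsed, out / "profiles_collapsed.csv")
        log.info(
            "hits: %d of %d treatments (threshold %.3f)",
            len(result.final_hits), len(result.statistics), result.threshold,
        )
        art["centered"] = centered
        art["hit_result"] = result

    if "map" in enabled:
        result = art.get("hit_result")
        if result is None or len(result.final_hits) < 2:
            raise MorphomapError("stage 'map': needs >= 2 hit treatments")
        collapsed = hits.collapse_replicates(
            art["centered"], treatments=result.final_hits
        )
        gmap = genemap.build_gene_map(collapsed, config.clustering)
        pd.Series(
            {t: gmap.cluster_of(t) for t in gmap.correlations.index},
            name="cluster",
        ).to_csv(out / "clusters.csv")
        gmap.correlations.to_csv(out / "correlations.csv")
        art["gene_map"] = gmap

    cluster_treatments = None
    if "subpop" in enabled or "interpret" in enabled:
        gmap = art.get("gene_map")
        if gmap is not None:
            sizes = {c: len(m) for c, m in gmap.clusters.items()}
            biggest = max(sizes, key=lambda c: (sizes[c], -c))
            cluster_treatments = gmap.clusters[biggest]

    if "subpop" in enabled:
        if cluster_treatments is None or len(cluster_treatments) < 2:
            log.warning("subpop: no multi-member cluster; stage skipped")
        else:
            model = subpop.fit_subpopulations(
                art["normalized_cells"],
                cluster_treatments,
                config.subpopulations,
                seed=stage_seed(config.seed, "subpop"),
                features=art["selection"].selected
                if "selection" in art
                else None,
            )
            props = subpop.subpop_proportions(model)
            verdicts = subpop.enrichment_consistency(
                props, cluster_treatments, config.subpopulations
            )
            props.to_csv(out / "subpop_proportions.csv")
            verdicts.to_csv(out / "subpop_enrichment.csv")
            art["subpop_model"] = model
            art["subpop_proportions"] = props
            art["subpop_enrichment"] = verdicts

    if "interpret" in enabled and cluster_treatments:
        # grid/map need named features: collapse the selected-stage profiles
        sel = art.get("selection")
        if sel is not None:
            centered_sel = hits.center_to_controls(sel.profiles)
            collapsed_sel = hits.collapse_replicates(
                centered_sel, treatments=cluster_treatments
            )
            grid = interpret.feature_grid(collapsed_sel, cluster_treatments)
            fmap = interpret.feature_map(
                collapsed_sel, cluster_treatments,
                top_k=min(20, len(collapsed_sel.value_columns)),
            )
            grid.values.to_csv(out / "feature_grid.csv")
            fmap.to_csv(out / "feature_map.csv")
            art["feature_grid"] = grid
            art["feature_map"] = fmap

    if "targets" in enabled and truth is not None:
        expr, planted = simulate.simulate_expression(
            truth, seed=stage_seed(config.seed, "targets")
        )
        expr.to_csv(out / "expression.csv")
        genes = [t for t in truth.treatments if not truth.is_null[t]][:2]
        derived = {}
        for gene in genes:
            cols = [c for c in expr.columns if c.startswith(f"{gene}:")]
            derived[gene] = targets.derive_targets(
                expr[cols], config.target_derivation
            )
        if len(genes) == 2:
            shared = targets.common_targets(derived[genes[0]], derived[genes[1]])
            art["common_targets"] = shared
        art["expression"] = expr
        art["derived_targets"] = derived
        art["planted_targets"] = planted
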