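"""Single-cell subpopulation discovery and enrichment consistency.

For a gene cluster, normalized single cells of the cluster's treatments
are pooled with negative-control cells (restricted to the selected,
pre-PCA feature set) and partitioned with k-means.  Each treatment's
cells are counted per subpopulation and the per-treatment proportion
vectors compared with the pooled control proportions.  A subpopulation's
enrichment is called consistent when the inverse coefficient of
variation of the proportion change across the cluster's genes --
|mean change| / sd of change -- exceeds one; its sign gives the
direction (enriched vs depleted).  Subpopulations that are very small in
both the cluster and the control are omitted from reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin

from .errors import DegenerateInputError, MorphomapError
from .io import NEGATIVE_CONTROL, TREATMENT, CellTable

CONTROL_KEY = "control"


@dataclass(frozen=True)
class SubpopConfig:
    k: int = 20
    max_iterations: int = 5000
    consistency_cutoff: float = 1.0
    min_abundance: float = 0.005
    n_init: int = 5  # k-means++ restarts; best inertia wins, seed-deterministic

    def __post_init__(self) -> None:
        if self.k < 2:
            raise MorphomapError("k must be >= 2")
        if self.max_iterations < 1:
            raise MorphomapError("max_iterations must be >= 1")


@dataclass
class SubpopModel:
    centers: np.ndarray  # (k, n_features)
    assignments: np.ndarray  # subpopulation index per pooled cell
    cells: pd.DataFrame  # pooled cell rows (metadata + features)
    feature_names: list[str]
    cluster_treatments: list


def fit_subpopulations(
    cells: CellTable,
    cluster_treatments: list,
    cfg: SubpopConfig = SubpopConfig(),
    seed: int = 0,
    features: list[str] | None = None,
) -> SubpopModel:
    """k-means over the cluster's cells pooled with negative controls.

    ``cells`` should be plate-normalized single-cell data; ``features``
    restricts to the selected feature set (all features by default).
    Initialization is k-means++ with a fixed seed, run for at most
    ``cfg.max_iterations`` Lloyd iterations; afterwards every cell is
    re-assigned to its nearest center by Euclidean distance, which is
    the invariant the rest of the analysis relies on.
    """
    feats = features if features is not None else cells.feature_names
    mask = cells.data[TREATMENT].isin(set(cluster_treatments) | {NEGATIVE_CONTROL})
    pooled = cells.data.loc[mask, [TREATMENT] + list(feats)].reset_index(drop=True)
    X = pooled[feats].to_numpy(dtype=float)
    if len(X) < cfg.k:
        raise DegenerateInputError(
            f"{len(X)} cells is fewer than k = {cfg.k} subpopulations"
        )
    km = KMeans(
        n_clusters=cfg.k,
        init="k-means++",
        n_init=cfg.n_init,
        max_iter=cfg.max_iterations,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    assignments = pairwise_distances_argmin(X, km.cluster_centers_)
    return SubpopModel(
        centers=km.cluster_centers_,
        assignments=assignments,
        cells=pooled,
        feature_names=list(feats),
        cluster_treatments=list(cluster_treatments),
    )


def subpop_proportions(model: SubpopModel) -> pd.DataFrame:
    """Per-treatment (cells pooled across replicates) and pooled-control
    fractions of cells in each subpopulation; rows sum to 1."""
    k = len(model.centers)
    treatment = model.cells[TREATMENT].to_numpy()
    rows = {}
    for t in model.cluster_treatments + [NEGATIVE_CONTROL]:
        sel = model.assignments[treatment == t]
        if sel.size == 0:
            warnings.warn(f"treatment {t!r} has no cells; omitted")
            continue
        counts = np.bincount(sel, minlength=k).astype(float)
        key = CONTROL_KEY if t == NEGATIVE_CONTROL else t
        rows[key] = counts / counts.sum()
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"subpop_{i}" for i in range(k)]
    )


def enrichment_consistency(
    proportions: pd.DataFrame,
    cluster_treatments: list,
    cfg: SubpopConfig = SubpopConfig(),
) -> pd.DataFrame:
    """Inverse-CV consistency of per-gene proportion changes vs control.

    For each subpopulation s the change d_g = p_g(s) - p_control(s) is
    taken over the cluster's genes; inverse CV = |mean d| / sd d.  A
    subpopulation is consistent when the inverse CV exceeds the cutoff;
    ``direction`` is the sign of the mean change.  Subpopulations below
    ``min_abundance`` in both the cluster average and the control are
    marked omitted.
    """
    present = [t for t in cluster_treatments if t in proportions.index]
    if len(present) < 2:
        raise DegenerateInputError(
            "enrichment consistency needs >= 2 cluster treatments"
        )
    if CONTROL_KEY not in proportions.index:
        raise DegenerateInputError("proportions lack a control row")
    ctrl = proportions.loc[CONTROL_KEY]
    genes = proportions.loc[present]
    rows = []
    for s in proportions.columns:
        d = (genes[s] - ctrl[s]).to_numpy(dtype=float)
        mean = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd == 0.0:
            icv = float("inf") if mean != 0 else 0.0
            if mean != 0:
                warnings.warn(
                    f"{s}: zero spread with nonzero mean change; inverse CV "
                    "reported as infinite"
                )
        else:
            icv = abs(mean) / sd
        omitted = (
            float(genes[s].mean()) < cfg.min_abundance
            and float(ctrl[s]) < cfg.min_abundance
        )
        rows.append(
            {
                "subpopulation": s,
                "mean_change": mean,
                "sd_change": sd,
                "inverse_cv": icv,
                "direction": int(np.sign(mean)),
                "consistent": (icv > cfg.consistency_cutoff) and not omitted,
                "omitted": omitted,
            }
        )
    return pd.DataFrame(rows).set_index("subpopulation")


def exemplar_cells(model: SubpopModel, subpopulation: int, n: int) -> pd.Index:
    """Indices (into ``model.cells``) of the n member cells closest to the
    subpopulation center, in ascending distance order."""
    members = np.flatnonzero(model.assignments == subpopulation)
    if members.size == 0:
        raise DegenerateInputError(f"subpopulation {subpopulation} is empty")
    if n > members.size:
        warnings.warn(
            f"requested {n} exemplars but subpopulation {subpopulation} has "
            f"{members.size} cells; returning all"
        )
        n = members.size
    X = model.cells[model.feature_names].to_numpy(dtype=float)[members]
    d = np.linalg.norm(X - model.centers[subpopulation], axis=1)
    order = np.argsort(d, kind="stable")[:n]
    return pd.Index(members[order])


def dna_content_histogram(
    cells: CellTable,
    dna_feature_name: str,
    bins: int = 40,
    treatments: list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of single-cell DNA content (integrated DNA intensity)
    pooled over the given treatments' cells; mirrors a cell-cycle
    distribution readout."""
    if dna_feature_name not in cells.data.columns:
        raise MorphomapError(
            f"DNA content feature {dna_feature_name!r} not in the cell table"
        )
    df = cells.data
    if treatments is not None:
        df = df[df[TREATMENT].isin(set(treatments))]
    return np.histogram(df[dna_feature_name].to_numpy(dtype=float), bins=bins)
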