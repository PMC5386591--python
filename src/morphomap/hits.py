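"""Phenotype-strength statistic, empirical nulls and hit calling.

A treatment's phenotype strength is the median Pearson correlation among
its replicate profiles after every profile has been centered to the
per-plate negative-control median.  Replicates of a treatment without a
phenotype scatter about the origin and decorrelate; a consistent
phenotype concentrates them far from the origin and correlates them.

The hit threshold is the 95th percentile of an empirical null built
from non-replicates (profiles of different treatments).  For calling
hits the null statistic is matched to the treatment statistic: random
groups of non-replicate profiles, one per replicate plate, are formed
and their median pairwise correlation pooled, so that under a global
null the hit rate converges to 5% by construction.  A pessimistic
variant restricts the null to negative-control pairs sharing a well
position on different plates (edge wells excluded), which preserves any
residual plate-position artifact in the null.

Hits are additionally confirmed by a distance check: the collapsed
(replicate-averaged) profile must lie farther from the untreated
profiles than the 95th percentile of untreated-to-untreated distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .errors import DegenerateInputError, MorphomapError
from .io import (
    NEGATIVE_CONTROL,
    PLATE,
    REPLICATE,
    TREATMENT,
    WELL,
    ProfileMatrix,
    is_edge_well,
    well_position,
)


@dataclass(frozen=True)
class HitCallConfig:
    null_percentile: float = 95.0
    edge_well_exclusion: bool = True
    n_null_groups: int = 2000
    match_replicate_structure: bool = True
    distance_percentile: float = 95.0

    def __post_init__(self) -> None:
        if not 50.0 < self.null_percentile < 100.0:
            raise MorphomapError(
                f"null_percentile must be in (50, 100), got {self.null_percentile}"
            )


def center_to_controls(profiles: ProfileMatrix) -> ProfileMatrix:
    """Subtract the per-plate median negative-control profile vector."""
    df = profiles.data
    comps = profiles.value_columns
    out = df.copy()
    for plate, sub in df.groupby(PLATE, observed=True):
        ctrl = sub[sub[TREATMENT] == NEGATIVE_CONTROL]
        if len(ctrl) == 0:
            raise DegenerateInputError(
                f"plate {plate!r} has no negative-control profiles to center to"
            )
        med = ctrl[comps].median()
        out.loc[sub.index, comps] = (sub[comps] - med).to_numpy()
    return ProfileMatrix(out, stage=profiles.stage,
                         dropped_features=profiles.dropped_features,
                         notes=dict(profiles.notes))


def _pairwise_pearson(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Xc, axis=1)
    if np.any(norm == 0):
        raise DegenerateInputError("constant profile encountered in correlation")
    Xn = Xc / norm[:, None]
    return np.clip(Xn @ Xn.T, -1.0, 1.0)


def treatment_replicate_correlation(profiles: ProfileMatrix) -> pd.DataFrame:
    """Median pairwise Pearson correlation among each treatment's replicates.

    Treatments with a single replicate get a NaN statistic and are
    flagged; negative controls are skipped.
    """
    rows = []
    for t, sub in profiles.non_controls().groupby(TREATMENT, observed=True):
        X = sub[profiles.value_columns].to_numpy(dtype=float)
        if len(X) < 2:
            rows.append((t, np.nan, len(X), False))
            continue
        R = _pairwise_pearson(X)
        iu = np.triu_indices(len(X), k=1)
        rows.append((t, float(np.median(R[iu])), len(X), True))
    return pd.DataFrame(
        rows, columns=["treatment", "statistic", "n_replicates", "defined"]
    ).set_index("treatment")


def null_threshold(
    profiles: ProfileMatrix,
    cfg: HitCallConfig = HitCallConfig(),
    group_size: int = 1,
    seed: int = 0,
) -> float:
    """Percentile of the non-replicate (different-treatment) correlation null.

    With ``group_size <= 2`` the null pools the Pearson correlations of
    all profile pairs belonging to different treatments.  With
    ``group_size = R > 2`` it instead pools the median pairwise
    correlation of randomly sampled groups of R profiles from R distinct
    treatments (one per replicate plate when
    ``cfg.match_replicate_structure``), the group-matched null used for
    hit calling.
    """
    df = profiles.non_controls().reset_index(drop=True)
    if df[TREATMENT].nunique() < 2:
        raise DegenerateInputError("null needs at least 2 distinct treatments")
    X = df[profiles.value_columns].to_numpy(dtype=float)
    R = _pairwise_pearson(X)
    treatments = df[TREATMENT].to_numpy()
    if group_size <= 2:
        iu = np.triu_indices(len(df), k=1)
        mask = treatments[iu[0]] != treatments[iu[1]]
        pool = R[iu][mask]
        if pool.size == 0:
            raise DegenerateInputError("empty non-replicate correlation pool")
        thr = float(np.percentile(pool, cfg.null_percentile))
        if thr >= 1.0 - 1e-12:
            warnings.warn("degenerate null: threshold reached 1.0")
        return thr

    rng = np.random.default_rng(seed)
    reps = sorted(df[REPLICATE].unique())
    rows_by_rep = {
        r: sub.index.to_numpy() for r, sub in df.groupby(REPLICATE, observed=True)
    }
    medians = np.empty(cfg.n_null_groups)
    for g in range(cfg.n_null_groups):
        if cfg.match_replicate_structure and len(reps) >= group_size:
            chosen_reps = rng.choice(len(reps), size=group_size, replace=False)
            idx = []
            used: set = set()
            for ri in chosen_reps:
                cand = rows_by_rep[reps[ri]]
                cand = cand[~np.isin(treatments[cand], list(used))]
                pick = int(rng.choice(cand))
                idx.append(pick)
                used.add(treatments[pick])
        else:
            idx = []
            used = set()
            order = rng.permutation(len(df))
            for i in order:
                if treatments[i] not in used:
                    idx.append(int(i))
                    used.add(treatments[i])
                if len(idx) == group_size:
                    break
        sub = np.array(idx)
        iu = np.triu_indices(len(sub), k=1)
        medians[g] = np.median(R[np.ix_(sub, sub)][iu])
    return float(np.percentile(medians, cfg.null_percentile))


def pessimistic_null_threshold(
    profiles: ProfileMatrix,
    cfg: HitCallConfig = HitCallConfig(),
    plate_shape: tuple[int, int] | None = None,
) -> float:
    """Null percentile from position-matched negative-control pairs.

    Pools correlations only between negative-control profiles occupying
    the same well position on different plates; plate-edge wells are
    excluded (per config) because they are most artifact-prone.
    """
    ctrl = profiles.controls().reset_index(drop=True)
    if len(ctrl) == 0:
        raise DegenerateInputError("no negative-control profiles")
    if plate_shape is None:
        pos = [well_position(w) for w in profiles.data[WELL]]
        plate_shape = (max(p[0] for p in pos) + 1, max(p[1] for p in pos) + 1)
    if cfg.edge_well_exclusion:
        keep = [
            not is_edge_well(w, plate_shape[0], plate_shape[1])
            for w in ctrl[WELL]
        ]
        ctrl = ctrl[keep].reset_index(drop=True)
    X = ctrl[profiles.value_columns].to_numpy(dtype=float)
    pool = []
    for w, sub in ctrl.groupby(WELL, observed=True):
        idx = sub.index.to_numpy()
        if len(idx) < 2:
            continue
        R = _pairwise_pearson(X[idx])
        iu = np.triu_indices(len(idx), k=1)
        plates = sub[PLATE].to_numpy()
        mask = plates[iu[0]] != plates[iu[1]]
        pool.extend(R[iu][mask].tolist())
    if not pool:
        raise DegenerateInputError(
            "no position-matched negative-control pairs (after edge-well "
            "exclusion)"
        )
    return float(np.percentile(pool, cfg.null_percentile))


def collapse_replicates(
    profiles: ProfileMatrix, treatments: list | None = None
) -> ProfileMatrix:
    """One row per treatment: the component-wise mean of its replicates."""
    df = profiles.non_controls()
    if treatments is not None:
        df = df[df[TREATMENT].isin(set(treatments))]
    comps = profiles.value_columns
    agg = df.groupby(TREATMENT, observed=True)[comps].mean().reset_index()
    return ProfileMatrix(agg, stage="collapsed",
                         dropped_features=profiles.dropped_features)


def distance_check(
    collapsed: ProfileMatrix,
    control_profiles: pd.DataFrame | ProfileMatrix,
    percentile: float = 95.0,
) -> pd.Series:
    """Per-treatment flag: mean Euclidean distance to all untreated
    profiles exceeds the given percentile of untreated pairwise distances."""
    if isinstance(control_profiles, ProfileMatrix):
        ctrl = control_profiles.controls()[collapsed.value_columns]
    else:
        ctrl = control_profiles[collapsed.value_columns]
    C = ctrl.to_numpy(dtype=float)
    if len(C) < 2:
        raise DegenerateInputError("distance check needs >= 2 control profiles")
    q = float(np.percentile(pdist(C), percentile))
    X = collapsed.matrix()
    mean_d = cdist(X, C).mean(axis=1)
    return pd.Series(mean_d > q, index=collapsed.data[TREATMENT], name="distance_pass")


@dataclass
class HitCallResult:
    statistics: pd.DataFrame  # per treatment: statistic, n_replicates, defined
    threshold: float
    hits: list  # treatments passing statistic > threshold
    distance_pass: pd.Series
    final_hits: list  # hits that also pass the distance check
    collapsed: ProfileMatrix
    notes: dict = field(default_factory=dict)

    @property
    def hit_rate(self) -> float:
        n = int(self.statistics["defined"].sum())
        return len(self.hits) / n if n else float("nan")


def call_hits(
    profiles: ProfileMatrix,
    cfg: HitCallConfig = HitCallConfig(),
    seed: int = 0,
) -> HitCallResult:
    """Call treatments whose phenotype strength beats the empirical null.

    ``profiles`` must already be centered to the negative controls.  The
    null is group-matched to the modal replicate count (see
    :func:`null_threshold`).  Hits use strict inequality; passing hits
    whose collapsed profile stays within the negative-control scatter
    (distance check) are excluded from ``final_hits``.
    """
    stats = treatment_replicate_correlation(profiles)
    defined = stats[stats["defined"]]
    group_size = int(defined["n_replicates"].mode().iloc[0]) if len(defined) else 1
    thr = null_threshold(profiles, cfg, group_size=group_size, seed=seed)
    hits = sorted(defined.index[defined["statistic"] > thr])
    boundary = defined.index[defined["statistic"] == thr]
    notes = {}
    if len(boundary):
        notes["boundary_treatments"] = list(boundary)
        warnings.warn(
            f"{len(boundary)} treatments sit exactly at the null threshold "
            "and are not hits (strict inequality)"
        )
    collapsed = collapse_replicates(profiles, treatments=hits)
    if len(hits) and len(profiles.controls()) >= 2:
        dpass = distance_check(collapsed, profiles, cfg.distance_percentile)
        final = sorted(t for t in hits if bool(dpass.loc[t]))
    else:
        dpass = pd.Series(dtype=bool, name="distance_pass")
        final = list(hits)
    return HitCallResult(
        statistics=stats,
        threshold=thr,
        hits=list(hits),
        distance_pass=dpass,
        final_hits=final,
        collapsed=collapsed,
        notes=notes,
    )


def clone_pair_consistency(
    collapsed: ProfileMatrix,
    clone_pairs: list[tuple],
    threshold: float | None = None,
    percentile: float = 95.0,
) -> tuple[pd.DataFrame, float, float]:
    """Correlation of same-gene construct pairs vs the different-gene null.

    Returns (per-pair table, threshold, fraction of pairs above it).
    The default threshold is the ``percentile`` of profile correlations
    between constructs not listed as clone pairs.  Pairs with a member
    missing from ``collapsed`` (e.g. a non-hit) are excluded and logged.
    """
    df = collapsed.data.set_index(TREATMENT)
    comps = collapsed.value_columns
    X = df[comps].to_numpy(dtype=float)
    idx = {t: i for i, t in enumerate(df.index)}
    R = _pairwise_pearson(X)
    pair_set = {frozenset(p) for p in clone_pairs}
    if threshold is None:
        iu = np.triu_indices(len(df), k=1)
        labels = list(df.index)
        mask = np.array(
            [frozenset((labels[i], labels[j])) not in pair_set
             for i, j in zip(*iu)]
        )
        threshold = float(np.percentile(R[iu][mask], percentile))
    rows = []
    excluded = []
    for a, b in clone_pairs:
        if a not in idx or b not in idx:
            excluded.append((a, b))
            continue
        r = float(R[idx[a], idx[b]])
        rows.append((a, b, r, r > threshold))
    if excluded:
        warnings.warn(
            f"{len(excluded)} clone pairs excluded (member not in collapsed "
            f"profiles): {excluded[:5]}"
        )
    table = pd.DataFrame(rows, columns=["construct_a", "construct_b",
                                        "correlation", "above_threshold"])
    frac = float(table["above_threshold"].mean()) if len(table) else float("nan")
    return table, threshold, frac


def compare_allele_strength(
    statistics: pd.Series | dict,
    paired_list: list[tuple],
) -> float:
    """One-sided paired t-test that engineered (e.g. constitutively
    active) alleles show stronger phenotypes than their wild-type
    counterparts, on the median-replicate-correlation statistic.

    ``paired_list`` holds (allele, wild_type) treatment pairs.  Returns
    the one-sided p-value for allele > wild type.
    """
    stats = pd.Series(statistics)
    if len(paired_list) < 2:
        raise DegenerateInputError("paired t-test needs at least 2 pairs")
    a = np.array([stats[x] for x, _ in paired_list], dtype=float)
    w = np.array([stats[y] for _, y in paired_list], dtype=float)
    d = a - w
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.5 if d.mean() == 0 else (0.0 if d.mean() > 0 else 1.0)
    from scipy import stats as sps

    t = d.mean() / (sd / np.sqrt(len(d)))
    return float(sps.t.sf(t, df=len(d) - 1))


def pathway_strength_summary(
    statistics: pd.Series | dict,
    pathways: dict,
    gene_of: dict | None = None,
) -> pd.DataFrame:
    """Per-pathway mean and standard deviation of phenotype strength.

    ``pathways`` maps pathway -> member genes.  ``gene_of`` maps
    construct -> gene; duplicate wild-type clones of a gene are averaged
    first so each gene is counted once.  Empty pathways are omitted with
    a warning.
    """
    stats = pd.Series(statistics, dtype=float)
    if gene_of:
        stats = stats.groupby(lambda c: gene_of.get(c, c)).mean()
    rows = []
    for pw in sorted(pathways):
        members = [g for g in pathways[pw] if g in stats.index]
        if not members:
            warnings.warn(f"pathway {pw!r} has no members with a statistic")
            continue
        vals = stats[members]
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append((pw, len(members), float(vals.mean()), sd))
    return pd.DataFrame(
        rows, columns=["pathway", "n_genes", "mean_strength", "sd_strength"]
    ).set_index("pathway")
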