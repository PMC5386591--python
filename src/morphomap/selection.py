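"""Replicate-correlation feature filtering, greedy feature selection and PCA.

The reproducibility of a profile component is measured by its replicate
correlation: for every unordered pair of replicate plates, the Pearson
correlation of the component's per-treatment values between the two
replicates (negative controls excluded), averaged over pairs.
Components below 0.30 carry little reproducible signal and are dropped.

Redundancy among the survivors is then removed by a greedy procedure:
starting from the most reproducible component, each remaining candidate
is regressed (ordinary least squares, with intercept) on the already
selected components that correlate with it above 0.50 -- restricting the
regressors prevents overfitting when many components are selected -- and
the candidate whose residual has the highest replicate correlation is
added, until that maximum drops below 0.30.  Finally PCA keeps the
smallest number of leading components explaining 99% of variance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, MorphomapError
from .io import REPLICATE, TREATMENT, ProfileMatrix


@dataclass(frozen=True)
class FeatureSelectionConfig:
    filter_threshold: float = 0.30
    regression_corr_threshold: float = 0.50
    stop_threshold: float = 0.30
    pca_variance: float = 0.99
    pair_aggregate: str = "mean"  # or "median" over replicate pairs
    seed_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("filter_threshold", "regression_corr_threshold",
                     "stop_threshold", "pca_variance"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise MorphomapError(f"{name} must be in (0, 1], got {v}")


def _replicate_pair_views(profiles: ProfileMatrix):
    """Aligned per-treatment value blocks for every unordered replicate pair.

    Yields (values_a, values_b) DataFrames indexed by the treatments
    common to replicates a and b, with one row per treatment.
    """
    df = profiles.non_controls()
    reps = sorted(df[REPLICATE].unique())
    if len(reps) < 2:
        raise DegenerateInputError(
            f"replicate correlation needs >= 2 replicates, found {len(reps)}"
        )
    by_rep = {
        r: sub.set_index(TREATMENT)
        for r, sub in df.groupby(REPLICATE, observed=True)
    }
    for a, b in itertools.combinations(reps, 2):
        common = by_rep[a].index.intersection(by_rep[b].index)
        if len(common) < 3:
            continue
        yield by_rep[a].loc[common], by_rep[b].loc[common]


class _PairIndex:
    """Row-position index pairs aligning replicate plates by treatment.

    Built over the non-control rows of a profile matrix; used to compute
    replicate correlations of arbitrary vectors without re-grouping.
    """

    def __init__(self, profiles: ProfileMatrix):
        df = profiles.non_controls().reset_index(drop=True)
        reps = sorted(df[REPLICATE].unique())
        if len(reps) < 2:
            raise DegenerateInputError(
                f"replicate correlation needs >= 2 replicates, found {len(reps)}"
            )
        pos = {
            r: sub.groupby(TREATMENT, observed=True).head(1)
            .set_index(TREATMENT).index
            for r, sub in df.groupby(REPLICATE, observed=True)
        }
        locs = {
            r: dict(
                zip(
                    sub.groupby(TREATMENT, observed=True).head(1)[TREATMENT],
                    sub.groupby(TREATMENT, observed=True).head(1).index,
                )
            )
            for r, sub in df.groupby(REPLICATE, observed=True)
        }
        self.pairs: list[tuple[np.ndarray, np.ndarray]] = []
        for a, b in itertools.combinations(reps, 2):
            common = sorted(set(locs[a]) & set(locs[b]))
            if len(common) < 3:
                continue
            ia = np.array([locs[a][t] for t in common])
            ib = np.array([locs[b][t] for t in common])
            self.pairs.append((ia, ib))
        if not self.pairs:
            raise DegenerateInputError(
                "no replicate pair shares enough treatments to correlate"
            )

    def vector_rc(self, v: np.ndarray, aggregate: str = "mean") -> float:
        """Replicate correlation of a vector over the non-control rows."""
        vals = []
        for ia, ib in self.pairs:
            a = v[ia] - v[ia].mean()
            b = v[ib] - v[ib].mean()
            denom = np.sqrt((a**2).sum() * (b**2).sum())
            vals.append(float((a * b).sum() / denom) if denom > 0 else 0.0)
        agg = np.median if aggregate == "median" else np.mean
        return float(agg(vals))


def _pair_correlations(profiles: ProfileMatrix, columns: list[str]) -> np.ndarray:
    """(n_pairs, n_columns) Pearson correlations between replicate pairs.

    Column pairs where either side has zero variance contribute 0 (no
    reproducible signal by convention).
    """
    rows = []
    for va, vb in _replicate_pair_views(profiles):
        a = va[columns].to_numpy(dtype=float)
        b = vb[columns].to_numpy(dtype=float)
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        sa = np.sqrt((a**2).sum(axis=0))
        sb = np.sqrt((b**2).sum(axis=0))
        denom = sa * sb
        num = (a * b).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        rows.append(r)
    if not rows:
        raise DegenerateInputError(
            "no replicate pair shares enough treatments to correlate"
        )
    return np.asarray(rows)


def feature_replicate_correlation(
    profiles: ProfileMatrix,
    feature: str | None = None,
    cfg: FeatureSelectionConfig = FeatureSelectionConfig(),
) -> pd.Series | float:
    """Replicate correlation of one profile component, or of all of them.

    Negative controls are excluded.  Returns the mean (or median, per
    config) over unordered replicate-plate pairs of the per-treatment
    Pearson correlation.
    """
    columns = [feature] if feature is not None else profiles.value_columns
    pair_corr = _pair_correlations(profiles, columns)
    agg = np.median if cfg.pair_aggregate == "median" else np.mean
    out = pd.Series(agg(pair_corr, axis=0), index=columns)
    return float(out.iloc[0]) if feature is not None else out


def filter_features(
    profiles: ProfileMatrix, cfg: FeatureSelectionConfig = FeatureSelectionConfig()
) -> ProfileMatrix:
    """Keep exactly the components with replicate correlation >= threshold."""
    rc = feature_replicate_correlation(profiles, cfg=cfg)
    keep = [c for c in profiles.value_columns if rc[c] >= cfg.filter_threshold]
    if not keep:
        raise DegenerateInputError(
            "no feature reaches the replicate-correlation filter threshold "
            f"({cfg.filter_threshold}); review the threshold or the data"
        )
    dropped = tuple(c for c in profiles.value_columns if c not in set(keep))
    data = profiles.data[profiles.metadata_columns + keep]
    return ProfileMatrix(
        data, stage="filtered",
        dropped_features=profiles.dropped_features + dropped,
        notes=dict(profiles.notes),
    )


@dataclass
class SelectionResult:
    selected: list[str]
    trace: pd.DataFrame  # feature, residual replicate correlation at selection
    profiles: ProfileMatrix  # stage="selected", restricted to the selection

    def __iter__(self):
        return iter(self.selected)


def select_features(
    profiles: ProfileMatrix, cfg: FeatureSelectionConfig = FeatureSelectionConfig()
) -> SelectionResult:
    """Greedy residual-based selection of non-redundant reproducible features.

    Deterministic: ties on the residual replicate correlation are broken
    by lexicographic feature name.  The loop is seeded with the feature
    of maximal replicate correlation unless ``cfg.seed_features`` names
    an explicit starting set.
    """
    noncon = profiles.non_controls()
    columns = profiles.value_columns
    X = noncon[columns].to_numpy(dtype=float)
    colpos = {c: i for i, c in enumerate(columns)}

    rc = feature_replicate_correlation(profiles, cfg=cfg)
    order = sorted(columns, key=lambda c: (-rc[c], c))
    if cfg.seed_features:
        missing = [f for f in cfg.seed_features if f not in colpos]
        if missing:
            raise MorphomapError(f"seed features not in profiles: {missing}")
        selected = list(cfg.seed_features)
        trace_rows = [(f, float(rc[f])) for f in selected]
    else:
        first = order[0]
        selected = [first]
        trace_rows = [(first, float(rc[first]))]

    # feature-feature correlations over non-control rows, for restricting
    # the regressor set
    with np.errstate(invalid="ignore"):
        ff = np.corrcoef(X, rowvar=False)
    ff = np.nan_to_num(ff)
    pairs = _PairIndex(profiles)

    remaining = [c for c in columns if c not in set(selected)]
    while remaining:
        best_feature = None
        best_val = -np.inf
        for f in remaining:
            j = colpos[f]
            regs = [s for s in selected
                    if ff[j, colpos[s]] > cfg.regression_corr_threshold]
            y = X[:, j]
            if regs:
                A = np.column_stack(
                    [np.ones(len(y))] + [X[:, colpos[s]] for s in regs]
                )
                beta, *_ = np.linalg.lstsq(A, y, rcond=None)
                resid = y - A @ beta
            else:
                resid = y - y.mean()
            val = pairs.vector_rc(resid, cfg.pair_aggregate)
            if val > best_val or (val == best_val and best_feature is not None
                                  and f < best_feature):
                best_val = val
                best_feature = f
        if best_val < cfg.stop_threshold:
            break
        selected.append(best_feature)
        trace_rows.append((best_feature, best_val))
        remaining.remove(best_feature)

    trace = pd.DataFrame(trace_rows, columns=["feature", "residual_replicate_corr"])
    data = profiles.data[profiles.metadata_columns + selected]
    restricted = ProfileMatrix(
        data, stage="selected",
        dropped_features=profiles.dropped_features,
        notes=dict(profiles.notes),
    )
    return SelectionResult(selected=selected, trace=trace, profiles=restricted)


@dataclass
class PCAResult:
    profiles: ProfileMatrix  # stage="reduced", PC scores
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    n_components: int


def pca_reduce(
    profiles: ProfileMatrix, cfg: FeatureSelectionConfig = FeatureSelectionConfig()
) -> PCAResult:
    """Project onto the smallest set of leading principal components whose
    cumulative explained variance reaches ``cfg.pca_variance``.

    Components are computed on mean-centered, unscaled values (profile
    components are already on a common robust-z scale) and ordered by
    decreasing variance; numerically null components of rank-deficient
    input are dropped before the cumulative-variance cut.
    """
    X = profiles.matrix()
    if X.shape[0] < 2:
        raise DegenerateInputError("PCA needs at least 2 profile rows")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    # drop numerically null directions of rank-deficient input
    nonnull = evr > 1e-12
    evr = evr[nonnull]
    scores = scores[:, nonnull]
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, cfg.pca_variance - 1e-12) + 1)
    k = min(k, scores.shape[1])
    pc_names = [f"PC{i + 1:03d}" for i in range(k)]
    values = pd.DataFrame(scores[:, :k], columns=pc_names)
    reduced = profiles.with_values(values, stage="reduced")
    loadings = pd.DataFrame(
        pca.components_[: len(evr)][:k].T,
        index=profiles.value_columns,
        columns=pc_names,
    )
    return PCAResult(
        profiles=reduced,
        loadings=loadings,
        explained_variance_ratio=evr[:k],
        n_components=k,
    )
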