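"""Gene-function map: correlations, enrichment, clustering and stability.

Collapsed hit profiles are compared by Pearson correlation.  Pairs above
a data-driven threshold -- the point where the densities of same-gene
(wild-type clone) and different-gene pair correlations intersect, which
minimizes the classification error between the two -- are called highly
correlated, and their overlap with external gene-pair annotations
(physical interactions, shared pathway membership) is scored with a
one-tailed Fisher's exact test.

The map itself is an average-linkage dendrogram on correlation distance
1 - r.  The flat cutoff is chosen by a stability score: the fraction of
treatments whose cluster membership is unchanged when the cutoff is
perturbed by +/- epsilon, swept over a cutoff grid, smoothed with a
centered moving average; the maximizing cutoff (smallest on ties) is
used to form gene clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import brentq
from scipy.spatial.distance import squareform

from .errors import DegenerateInputError, MorphomapError
from .io import TREATMENT, AnnotationSet, ProfileMatrix


@dataclass(frozen=True)
class ClusteringConfig:
    """Dendrogram-cutting parameters; cutoffs are correlation levels
    (a cutoff c cuts the tree at distance 1 - c)."""

    cutoff_min: float = 0.43
    cutoff_max: float = 0.70
    grid_step: float = 0.002
    epsilon: float = 0.002
    smoothing_window: float = 0.02

    def __post_init__(self) -> None:
        if self.epsilon > self.grid_step + 1e-12:
            raise MorphomapError("epsilon must not exceed the grid step")
        if self.smoothing_window < self.grid_step - 1e-12:
            raise MorphomapError("smoothing_window must cover the grid step")

    def grid(self) -> np.ndarray:
        n = int(round((self.cutoff_max - self.cutoff_min) / self.grid_step))
        return self.cutoff_min + self.grid_step * np.arange(n + 1)


def correlation_matrix(collapsed: ProfileMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlations of collapsed profiles (symmetric,
    unit diagonal).  A constant profile has undefined correlations and is
    reported by treatment name."""
    df = collapsed.data
    if len(df) < 2:
        raise DegenerateInputError("need >= 2 collapsed profiles")
    labels = df[TREATMENT].tolist()
    X = collapsed.matrix()
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise DegenerateInputError(f"constant profiles for treatments: {bad}")
    R = np.corrcoef(X)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=labels, columns=labels)


def density_intersection_threshold(
    same_gene_corrs: np.ndarray,
    diff_gene_corrs: np.ndarray,
    n_grid: int = 1024,
) -> float:
    """Correlation value where the two pair-correlation densities cross.

    Both samples are smoothed with a Gaussian kernel (Silverman
    bandwidth) and the crossing of the two estimated densities between
    the two sample means is returned; classifying pairs by this
    threshold minimizes the probability of confusing same-gene with
    different-gene pairs.
    """
    same = np.asarray(same_gene_corrs, dtype=float)
    diff = np.asarray(diff_gene_corrs, dtype=float)
    if same.size == 0 or diff.size == 0:
        raise DegenerateInputError("both correlation samples must be non-empty")
    m_same, m_diff = same.mean(), diff.mean()
    if m_same <= m_diff:
        raise MorphomapError(
            "same-gene correlations do not sit right of different-gene "
            "correlations; supply a manual threshold"
        )
    kde_same = sps.gaussian_kde(same, bw_method="silverman")
    kde_diff = sps.gaussian_kde(diff, bw_method="silverman")

    def g(x):
        return kde_same(x)[0] - kde_diff(x)[0]

    xs = np.linspace(m_diff, m_same, n_grid)
    vals = np.array([g(x) for x in xs])
    sign = np.sign(vals)
    crossings = np.flatnonzero(np.diff(sign) != 0)
    if len(crossings) == 0:
        raise MorphomapError(
            "densities do not cross between the group means; supply a "
            "manual threshold"
        )
    i = crossings[0]
    return float(brentq(g, xs[i], xs[i + 1]))


@dataclass
class FisherResult:
    table: np.ndarray  # rows: correlated yes/no, cols: annotated yes/no
    odds_ratio: float
    p_value: float


def fisher_test(table) -> FisherResult:
    """One-tailed (enrichment) Fisher's exact test on a 2x2 table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise MorphomapError("Fisher test needs a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate Fisher margins; p = 1")
        return FisherResult(t, float("nan"), 1.0)
    odds, p = sps.fisher_exact(t, alternative="greater")
    return FisherResult(t, float(odds), float(p))


def fisher_enrichment(
    corr_matrix: pd.DataFrame,
    threshold: float,
    relation,
) -> FisherResult:
    """Enrichment of annotated gene pairs among highly correlated pairs.

    ``relation`` is a set of unordered gene pairs (``frozenset`` pairs),
    or an :class:`AnnotationSet` whose interaction pairs are used.  The
    caller is expected to pass a matrix over one wild-type construct per
    gene.  Rows of the table: pair correlation > threshold or not;
    columns: pair annotated or not.
    """
    if isinstance(relation, AnnotationSet):
        relation = relation.interactions
    relation = set(relation)
    genes = list(corr_matrix.index)
    R = corr_matrix.to_numpy()
    a = b = c = d = 0
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            high = R[i, j] > threshold
            annotated = frozenset((genes[i], genes[j])) in relation
            if high and annotated:
                a += 1
            elif high:
                b += 1
            elif annotated:
                c += 1
            else:
                d += 1
    return fisher_test([[a, b], [c, d]])


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix on distance 1 - r
    labels: list

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def build_dendrogram(corr_matrix: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomerative tree on correlation distance."""
    D = 1.0 - corr_matrix.to_numpy()
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return Dendrogram(linkage=Z, labels=list(corr_matrix.index))


def cut_clusters(dendro: Dendrogram, corr_cutoff: float) -> dict[int, list]:
    """Flat clusters from cutting the tree at correlation level
    ``corr_cutoff`` (distance 1 - corr_cutoff)."""
    flat = fcluster(dendro.linkage, t=1.0 - corr_cutoff, criterion="distance")
    out: dict[int, list] = {}
    for label, cid in zip(dendro.labels, flat):
        out.setdefault(int(cid), []).append(label)
    return {cid: sorted(m) for cid, m in out.items()}


def _membership_sets(dendro: Dendrogram, corr_cutoff: float) -> dict:
    clusters = cut_clusters(dendro, corr_cutoff)
    member_of = {}
    for members in clusters.values():
        fs = frozenset(members)
        for m in members:
            member_of[m] = fs
    return member_of


@dataclass
class StabilityCurve:
    cutoffs: np.ndarray
    scores: np.ndarray
    smoothed: np.ndarray

    def choose_cutoff(self) -> float:
        """Argmax of the smoothed score; the smallest cutoff wins ties."""
        i = int(np.argmax(self.smoothed))  # first occurrence = smallest cutoff
        return float(self.cutoffs[i])


def stability_curve(
    dendro: Dendrogram, cfg: ClusteringConfig = ClusteringConfig()
) -> StabilityCurve:
    """Cluster-membership stability along the cutoff grid.

    For each grid cutoff c the score is the fraction of treatments whose
    cluster (as a member set) is identical when cutting at c - epsilon
    and c + epsilon; scores are smoothed by a centered moving average of
    width ``smoothing_window`` on the cutoff axis.
    """
    grid = cfg.grid()
    dmin, dmax = 0.0, float(dendro.heights.max(initial=0.0))
    lo, hi = 1.0 - dmax, 1.0
    if grid[-1] < lo or grid[0] > hi:
        warnings.warn(
            "stability grid lies outside the dendrogram height range; "
            "scores will be flat"
        )
    n = len(dendro.labels)
    scores = np.empty(len(grid))
    for k, c in enumerate(grid):
        below = _membership_sets(dendro, c - cfg.epsilon)
        above = _membership_sets(dendro, c + cfg.epsilon)
        stable = sum(1 for t in dendro.labels if below[t] == above[t])
        scores[k] = stable / n
    half_pts = int(round(cfg.smoothing_window / cfg.grid_step)) // 2
    window = 2 * half_pts + 1
    smoothed = (
        pd.Series(scores).rolling(window, center=True, min_periods=1).mean()
        .to_numpy()
    )
    return StabilityCurve(cutoffs=grid, scores=scores, smoothed=smoothed)


@dataclass
class ClusterSummary:
    cluster_id: int
    members: list
    is_singleton: bool
    within_correlation: float
    cross_correlation: pd.Series  # mean correlation to each other cluster
    top_negative: pd.Series  # top-5 most negatively correlated outsiders


@dataclass
class GeneMap:
    correlations: pd.DataFrame
    dendrogram: Dendrogram
    cutoff: float
    clusters: dict[int, list]
    summaries: dict[int, ClusterSummary]
    stability: StabilityCurve | None = None

    def cluster_of(self, treatment) -> int:
        for cid, members in self.clusters.items():
            if treatment in members:
                return cid
        raise KeyError(treatment)


def cluster_summaries(
    clusters: dict[int, list], corr_matrix: pd.DataFrame, top_n: int = 5
) -> dict[int, ClusterSummary]:
    """Per-cluster averages: within-cluster correlation, mean correlation
    to every other cluster, and the most negatively correlated outside
    treatments (ranked by average correlation to the cluster members)."""
    out = {}
    for cid, members in clusters.items():
        sub = corr_matrix.loc[members, members].to_numpy()
        if len(members) > 1:
            iu = np.triu_indices(len(members), k=1)
            within = float(sub[iu].mean())
        else:
            within = float("nan")
        cross = {}
        for other, omembers in clusters.items():
            if other == cid:
                continue
            cross[other] = float(
                corr_matrix.loc[members, omembers].to_numpy().mean()
            )
        outside = [t for t in corr_matrix.index if t not in set(members)]
        if outside:
            avg = corr_matrix.loc[outside, members].mean(axis=1)
            top_neg = avg.sort_values().head(top_n)
        else:
            top_neg = pd.Series(dtype=float)
        out[cid] = ClusterSummary(
            cluster_id=cid,
            members=list(members),
            is_singleton=len(members) == 1,
            within_correlation=within,
            cross_correlation=pd.Series(cross, dtype=float).sort_index(),
            top_negative=top_neg,
        )
    return out


def build_gene_map(
    collapsed: ProfileMatrix,
    cfg: ClusteringConfig = ClusteringConfig(),
    cutoff: float | None = None,
) -> GeneMap:
    """Full map: correlations, dendrogram, stability-selected cutoff,
    clusters and summaries.  ``cutoff`` (a correlation level) overrides
    the stability selection when given."""
    corr = correlation_matrix(collapsed)
    dendro = build_dendrogram(corr)
    stability = None
    if cutoff is None:
        stability = stability_curve(dendro, cfg)
        cutoff = stability.choose_cutoff()
    clusters = cut_clusters(dendro, cutoff)
    summaries = cluster_summaries(clusters, corr)
    return GeneMap(
        correlations=corr,
        dendrogram=dendro,
        cutoff=float(cutoff),
        clusters=clusters,
        summaries=summaries,
        stability=stability,
    )
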