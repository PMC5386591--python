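"""Interpretation summaries: Feature Grid and Feature Map.

The Feature Grid condenses a cluster's phenotype into a small matrix of
median z-scores indexed by measurement type (rows) and channel
(columns): each cell is the median, over the cluster's treatments and
all member features of that (type, channel) combination, of the
control-referenced profile values.  Combinations with no features
(e.g. geometric measurements, which carry no channel) are masked, never
zero-filled.

The Feature Map picks the top-k features with the largest absolute
median z-score and lays them out in the plane so that features highly
correlated across all treatments' profiles sit close together (classical
metric multidimensional scaling on distance 1 - |r|), with the sign of
each feature's change attached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MorphomapError
from .io import TREATMENT, ProfileMatrix
from .names import (
    CELL_COUNT,
    CHANNEL_FREE_TYPES,
    DEFAULT_CHANNELS,
    MEASUREMENT_TYPES,
    is_parseable,
    parse_feature_name,
)

#: Column label of the channel-free (geometric) measurement types.
NO_CHANNEL = "(none)"


@dataclass
class FeatureGrid:
    values: pd.DataFrame  # measurement type x channel, median z-scores
    mask: pd.DataFrame  # True where the combination is undefined
    n_features: pd.DataFrame  # member-feature counts per combination


def _cluster_z(
    collapsed: ProfileMatrix,
    cluster_treatments: list,
    control_profiles: ProfileMatrix | None,
) -> pd.DataFrame:
    """Collapsed values of the cluster rows, re-referenced to the median
    control profile when controls are supplied (profiles straight out of
    the pipeline are already control-referenced z-units)."""
    df = collapsed.data.set_index(TREATMENT)
    missing = [t for t in cluster_treatments if t not in df.index]
    if missing:
        raise MorphomapError(f"treatments not in collapsed profiles: {missing}")
    vals = df.loc[cluster_treatments, collapsed.value_columns]
    if control_profiles is not None:
        ref = control_profiles.controls()[collapsed.value_columns].median()
        vals = vals - ref
    return vals


def feature_grid(
    collapsed: ProfileMatrix,
    cluster_treatments: list,
    control_profiles: ProfileMatrix | None = None,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> FeatureGrid:
    """Median z-score per (measurement type, channel) meta-feature.

    A feature measured on several channels (cross-channel correlations)
    contributes to each of its channels' columns.  The cell-count
    component and unparseable columns are skipped.
    """
    vals = _cluster_z(collapsed, cluster_treatments, control_profiles)
    types = sorted(MEASUREMENT_TYPES)
    cols = list(channels) + [NO_CHANNEL]
    buckets: dict[tuple[str, str], list] = {}
    counts: dict[tuple[str, str], int] = {}
    for feat in vals.columns:
        if feat == CELL_COUNT or not is_parseable(feat, channels):
            continue
        desc = parse_feature_name(feat, channels)
        targets = desc.channels if desc.channels else (NO_CHANNEL,)
        for ch in targets:
            key = (desc.measurement_type, ch)
            buckets.setdefault(key, []).extend(vals[feat].tolist())
            counts[key] = counts.get(key, 0) + 1
    values = pd.DataFrame(np.nan, index=types, columns=cols)
    nfeat = pd.DataFrame(0, index=types, columns=cols)
    for (mt, ch), pool in buckets.items():
        values.loc[mt, ch] = float(np.median(pool))
        nfeat.loc[mt, ch] = counts[(mt, ch)]
    # channel columns are undefined for geometric types, and vice versa
    mask = values.isna()
    for mt in CHANNEL_FREE_TYPES:
        mask.loc[mt, list(channels)] = True
    return FeatureGrid(values=values, mask=mask, n_features=nfeat)


def _classical_mds(D: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Deterministic classical (Torgerson) MDS embedding."""
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_dims]
    w = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(w)
    # fix the sign of each axis for determinism
    for d in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, d]))
        if coords[i, d] < 0:
            coords[:, d] = -coords[:, d]
    return coords


def feature_map(
    collapsed: ProfileMatrix,
    cluster_treatments: list,
    control_profiles: ProfileMatrix | None = None,
    top_k: int = 20,
) -> pd.DataFrame:
    """2D layout of the top-k most-distinguishing features.

    Features are ranked by the absolute median z-score of the cluster
    relative to controls (ties broken by name); the embedding places
    features correlated across all treatments' profiles close together.
    Returns a frame with columns x, y, z_score and sign (+1 enriched,
    -1 depleted).
    """
    vals = _cluster_z(collapsed, cluster_treatments, control_profiles)
    feats = [c for c in vals.columns if c != CELL_COUNT]
    z = vals[feats].median(axis=0)
    if top_k > len(feats):
        warnings.warn(
            f"top_k = {top_k} exceeds the {len(feats)} available features; "
            "using all"
        )
        top_k = len(feats)
    ranked = sorted(feats, key=lambda f: (-abs(z[f]), f))[:top_k]

    all_rows = collapsed.data[ranked].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(all_rows, rowvar=False)
    R = np.nan_to_num(R)
    D = 1.0 - np.abs(R)
    coords = _classical_mds(D)
    return pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1] if coords.shape[1] > 1 else 0.0,
            "z_score": [float(z[f]) for f in ranked],
            "sign": [int(np.sign(z[f])) for f in ranked],
        },
        index=pd.Index(ranked, name="feature"),
    )
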