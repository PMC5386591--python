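"""Data-driven transcriptional targets from landmark-gene signatures.

For each replicate (or clone) of an overexpression construct, landmark
genes are ranked by their control-normalized expression and the top and
bottom 50 taken.  A landmark is an up- (down-) target of the gene if it
appears in the top (bottom) list of at least p% of the gene's
replicates; shared targets of two genes are the direction-respecting
intersection of their target sets.  A separate summarization rule scores
a construct across cell-line/time-point combinations by the mean of its
4 largest scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MorphomapError


@dataclass(frozen=True)
class TargetConfig:
    top_n: int = 50
    bottom_n: int = 50
    presence_fraction: float = 0.5  # p: 0.33 or 0.50 depending on the gene
    orf_score_top_m: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence_fraction <= 1.0:
            raise MorphomapError("presence_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TargetSets:
    up: frozenset
    down: frozenset


def _presence_threshold(p: float, n_replicates: int) -> int:
    """Minimum number of replicates a landmark must appear in: at least
    p% of replicates, rounded up, and never fewer than one."""
    return max(1, math.ceil(round(p * n_replicates, 9)))


def derive_targets(
    expression: pd.DataFrame, cfg: TargetConfig = TargetConfig()
) -> TargetSets:
    """Up/down target sets of one gene from its replicate signatures.

    ``expression`` is a landmark x replicate matrix of control-normalized
    values.  Per replicate, the ``top_n`` highest and ``bottom_n`` lowest
    landmarks are listed (rank ties at the boundary broken by landmark
    identifier); a landmark qualifies in a direction when it is listed in
    at least ``presence_fraction`` of the replicates.  Within a replicate
    the two lists are disjoint by construction; a landmark that still
    qualifies in both directions across replicates (possible only for
    inconsistent signatures at low ``presence_fraction``) is kept in both
    and flagged with a warning.
    """
    if expression.shape[1] < 1:
        raise DegenerateInputError("need at least one replicate column")
    if cfg.top_n + cfg.bottom_n > expression.shape[0]:
        raise MorphomapError(
            "top_n + bottom_n exceeds the number of landmark genes"
        )
    n_reps = expression.shape[1]
    need = _presence_threshold(cfg.presence_fraction, n_reps)
    up_counts: dict = {}
    down_counts: dict = {}
    for col in expression.columns:
        vals = expression[col]
        top = sorted(vals.index, key=lambda g: (-vals[g], g))[: cfg.top_n]
        bottom = sorted(vals.index, key=lambda g: (vals[g], g))[: cfg.bottom_n]
        for g in top:
            up_counts[g] = up_counts.get(g, 0) + 1
        for g in bottom:
            down_counts[g] = down_counts.get(g, 0) + 1
    up = {g for g, c in up_counts.items() if c >= need}
    down = {g for g, c in down_counts.items() if c >= need}
    both = up & down
    if both:
        warnings.warn(
            f"{len(both)} landmarks qualified as both up- and down-targets "
            "(inconsistent signatures at low presence_fraction)"
        )
    return TargetSets(up=frozenset(up), down=frozenset(down))


def common_targets(targets_a: TargetSets, targets_b: TargetSets) -> TargetSets:
    """Direction-respecting intersection of two genes' target sets."""
    return TargetSets(
        up=targets_a.up & targets_b.up, down=targets_a.down & targets_b.down
    )


def summarize_orf_score(scores, cfg: TargetConfig = TargetConfig()) -> float:
    """Mean of the ``orf_score_top_m`` largest scores across cell-line /
    time-point combinations (all scores if fewer)."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("summarize_orf_score needs at least one score")
    top = np.sort(arr)[::-1][: cfg.orf_score_top_m]
    return float(top.mean())
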