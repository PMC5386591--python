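"""Robust per-plate normalization, well aggregation and median polish.

Single cells are normalized per plate to the untreated (negative
control) population: subtract the control median and divide by the
control MAD times 1.4826 (the consistency constant that makes the MAD
match the standard deviation under normality).  Features whose control
MAD is zero on any plate carry no robust scale information and are
excluded everywhere.  Normalized cells are then summarized per well into
a profile vector of per-feature medians, per-feature MADs, and the cell
count (2F + 1 components).  Finally a per-plate Tukey median polish
removes additive row/column plate-position trends from every profile
component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MorphomapError
from .io import (
    NEGATIVE_CONTROL,
    PLATE,
    REPLICATE,
    TREATMENT,
    WELL,
    CellTable,
    ProfileMatrix,
    well_position,
)
from .names import CELL_COUNT, MAD_PREFIX

#: MAD-to-standard-deviation consistency constant for the normal
#: distribution, 1 / Phi^{-1}(3/4).
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class NormalizationConfig:
    mad_scale: float = MAD_SCALE
    control_label: str = NEGATIVE_CONTROL
    drop_zero_mad: bool = True
    robust: bool = True  # False: mean/sd z-scoring instead of median/MAD

    def __post_init__(self) -> None:
        if self.mad_scale <= 0:
            raise MorphomapError("mad_scale must be positive")


def _mad(x: pd.DataFrame) -> pd.Series:
    """Unscaled median absolute deviation per column."""
    return (x - x.median()).abs().median()


def normalize_cells(
    cells: CellTable, cfg: NormalizationConfig = NormalizationConfig()
) -> CellTable:
    """Normalize each feature per plate against the untreated cells.

    output = (value - control median) / (mad_scale x control MAD), with
    location/scale computed across all control cells of the cell's
    plate.  Features with control MAD = 0 on any plate are removed from
    every plate (when ``drop_zero_mad``).  With ``robust=False`` the
    control mean and standard deviation are used instead.
    """
    df = cells.data
    features = cells.feature_names
    centers: dict = {}
    scales: dict = {}
    zero_mad: set[str] = set()
    for plate, sub in df.groupby(PLATE, observed=True):
        ctrl = sub[sub[TREATMENT] == cfg.control_label]
        if len(ctrl) == 0:
            raise DegenerateInputError(
                f"plate {plate!r} has no {cfg.control_label!r} control cells"
            )
        x = ctrl[features]
        if cfg.robust:
            center = x.median()
            scale = cfg.mad_scale * _mad(x)
        else:
            center = x.mean()
            scale = x.std(ddof=1)
        centers[plate] = center
        scales[plate] = scale
        zero_mad.update(scale.index[scale == 0.0])
    if cfg.drop_zero_mad:
        keep = [f for f in features if f not in zero_mad]
    else:
        keep = features
        if zero_mad:
            warnings.warn(
                f"{len(zero_mad)} features have zero control MAD but "
                "drop_zero_mad is off; their normalized values are undefined"
            )
    if not keep:
        raise DegenerateInputError("all features have zero control MAD")

    meta_cols = [c for c in df.columns if c.startswith("Metadata_")]
    out = []
    for plate, sub in df.groupby(PLATE, observed=True):
        vals = (sub[keep] - centers[plate][keep]) / scales[plate][keep]
        out.append(pd.concat([sub[meta_cols], vals], axis=1))
    res = pd.concat(out).loc[df.index]
    return cells.with_data(res)


def aggregate_well(cells: CellTable) -> ProfileMatrix:
    """Summarize normalized cells into one profile row per (plate, well).

    The profile vector is the per-feature median, the per-feature MAD
    (``mad_``-prefixed), and the cell count: 2F + 1 components.  The
    result is invariant to the ordering of cells.  Wells with zero cells
    simply contribute no row.
    """
    features = cells.feature_names
    rows = []
    for (plate, well), sub in cells.data.groupby([PLATE, WELL], observed=True):
        x = sub[features]
        med = x.median()
        mad = _mad(x)
        rec = {
            PLATE: plate,
            WELL: well,
            TREATMENT: sub[TREATMENT].iloc[0],
            REPLICATE: sub[REPLICATE].iloc[0],
        }
        rec.update(med.to_dict())
        rec.update({f"{MAD_PREFIX}_{f}": v for f, v in mad.items()})
        rec[CELL_COUNT] = float(len(sub))
        rows.append(rec)
    cols = (
        [PLATE, WELL, TREATMENT, REPLICATE]
        + features
        + [f"{MAD_PREFIX}_{f}" for f in features]
        + [CELL_COUNT]
    )
    data = pd.DataFrame(rows, columns=cols).sort_values(
        [PLATE, WELL], kind="mergesort"
    ).reset_index(drop=True)
    return ProfileMatrix(data, stage="raw")


def zscore_cell_count(
    profiles: ProfileMatrix, cfg: NormalizationConfig = NormalizationConfig()
) -> ProfileMatrix:
    """Convert the raw cell-count component to a control-referenced
    robust z-score, per plate.

    Per-cell features arrive on the robust-z scale from
    :func:`normalize_cells`, but the cell count is appended as a raw
    count at aggregation; left unscaled it would dominate any
    variance-based step downstream.  Per plate the control wells' count
    median and MAD provide the reference; if the control counts have
    zero MAD the plate-wide MAD is used instead.
    """
    if CELL_COUNT not in profiles.data.columns:
        return profiles
    df = profiles.data.copy()
    for plate, sub in df.groupby(PLATE, observed=True):
        ctrl = sub[sub[TREATMENT] == cfg.control_label]
        ref = ctrl if len(ctrl) else sub
        counts = ref[CELL_COUNT].astype(float)
        med = counts.median()
        mad = (counts - med).abs().median()
        if mad == 0.0:
            allc = sub[CELL_COUNT].astype(float)
            mad = (allc - allc.median()).abs().median()
        scale = cfg.mad_scale * mad if mad > 0 else 1.0
        df.loc[sub.index, CELL_COUNT] = (sub[CELL_COUNT] - med) / scale
    return ProfileMatrix(df, stage=profiles.stage,
                         dropped_features=profiles.dropped_features,
                         notes=dict(profiles.notes))


@dataclass
class PolishResult:
    profiles: ProfileMatrix
    row_effects: dict  # plate -> (n_rows, n_components) array
    col_effects: dict
    converged: dict  # plate -> bool
    n_iter: dict


def median_polish(
    profiles: ProfileMatrix,
    tol: float = 1e-6,
    max_iter: int = 500,
    full: bool = False,
) -> ProfileMatrix | PolishResult:
    """Remove additive plate-position trends per plate and component.

    For each plate, profiles are arranged on the physical well grid and,
    independently for every profile component, row medians then column
    medians are subtracted, alternating until the largest adjustment of
    a sweep is at most ``tol`` (Tukey's median polish; the overall term
    is absorbed into the row effects).  Non-convergence within
    ``max_iter`` sweeps returns the best iterate with a warning.
    Missing wells are ignored via median-over-available.
    """
    df = profiles.data
    comps = profiles.value_columns
    out = df.copy()
    row_effects: dict = {}
    col_effects: dict = {}
    converged: dict = {}
    n_iters: dict = {}
    for plate, sub in df.groupby(PLATE, observed=True):
        pos = np.array([well_position(w) for w in sub[WELL]])
        n_rows = pos[:, 0].max() + 1
        n_cols = pos[:, 1].max() + 1
        grid = np.full((n_rows, n_cols, len(comps)), np.nan)
        grid[pos[:, 0], pos[:, 1], :] = sub[comps].to_numpy(dtype=float)
        re = np.zeros((n_rows, len(comps)))
        ce = np.zeros((n_cols, len(comps)))
        ok = False
        it = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            for it in range(1, max_iter + 1):
                r = np.nanmedian(grid, axis=1)  # (n_rows, C)
                r = np.nan_to_num(r)
                grid -= r[:, None, :]
                re += r
                c = np.nanmedian(grid, axis=0)  # (n_cols, C)
                c = np.nan_to_num(c)
                grid -= c[None, :, :]
                ce += c
                if max(np.abs(r).max(initial=0), np.abs(c).max(initial=0)) <= tol:
                    ok = True
                    break
        if not ok:
            warnings.warn(
                f"median polish did not converge on plate {plate!r} within "
                f"{max_iter} sweeps (tol={tol})"
            )
        out.loc[sub.index, comps] = grid[pos[:, 0], pos[:, 1], :]
        row_effects[plate] = re
        col_effects[plate] = ce
        converged[plate] = ok
        n_iters[plate] = it
    polished = ProfileMatrix(
        out, stage="polished", dropped_features=profiles.dropped_features,
        notes=dict(profiles.notes),
    )
    if full:
        return PolishResult(polished, row_effects, col_effects, converged, n_iters)
    return polished
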