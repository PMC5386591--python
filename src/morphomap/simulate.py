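"""Synthetic plate-structured single-cell experiments with known ground truth.

The generator emulates the design of an overexpression morphological
profiling screen: replicate plates with treatments in fixed well
positions, negative-control wells spread across the plate (edges
included), per-cell features drawn from a mixture of subpopulation
Gaussians, treatment effects expressed as feature-mean shifts and
subpopulation-proportion shifts, additive row/column plate artifacts,
degenerate (zero-variance) features and over-dispersed cell counts.

It also fabricates matched annotation sets (interaction pairs and
pathway memberships consistent with the planted gene groups) and a
landmark-gene expression matrix with planted transcriptional targets, so
every downstream stage of the pipeline can be tested against a known
answer without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import LayoutError, MorphomapError
from .io import (
    NEGATIVE_CONTROL,
    PLATE,
    REPLICATE,
    TREATMENT,
    WELL,
    AnnotationSet,
    CellTable,
    well_name,
)
from .names import DEFAULT_CHANNELS, canonical_name


@dataclass(frozen=True)
class SubpopulationSpec:
    """One subpopulation of the single-cell mixture.

    ``center`` is its mean in feature space, ``scale`` the standard
    deviation of its isotropic (diagonal) Gaussian, ``proportion`` its
    baseline mixture weight in untreated cells.
    """

    center: tuple[float, ...]
    scale: float
    proportion: float


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults describe the test-scale design: five replicate plates
    (one replicate per plate, treatments in the same well position on
    every plate), a 96-well 8x12 geometry, 60 features over the five
    Cell Painting channels, and 100-300 cells per well drawn from a
    negative binomial.
    """

    n_plates: int = 5
    plate_rows: int = 8
    plate_cols: int = 12
    n_treatments: int = 76
    n_negative_control_wells: int = 20
    n_features: int = 60
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    cells_per_well_mean: float = 200.0
    cells_per_well_dispersion: float = 20.0  # NB size parameter
    n_subpopulations: int = 4
    subpopulation_separation: float = 4.0
    subpopulation_scale: float = 1.0
    baseline_proportions: tuple[float, ...] | None = None
    #: explicit subpopulation specs override the randomly placed centers
    subpopulations: tuple[SubpopulationSpec, ...] | None = None
    n_groups: int = 4
    effect_magnitude: float = 2.0
    within_group_noise: float = 0.15
    proportion_shift_magnitude: float = 0.0
    cell_count_effect_sd: float = 0.0  # multiplicative log-normal sd per treatment
    row_artifact_sd: float = 0.0
    col_artifact_sd: float = 0.0
    #: plate-position artifacts recur across replicate plates (evaporation
    #: and gradient patterns are persistent); False draws fresh offsets
    #: per plate
    artifact_shared_across_plates: bool = True
    #: orthonormalize the planted group effect directions so groups are
    #: geometrically distinct phenotypes; requires n_groups <= n_features
    orthogonal_group_directions: bool = True
    fraction_null: float = 0.2
    n_constant_features: int = 1
    seed: int = 0

    @property
    def n_wells(self) -> int:
        return self.plate_rows * self.plate_cols


@dataclass
class GroundTruth:
    """Planted truth of a simulated experiment."""

    treatments: list[str]
    is_null: dict[str, bool]
    effect_magnitude: dict[str, float]
    group_of: dict[str, str]  # non-null treatment -> group label
    mean_shift: dict[str, np.ndarray]
    group_proportion_shift: dict[str, np.ndarray]  # group -> per-subpop delta
    treatment_well: dict[str, str]
    control_wells: list[str]
    subpop_centers: np.ndarray  # (n_subpop, n_features)
    subpop_scales: np.ndarray
    baseline_proportions: np.ndarray
    row_offsets: dict = field(default_factory=dict)  # (plate -> (rows, F))
    col_offsets: dict = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for t, g in self.group_of.items():
            out.setdefault(g, []).append(t)
        return {g: sorted(ts) for g, ts in out.items()}

    def shifted_proportions(self, treatment: str) -> np.ndarray:
        """Mixture weights of a treatment: baseline plus its group's shift,
        clipped to non-negative and renormalized to a simplex."""
        p = self.baseline_proportions.copy()
        g = self.group_of.get(treatment)
        if g is not None:
            p = np.clip(p + self.group_proportion_shift[g], 0.0, None)
            p = p / p.sum()
        return p


def _feature_name_list(n_features: int, n_constant: int,
                       channels: Sequence[str]) -> list[str]:
    """Deterministic parseable feature names cycling compartments, types
    and channels."""
    compartments = ("Cells", "Cytoplasm", "Nuclei")
    typed = (
        ("Intensity", True),
        ("Texture", True),
        ("AreaShape", False),
        ("Granularity", True),
        ("RadialDistribution", True),
        ("Neighbors", False),
    )
    names = []
    for i in range(n_features):
        comp = compartments[i % 3]
        mtype, has_channel = typed[i % len(typed)]
        chan = (channels[i % len(channels)],) if has_channel else ()
        names.append(canonical_name("none", comp, mtype, f"Metric{i:03d}", chan))
    for j in range(n_constant):
        names.append(
            canonical_name("none", "Nuclei", "AreaShape", f"Constant{j:03d}")
        )
    return names


def _default_subpops(cfg: SimulationConfig, rng: np.random.Generator):
    if cfg.subpopulations is not None:
        centers = np.array([s.center for s in cfg.subpopulations], dtype=float)
        if centers.shape != (len(cfg.subpopulations), cfg.n_features):
            raise MorphomapError(
                "subpopulation centers must be n_features-dimensional"
            )
        scales = np.array([s.scale for s in cfg.subpopulations], dtype=float)
        props = np.array([s.proportion for s in cfg.subpopulations], dtype=float)
        if not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
            raise MorphomapError("subpopulation proportions must sum to 1")
        return centers, scales, props
    k, f = cfg.n_subpopulations, cfg.n_features
    # orthogonal-ish random directions scaled to the requested separation
    dirs = rng.normal(size=(k, f))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    centers = dirs * cfg.subpopulation_separation
    scales = np.full(k, cfg.subpopulation_scale)
    if cfg.baseline_proportions is not None:
        props = np.asarray(cfg.baseline_proportions, dtype=float)
        if len(props) != k or not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
            raise MorphomapError(
                "baseline_proportions must have one weight per subpopulation "
                "and sum to 1"
            )
    else:
        props = np.full(k, 1.0 / k)
    return centers, scales, props


def _layout(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    """Assign control wells (spread across the plate, edges included) and
    treatment wells; the same layout is reused on every replicate plate."""
    n_needed = cfg.n_treatments + cfg.n_negative_control_wells
    if n_needed > cfg.n_wells:
        raise LayoutError(
            f"layout infeasible: {cfg.n_treatments} treatments + "
            f"{cfg.n_negative_control_wells} controls > {cfg.n_wells} wells"
        )
    wells = [
        well_name(r, c)
        for r in range(cfg.plate_rows)
        for c in range(cfg.plate_cols)
    ]
    # evenly strided control positions cover all rows/columns incl. edges
    if cfg.n_negative_control_wells > 0:
        idx = np.linspace(0, cfg.n_wells - 1, cfg.n_negative_control_wells)
        control_idx = sorted(set(int(round(i)) for i in idx))
        while len(control_idx) < cfg.n_negative_control_wells:
            cand = next(i for i in range(cfg.n_wells) if i not in control_idx)
            control_idx.append(cand)
            control_idx.sort()
    else:
        control_idx = []
    control_wells = [wells[i] for i in control_idx]
    rest = [w for w in wells if w not in set(control_wells)]
    treatment_wells = rest[: cfg.n_treatments]
    return control_wells, treatment_wells


def _plant_truth(cfg: SimulationConfig) -> GroundTruth:
    # independent child streams: changing artifact magnitudes or effect
    # sizes must not perturb the cell-level draws
    rng_truth = np.random.default_rng([cfg.seed, 11])
    centers, scales, props = _default_subpops(cfg, rng_truth)
    control_wells, treatment_wells = _layout(cfg)

    treatments = [f"GENE{i:03d}" for i in range(cfg.n_treatments)]
    n_null = int(round(cfg.fraction_null * cfg.n_treatments))
    null_set = set(treatments[cfg.n_treatments - n_null:])

    group_of: dict[str, str] = {}
    active = [t for t in treatments if t not in null_set]
    n_groups = max(1, min(cfg.n_groups, len(active))) if active else 0
    for i, t in enumerate(active):
        group_of[t] = f"GRP{i % n_groups:02d}"

    group_labels = sorted(set(group_of.values()))
    raw_dirs = rng_truth.normal(size=(len(group_labels), cfg.n_features))
    if cfg.orthogonal_group_directions and len(group_labels) <= cfg.n_features:
        # orthonormal directions: planted groups are distinct phenotypes
        q, r = np.linalg.qr(raw_dirs.T)
        dirs = (q * np.sign(np.diag(r))).T[: len(group_labels)]
    else:
        dirs = raw_dirs / np.linalg.norm(raw_dirs, axis=1, keepdims=True)
    group_dirs = {g: dirs[i] for i, g in enumerate(group_labels)}

    group_prop_shift: dict[str, np.ndarray] = {}
    k = len(props)
    for j, g in enumerate(sorted(group_dirs)):
        shift = np.zeros(k)
        if cfg.proportion_shift_magnitude > 0 and k >= 2:
            target = j % k
            shift[target] = cfg.proportion_shift_magnitude
            shift[np.arange(k) != target] = -cfg.proportion_shift_magnitude / (k - 1)
        group_prop_shift[g] = shift

    mean_shift: dict[str, np.ndarray] = {}
    magnitude: dict[str, float] = {}
    for t in treatments:
        if t in null_set:
            mean_shift[t] = np.zeros(cfg.n_features)
            magnitude[t] = 0.0
        else:
            d = group_dirs[group_of[t]] + cfg.within_group_noise * rng_truth.normal(
                size=cfg.n_features
            )
            d /= np.linalg.norm(d)
            mean_shift[t] = cfg.effect_magnitude * d
            magnitude[t] = cfg.effect_magnitude

    feature_names = _feature_name_list(
        cfg.n_features, cfg.n_constant_features, cfg.channels
    )
    return GroundTruth(
        treatments=treatments,
        is_null={t: (t in null_set) for t in treatments},
        effect_magnitude=magnitude,
        group_of=group_of,
        mean_shift=mean_shift,
        group_proportion_shift=group_prop_shift,
        treatment_well={t: w for t, w in zip(treatments, treatment_wells)},
        control_wells=control_wells,
        subpop_centers=centers,
        subpop_scales=scales,
        baseline_proportions=props,
        feature_names=feature_names,
    )


def simulate_experiment(cfg: SimulationConfig) -> tuple[CellTable, GroundTruth]:
    """Simulate single cells for every well of every replicate plate.

    Treatments occupy the same well position on every plate.  Per-cell
    feature vectors are drawn from the subpopulation mixture with the
    treatment's mean and proportion shifts applied, then additive
    row/column plate artifacts are added.  Configured constant features
    are appended with zero variance to exercise the MAD = 0 exclusion.
    Output is byte-identical for identical config (including seed).
    """
    truth = _plant_truth(cfg)
    rng_cells = np.random.default_rng([cfg.seed, 23])
    rng_art = np.random.default_rng([cfg.seed, 37])
    rng_count = np.random.default_rng([cfg.seed, 41])

    f = cfg.n_features
    well_treatment = {w: t for t, w in truth.treatment_well.items()}
    for w in truth.control_wells:
        well_treatment[w] = NEGATIVE_CONTROL

    count_factor = {
        t: float(np.exp(rng_count.normal(0.0, cfg.cell_count_effect_sd)))
        if cfg.cell_count_effect_sd > 0
        else 1.0
        for t in truth.treatments
    }

    shared_row = cfg.row_artifact_sd * rng_art.normal(size=(cfg.plate_rows, f))
    shared_col = cfg.col_artifact_sd * rng_art.normal(size=(cfg.plate_cols, f))
    frames = []
    for p in range(cfg.n_plates):
        plate_id = f"PLATE{p + 1}"
        if cfg.artifact_shared_across_plates:
            row_off, col_off = shared_row, shared_col
        else:
            row_off = cfg.row_artifact_sd * rng_art.normal(
                size=(cfg.plate_rows, f)
            )
            col_off = cfg.col_artifact_sd * rng_art.normal(
                size=(cfg.plate_cols, f)
            )
        truth.row_offsets[plate_id] = row_off
        truth.col_offsets[plate_id] = col_off
        for r in range(cfg.plate_rows):
            for c in range(cfg.plate_cols):
                w = well_name(r, c)
                t = well_treatment.get(w)
                if t is None:
                    continue
                mean_count = cfg.cells_per_well_mean * (
                    count_factor[t] if t != NEGATIVE_CONTROL else 1.0
                )
                size = cfg.cells_per_well_dispersion
                n_cells = int(
                    rng_count.negative_binomial(size, size / (size + mean_count))
                )
                n_cells = max(n_cells, 5)
                if t == NEGATIVE_CONTROL:
                    props = truth.baseline_proportions
                    shift = 0.0
                else:
                    props = truth.shifted_proportions(t)
                    shift = truth.mean_shift[t]
                comp = rng_cells.choice(len(props), size=n_cells, p=props)
                x = (
                    truth.subpop_centers[comp]
                    + truth.subpop_scales[comp, None]
                    * rng_cells.normal(size=(n_cells, f))
                    + shift
                )
                x = x + row_off[r] + col_off[c]
                df = pd.DataFrame(x, columns=truth.feature_names[:f])
                for j in range(cfg.n_constant_features):
                    df[truth.feature_names[f + j]] = 7.0
                df.insert(0, PLATE, plate_id)
                df.insert(1, WELL, w)
                df.insert(2, TREATMENT, t)
                df.insert(3, REPLICATE, p + 1)
                frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return CellTable(data, channels=cfg.channels), truth


def make_annotations(
    truth: GroundTruth, noise_rate: float, seed: int
) -> AnnotationSet:
    """Annotation sets consistent with the planted groups.

    Within-group gene pairs are annotated (interacting and co-pathway)
    with probability ``1 - noise_rate``; all other pairs with probability
    ``noise_rate``.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise MorphomapError(f"noise_rate must be in [0, 1], got {noise_rate}")
    rng = np.random.default_rng([seed, 53])
    genes = truth.treatments
    interactions: set[frozenset] = set()
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            same = (
                a in truth.group_of
                and b in truth.group_of
                and truth.group_of[a] == truth.group_of[b]
            )
            p = (1.0 - noise_rate) if same else noise_rate
            if rng.random() < p:
                interactions.add(frozenset((a, b)))
    groups = sorted(set(truth.group_of.values())) or ["GRP00"]
    pathways: dict[str, frozenset] = {}
    for g in genes:
        own = truth.group_of.get(g)
        if own is not None:
            if rng.random() < 1.0 - noise_rate:
                pathways[g] = frozenset({f"PW_{own}"})
            else:
                others = [x for x in groups if x != own] or groups
                pathways[g] = frozenset({f"PW_{rng.choice(others)}"})
        elif noise_rate > 0 and rng.random() < noise_rate:
            pathways[g] = frozenset({f"PW_{rng.choice(groups)}"})
    return AnnotationSet(interactions=frozenset(interactions), pathways=pathways)


def simulate_expression(
    truth: GroundTruth,
    n_landmarks: int = 200,
    replicates_per_gene: int = 3,
    seed: int = 0,
    shift: float = 4.0,
    n_targets_per_direction: int = 20,
) -> tuple[pd.DataFrame, dict[str, dict[str, frozenset]]]:
    """Control-normalized landmark-gene expression with planted targets.

    Returns a (landmark x replicate-column) matrix (columns named
    ``GENE:repN``) and the planted per-gene target sets.  Genes in the
    same planted group share their up/down target sets, so the
    common-target intersection of two group mates recovers them exactly.
    Baseline values are standard normal (already control-normalized
    scale); planted targets receive a consistent +/-``shift`` in every
    replicate of the gene.
    """
    if n_landmarks < 100:
        raise MorphomapError("n_landmarks must be at least 100")
    if replicates_per_gene < 1:
        raise MorphomapError("replicates_per_gene must be >= 1")
    rng = np.random.default_rng([seed, 67])
    landmarks = [f"LM{i:04d}" for i in range(n_landmarks)]
    group_targets: dict[str, tuple[frozenset, frozenset]] = {}
    for g in sorted(set(truth.group_of.values())):
        pick = rng.choice(n_landmarks, size=2 * n_targets_per_direction, replace=False)
        up = frozenset(landmarks[i] for i in pick[:n_targets_per_direction])
        down = frozenset(landmarks[i] for i in pick[n_targets_per_direction:])
        group_targets[g] = (up, down)

    cols = {}
    targets: dict[str, dict[str, frozenset]] = {}
    for gene in truth.treatments:
        grp = truth.group_of.get(gene)
        up, down = group_targets.get(grp, (frozenset(), frozenset()))
        targets[gene] = {"up": up, "down": down}
        delta = np.zeros(n_landmarks)
        for i, lm in enumerate(landmarks):
            if lm in up:
                delta[i] = shift
            elif lm in down:
                delta[i] = -shift
        for r in range(1, replicates_per_gene + 1):
            cols[f"{gene}:rep{r}"] = rng.normal(size=n_landmarks) + delta
    expr = pd.DataFrame(cols, index=landmarks)
    return expr, targets


def null_config(cfg: SimulationConfig) -> SimulationConfig:
    """A copy of ``cfg`` with every planted effect switched off."""
    return replace(
        cfg,
        effect_magnitude=0.0,
        proportion_shift_magnitude=0.0,
        cell_count_effect_sd=0.0,
        fraction_null=1.0,
    )
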