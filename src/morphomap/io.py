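"""Data containers and delimited-text readers/writers.

All tables travel as pandas DataFrames wrapped in thin dataclasses that
carry pipeline metadata (stage tags, dropped-feature lists).  Metadata
columns use the reserved ``Metadata_`` prefix, so they can never collide
with CellProfiler feature names (which always start with a compartment or
``mad`` token).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .names import DEFAULT_CHANNELS, is_parseable

METADATA_PREFIX = "Metadata_"
PLATE = "Metadata_Plate"
WELL = "Metadata_Well"
TREATMENT = "Metadata_Treatment"
REPLICATE = "Metadata_Replicate"
REQUIRED_METADATA = (PLATE, WELL, TREATMENT, REPLICATE)

#: Sentinel treatment label of untreated (negative-control) wells.
NEGATIVE_CONTROL = "EMPTY"

#: Profile stages in pipeline order.
STAGES = ("raw", "polished", "filtered", "selected", "reduced", "collapsed")


def _is_metadata(col: str) -> bool:
    return col.startswith(METADATA_PREFIX)


@dataclass
class CellTable:
    """Per-cell feature matrix plus plate/well/treatment/replicate metadata.

    ``data`` holds one row per cell.  Feature columns are every column not
    starting with ``Metadata_``; they must all be numeric and (unless
    listed in ``extra_columns``) follow the CellProfiler naming
    convention.
    """

    data: pd.DataFrame
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    extra_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_METADATA if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cell table is missing metadata columns: {missing}")
        bad = [
            c
            for c in self.feature_names
            if not is_parseable(c, self.channels)
        ]
        if bad:
            raise SchemaError(
                f"feature columns do not follow the naming convention and are "
                f"not flagged as extra columns: {bad[:5]}"
                + ("..." if len(bad) > 5 else "")
            )
        nwt = self.data.groupby([PLATE, WELL], observed=True)[TREATMENT].nunique()
        clash = nwt[nwt > 1]
        if len(clash):
            raise SchemaError(
                f"wells holding more than one treatment: {list(clash.index)[:5]}"
            )

    @property
    def feature_names(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if not _is_metadata(c) and c not in self.extra_columns
        ]

    @property
    def plates(self) -> list:
        return sorted(self.data[PLATE].unique())

    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    def with_data(self, data: pd.DataFrame) -> "CellTable":
        return CellTable(data, channels=self.channels, extra_columns=self.extra_columns)


@dataclass
class ProfileMatrix:
    """Per-well (or per-treatment, once collapsed) profile vectors.

    Rows are indexed by the ``Metadata_`` columns; value columns are the
    per-feature medians, per-feature MADs (``mad_``-prefixed) and the cell
    count, or principal-component scores once reduced.
    """

    data: pd.DataFrame
    stage: str = "raw"
    dropped_features: tuple[str, ...] = ()
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise SchemaError(f"unknown profile stage {self.stage!r}")
        idx = STAGES.index(self.stage)
        if idx >= STAGES.index("filtered"):
            if self.values().isna().any().any():
                raise SchemaError(
                    f"profiles at stage {self.stage!r} must not contain "
                    "missing values"
                )

    @property
    def value_columns(self) -> list[str]:
        return [c for c in self.data.columns if not _is_metadata(c)]

    @property
    def metadata_columns(self) -> list[str]:
        return [c for c in self.data.columns if _is_metadata(c)]

    def values(self) -> pd.DataFrame:
        return self.data[self.value_columns]

    def matrix(self) -> np.ndarray:
        return self.data[self.value_columns].to_numpy(dtype=float)

    def treatments(self, include_controls: bool = False) -> list:
        t = self.data[TREATMENT].unique().tolist()
        if not include_controls:
            t = [x for x in t if x != NEGATIVE_CONTROL]
        return sorted(t)

    def controls(self) -> pd.DataFrame:
        return self.data[self.data[TREATMENT] == NEGATIVE_CONTROL]

    def non_controls(self) -> pd.DataFrame:
        return self.data[self.data[TREATMENT] != NEGATIVE_CONTROL]

    def with_values(self, values: pd.DataFrame, stage: str | None = None) -> "ProfileMatrix":
        """Replace value columns, keeping row metadata aligned by position."""
        meta = self.data[self.metadata_columns].reset_index(drop=True)
        out = pd.concat([meta, values.reset_index(drop=True)], axis=1)
        return ProfileMatrix(
            out,
            stage=stage or self.stage,
            dropped_features=self.dropped_features,
            notes=dict(self.notes),
        )


@dataclass(frozen=True)
class AnnotationSet:
    """Gene-pair relations: physical interactions and pathway membership."""

    interactions: frozenset[frozenset]
    pathways: Mapping[str, frozenset]

    def has_interaction(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.interactions

    def same_pathway(self, a: str, b: str) -> bool:
        pa = self.pathways.get(a, frozenset())
        pb = self.pathways.get(b, frozenset())
        return bool(pa & pb)

    def pathway_members(self) -> dict[str, set]:
        out: dict[str, set] = {}
        for gene, pws in self.pathways.items():
            for pw in pws:
                out.setdefault(pw, set()).add(gene)
        return out

    def same_pathway_pairs(self, genes: Iterable[str]) -> set[frozenset]:
        genes = list(genes)
        return {
            frozenset((a, b))
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
            if self.same_pathway(a, b)
        }


# ---------------------------------------------------------------------------
# readers / writers


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect in ("csv", ","):
        return ","
    if dialect in ("tsv", "\t", "tab"):
        return "\t"
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_cell_table(
    path: str | Path,
    dialect: str | None = None,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    extra_columns: Sequence[str] = (),
) -> CellTable:
    """Read a per-cell feature table from delimited text.

    The delimiter is inferred from the file extension (``.tsv``/``.txt``
    tab, otherwise comma) unless ``dialect`` says otherwise.  Feature
    columns containing non-numeric entries are rejected with row/column
    diagnostics.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_METADATA if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required metadata columns: {missing}"
        )
    feature_cols = [
        c for c in df.columns if not _is_metadata(c) and c not in extra_columns
    ]
    for c in feature_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[c].iloc[row]!r} in feature "
                f"column {c!r}, row {row}"
            )
        df[c] = coerced
    return CellTable(df, channels=tuple(channels), extra_columns=tuple(extra_columns))


def write_cell_table(cells: CellTable, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    cells.data.to_csv(path, sep=_infer_sep(path, dialect), index=False)


def write_profiles(profiles: ProfileMatrix, path: str | Path) -> None:
    """Write profiles as delimited text plus a JSON schema sidecar.

    Floats are written with ``repr`` round-trip precision so a read-back
    reproduces the numeric values exactly.
    """
    path = Path(path)
    profiles.data.to_csv(path, sep=_infer_sep(path, None), index=False,
                         float_format=None)
    sidecar = {
        "stage": profiles.stage,
        "metadata_columns": profiles.metadata_columns,
        "value_columns": profiles.value_columns,
        "dropped_features": list(profiles.dropped_features),
        "notes": {k: v for k, v in profiles.notes.items() if _jsonable(v)},
    }
    Path(str(path) + ".schema.json").write_text(json.dumps(sidecar, indent=1))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
    except TypeError:
        return False
    return True


def read_profiles(path: str | Path) -> ProfileMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, None))
    sidecar_path = Path(str(path) + ".schema.json")
    stage, dropped, notes = "raw", (), {}
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        stage = sc.get("stage", "raw")
        dropped = tuple(sc.get("dropped_features", ()))
        notes = sc.get("notes", {})
    return ProfileMatrix(df, stage=stage, dropped_features=dropped, notes=notes)


def read_annotations(
    interactions_path: str | Path | None = None,
    gmt_path: str | Path | None = None,
) -> AnnotationSet:
    """Read gene-pair interactions (two-column TSV) and pathway sets (GMT).

    Interaction pairs are unordered; ``(A,B)`` and ``(B,A)`` collapse to a
    single pair and self-pairs are dropped.
    """
    interactions: set[frozenset] = set()
    if interactions_path is not None:
        with open(interactions_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise SchemaError(
                        f"{interactions_path}: expected two tab-separated "
                        f"columns, got {line!r}"
                    )
                a, b = parts[0], parts[1]
                if a != b:
                    interactions.add(frozenset((a, b)))
    pathways: dict[str, set] = {}
    if gmt_path is not None:
        with open(gmt_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise SchemaError(
                        f"{gmt_path}: GMT lines need set name, description "
                        f"and at least one gene: {line!r}"
                    )
                name, _desc, *genes = parts
                for g in genes:
                    if g:
                        pathways.setdefault(g, set()).add(name)
    return AnnotationSet(
        interactions=frozenset(interactions),
        pathways={g: frozenset(p) for g, p in pathways.items()},
    )


def write_annotations(
    annotations: AnnotationSet,
    interactions_path: str | Path | None = None,
    gmt_path: str | Path | None = None,
) -> None:
    if interactions_path is not None:
        with open(interactions_path, "w") as fh:
            for pair in sorted(tuple(sorted(p)) for p in annotations.interactions):
                fh.write(f"{pair[0]}\t{pair[1]}\n")
    if gmt_path is not None:
        members = annotations.pathway_members()
        with open(gmt_path, "w") as fh:
            for pw in sorted(members):
                genes = "\t".join(sorted(members[pw]))
                fh.write(f"{pw}\tna\t{genes}\n")


# well-address helpers -------------------------------------------------------

_ROW_LETTERS = "ABCDEFGHIJKLMNOP"  # 16 rows covers 384-well plates


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A01'-style well address."""
    return f"{_ROW_LETTERS[row]}{col + 1:02d}"


def well_position(well: str) -> tuple[int, int]:
    """'A01'-style well address -> 0-based (row, col)."""
    row = _ROW_LETTERS.index(well[0].upper())
    return row, int(well[1:]) - 1


def is_edge_well(well: str, n_rows: int, n_cols: int) -> bool:
    r, c = well_position(well)
    return r in (0, n_rows - 1) or c in (0, n_cols - 1)
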