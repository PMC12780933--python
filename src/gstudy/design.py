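"""Measurement data model for crossed reliability designs.

A measurement study observes one quantity (here: muscle thickness in cm from
ultrasound images) under a fully crossed design over *facets* — participant,
observer, occasion and repetition.  Tables are long-format: one row per
observation, indexed by the facet labels plus a muscle label.  The participant
facet is the object of measurement; its variance is the "true" between-subject
variance, everything else is a potential source of measurement error.

This module defines the record/design containers, CSV input/output with
validation, and the conversion of per-image line measurements (distances
between the superficial and deep aponeuroses) into a single thickness value.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical facet ordering; component labels concatenate the symbols in this
#: order (p, r, o, ob), e.g. "po" = participant x occasion,
#: "proob" = participant x repetition x occasion x observer.
FACET_ORDER = ("participant", "repetition", "occasion", "observer")
FACET_SYMBOL = {
    "participant": "p",
    "repetition": "r",
    "occasion": "o",
    "observer": "ob",
}
SYMBOL_FACET = {v: k for k, v in FACET_SYMBOL.items()}
RESIDUAL = "residual"

DEFAULT_COLUMNS = {
    "participant": "participant",
    "observer": "observer",
    "occasion": "occasion",
    "repetition": "repetition",
    "muscle": "muscle",
    "thickness_cm": "thickness_cm",
}


class SchemaError(ValueError):
    """The input table does not have the expected shape/columns."""


class ValidationError(ValueError):
    """The input table has the right shape but invalid content."""


def component_label(facets: Iterable[str]) -> str:
    """Canonical label for a variance component (a set of facet names)."""
    facets = set(facets)
    unknown = facets - set(FACET_ORDER)
    if unknown:
        raise ValueError(f"unknown facets: {sorted(unknown)}")
    if not facets:
        raise ValueError("a variance component must involve at least one facet")
    return "".join(FACET_SYMBOL[f] for f in FACET_ORDER if f in facets)


def component_facets(label: str) -> frozenset[str]:
    """Parse a component label like ``'poob'`` back into its facet names."""
    if label == RESIDUAL:
        raise ValueError("the residual is not a facet component")
    facets: set[str] = set()
    i = 0
    while i < len(label):
        if label[i : i + 2] == "ob":
            facets.add("observer")
            i += 2
        elif label[i] in ("p", "r", "o"):
            facets.add(SYMBOL_FACET[label[i]])
            i += 1
        else:
            raise ValueError(f"cannot parse component label {label!r}")
    return frozenset(facets)


def component_order(label: str) -> int:
    """Number of facets in a component (residual sorts last)."""
    if label == RESIDUAL:
        return len(FACET_ORDER) + 1
    return len(component_facets(label))


def sort_components(labels: Iterable[str]) -> list[str]:
    """Deterministic ordering: by interaction order, then lexicographically."""
    return sorted(labels, key=lambda c: (component_order(c), c))


@dataclass
class MeasurementRecord:
    """One thickness observation of one muscle."""

    participant_id: str
    observer_id: str
    occasion_id: str
    repetition_id: str
    muscle: str
    thickness_cm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.thickness_cm) or self.thickness_cm <= 0:
            raise ValidationError(
                f"thickness must be a positive real, got {self.thickness_cm!r}"
            )


@dataclass
class StudyDesign:
    """Facet structure of a fully crossed measurement design.

    Parameters
    ----------
    facets : ordered facet names (a subset of :data:`FACET_ORDER`).
    levels : number of distinct labels per facet.
    object_facet : the facet whose variance is the true score variance.
    balanced : True iff every cell of the full cross holds exactly one record
        (per muscle).
    """

    facets: tuple[str, ...]
    levels: dict[str, int]
    object_facet: str = "participant"
    balanced: bool = True

    def __post_init__(self) -> None:
        self.facets = tuple(f for f in FACET_ORDER if f in self.facets)
        if self.object_facet not in self.facets:
            raise ValueError(
                f"object facet {self.object_facet!r} not among facets {self.facets}"
            )
        for f in self.facets:
            if self.levels.get(f, 0) < 1:
                raise ValueError(f"facet {f!r} must have >= 1 level")

    @property
    def n_cells(self) -> int:
        return int(np.prod([self.levels[f] for f in self.facets]))

    @property
    def multi_level_facets(self) -> tuple[str, ...]:
        return tuple(f for f in self.facets if self.levels[f] > 1)

    @property
    def single_level_facets(self) -> tuple[str, ...]:
        return tuple(f for f in self.facets if self.levels[f] == 1)

    def to_dict(self) -> dict:
        return {
            "facets": list(self.facets),
            "levels": dict(self.levels),
            "object_facet": self.object_facet,
            "balanced": self.balanced,
        }


@dataclass
class LineMeasurement:
    """Distances (cm) of the manually drawn lines between aponeuroses."""

    distances_cm: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.distances_cm) < 1:
            raise ValidationError("at least one line distance is required")
        arr = np.asarray(self.distances_cm, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValidationError("all line distances must be positive reals")


def thickness_from_lines(lines: LineMeasurement | Sequence[float]) -> float:
    """Muscle thickness as the arithmetic mean of the drawn-line distances.

    Three lines (left, middle, right) are standard; when an aponeurosis is
    partly invisible an extra line may be present — any number >= 1 of lines
    is averaged.
    """
    if not isinstance(lines, LineMeasurement):
        lines = LineMeasurement(list(lines))
    return float(np.mean(np.asarray(lines.distances_cm, dtype=float)))


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for facet in FACET_ORDER + ("muscle",):
        out[facet] = out[facet].astype(str).str.strip()
    out["thickness_cm"] = pd.to_numeric(out["thickness_cm"], errors="coerce")
    return out


def infer_design(records: pd.DataFrame, object_facet: str = "participant") -> StudyDesign:
    """Infer the :class:`StudyDesign` (levels, balance) from a long table."""
    levels = {f: int(records[f].nunique()) for f in FACET_ORDER}
    balanced = True
    n_cells = int(np.prod(list(levels.values())))
    for _, sub in records.groupby("muscle", sort=False):
        cells = sub.groupby(list(FACET_ORDER), sort=False).size()
        if len(cells) != n_cells or (cells != 1).any():
            balanced = False
            break
    return StudyDesign(
        facets=FACET_ORDER, levels=levels, object_facet=object_facet, balanced=balanced
    )


def load_measurements(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, StudyDesign]:
    """Read a long-format measurement CSV and infer its design.

    Returns a normalized DataFrame with the canonical columns
    ``participant, observer, occasion, repetition, muscle, thickness_cm`` and
    the inferred :class:`StudyDesign`.

    Raises
    ------
    SchemaError
        Missing file content or missing mapped columns.
    ValidationError
        Non-positive/NaN thickness values or duplicated
        (participant, observer, occasion, repetition, muscle) keys; the
        message lists the offending rows.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(raw.columns)}"
        )
    if len(raw) == 0:
        raise SchemaError(f"{path}: table has a header but no rows")
    df = raw.rename(columns={v: k for k, v in colmap.items()})
    df = _normalise(df[list(DEFAULT_COLUMNS)])

    bad = df.index[~(df["thickness_cm"] > 0) | df["thickness_cm"].isna()]
    if len(bad):
        rows = ", ".join(str(i) for i in bad[:20])
        raise ValidationError(
            f"{path}: non-positive or unparseable thickness in row(s) [{rows}]"
            + ("..." if len(bad) > 20 else "")
        )
    key = list(FACET_ORDER) + ["muscle"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        rows = ", ".join(str(i) for i in df.index[dup][:20])
        raise ValidationError(
            f"{path}: duplicated (participant, observer, occasion, repetition, "
            f"muscle) key in row(s) [{rows}]"
        )
    return df, infer_design(df)


def write_measurements(records: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table as CSV with the canonical column names."""
    records[list(DEFAULT_COLUMNS)].to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Report-only summary of a table against its (inferred) design."""

    n_records: int
    level_counts: dict[str, int]
    single_level_facets: list[str]
    balanced: bool
    missing_cells: list[tuple]
    duplicated_cells: list[tuple]
    replication: dict[str, float]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["missing_cells"] = [list(c) for c in self.missing_cells]
        d["duplicated_cells"] = [list(c) for c in self.duplicated_cells]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = [
            f"records: {self.n_records}",
            "levels: "
            + ", ".join(f"{f}={n}" for f, n in self.level_counts.items()),
            f"balanced: {self.balanced}",
        ]
        if self.single_level_facets:
            lines.append(
                "single-level facets (structurally absent variance): "
                + ", ".join(self.single_level_facets)
            )
        if self.missing_cells:
            shown = "; ".join(str(c) for c in self.missing_cells[:10])
            more = len(self.missing_cells) - 10
            lines.append(
                f"missing cells ({len(self.missing_cells)}): {shown}"
                + (f" ... and {more} more" if more > 0 else "")
            )
        if self.duplicated_cells:
            lines.append(f"duplicated cells: {len(self.duplicated_cells)}")
        lines.append(
            "replication per cell: min={min:.0f} max={max:.0f} mean={mean:.2f}".format(
                **self.replication
            )
        )
        return "\n".join(lines)


def validate_design(
    records: pd.DataFrame, design: StudyDesign | None = None
) -> ValidationReport:
    """Check a table against the full-cross expectation; never raises."""
    if len(records) == 0:
        raise ValidationError("cannot validate an empty record collection")
    design = design or infer_design(records)
    levels = {f: sorted(records[f].unique()) for f in FACET_ORDER}
    missing: list[tuple] = []
    duplicated: list[tuple] = []
    sizes: list[int] = []
    for muscle, sub in records.groupby("muscle", sort=False):
        cells = sub.groupby(list(FACET_ORDER), sort=False).size()
        observed = set(cells.index)
        for combo in product(*(levels[f] for f in FACET_ORDER)):
            if combo not in observed:
                missing.append((muscle,) + combo)
        duplicated.extend((muscle,) + c for c in cells.index[cells > 1])
        sizes.extend(cells.tolist())
    sizes_arr = np.asarray(sizes, dtype=float)
    return ValidationReport(
        n_records=len(records),
        level_counts={f: len(levels[f]) for f in FACET_ORDER},
        single_level_facets=[f for f in FACET_ORDER if len(levels[f]) == 1],
        balanced=not missing and not duplicated,
        missing_cells=missing,
        duplicated_cells=duplicated,
        replication={
            "min": float(sizes_arr.min()),
            "max": float(sizes_arr.max()),
            "mean": float(sizes_arr.mean()),
        },
    )
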