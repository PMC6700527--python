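"""Tidy plate-data model: readers/writers with validation, dose series, layouts.

All tabular data in this package travels as a "well table": a tidy
:class:`pandas.DataFrame` with one row per (well, timepoint, readout).  The
dialect is a plain UTF-8 CSV with a single header row.  Concentrations are
in micromolar throughout; times in hours; well coordinates are 1-based
(row 1..16, col 1..24 on a 384-well plate) with A1-style labels available
via :func:`well_label`.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: drug labels with reserved meaning
CONTROL = "control"
UNTREATED_T0 = "untreated_t0"
RESERVED_DRUGS = frozenset({CONTROL, UNTREATED_T0})

READOUT_TYPES = ("viable_count", "nuclei_count", "dead_count", "surrogate_signal")

REQUIRED_COLUMNS = (
    "center_id",
    "scientist_id",
    "bio_rep",
    "plate_id",
    "row",
    "col",
    "drug",
    "concentration",
    "timepoint_h",
    "readout_type",
    "value",
)

#: columns that uniquely identify one measurement
KEY_COLUMNS = ("plate_id", "row", "col", "timepoint_h", "readout_type")

PLATE_DIMS_384 = (16, 24)
PLATE_DIMS_96 = (8, 12)


class ValidationError(ValueError):
    """Raised when a well table violates the dialect; carries all violations."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            f"{len(self.errors)} validation error(s):\n" + "\n".join(self.errors)
        )


class CapacityError(ValueError):
    """More treatments than wells on the plate."""


# ---------------------------------------------------------------------------
# well coordinates


def well_label(row: int, col: int) -> str:
    """1-based (row, col) -> plate label, e.g. (3, 5) -> 'C05'."""
    if not (1 <= row <= 26):
        raise ValueError(f"row {row} out of range 1..26")
    if col < 1:
        raise ValueError(f"col {col} must be >= 1")
    return f"{string.ascii_uppercase[row - 1]}{col:02d}"


def parse_well_label(label: str) -> tuple[int, int]:
    """Plate label -> 1-based (row, col); 'C05' -> (3, 5)."""
    label = label.strip().upper()
    if not label or label[0] not in string.ascii_uppercase or not label[1:].isdigit():
        raise ValueError(f"malformed well label: {label!r}")
    return string.ascii_uppercase.index(label[0]) + 1, int(label[1:])


# ---------------------------------------------------------------------------
# dose series


def dose_series(top_dose: float, n_points: int, fold: float) -> np.ndarray:
    """Descending geometric dilution series c_i = top_dose / fold**i.

    The standard design is a nine-point sqrt(10)-fold series from the top
    dose, spanning fold**(n_points - 1) (four orders of magnitude).
    """
    if top_dose <= 0:
        raise ValueError(f"top_dose must be > 0, got {top_dose}")
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    if fold <= 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    return top_dose / fold ** np.arange(n_points, dtype=float)


# ---------------------------------------------------------------------------
# layouts


@dataclass(frozen=True)
class PlateLayout:
    """Assignment of treatments to wells of one plate.

    ``assignment`` maps 1-based (row, col) to (drug, concentration, role)
    where role is ``"treatment"`` or ``"control"``.
    """

    dims: tuple[int, int]
    assignment: dict[tuple[int, int], tuple[str, float, str]] = field(
        default_factory=dict
    )

    def treatments(self) -> list[tuple[str, float]]:
        """Multiset of (drug, concentration) over occupied wells (sorted)."""
        return sorted((d, c) for d, c, _ in self.assignment.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"row": r, "col": c, "well": well_label(r, c),
             "drug": d, "concentration": conc, "role": role}
            for (r, c), (d, conc, role) in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows)


def randomize_layout(
    treatments,
    dims: tuple[int, int] = PLATE_DIMS_384,
    seed: int | np.random.Generator | None = None,
) -> PlateLayout:
    """Uniformly random assignment of a treatment multiset to distinct wells.

    ``treatments`` is an iterable of (drug, concentration) pairs; wells are
    drawn without replacement from the full plate.  Deterministic under a
    fixed seed.  Randomized dispensing converts systematic spatial bias
    (edge effects) into random error.
    """
    treatments = list(treatments)
    n_rows, n_cols = dims
    capacity = n_rows * n_cols
    if len(treatments) > capacity:
        raise CapacityError(
            f"{len(treatments)} treatments exceed plate capacity {capacity} "
            f"({n_rows}x{n_cols})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_wells = list(itertools.product(range(1, n_rows + 1), range(1, n_cols + 1)))
    picks = rng.choice(len(all_wells), size=len(treatments), replace=False)
    assignment = {}
    for (drug, conc), idx in zip(treatments, picks):
        role = "control" if drug in RESERVED_DRUGS else "treatment"
        assignment[all_wells[idx]] = (str(drug), float(conc), role)
    return PlateLayout(dims=dims, assignment=assignment)


# ---------------------------------------------------------------------------
# validation + I/O


def validate_dataset(df: pd.DataFrame) -> list[str]:
    """Collect dialect violations (empty list = valid). Row numbers are 1-based
    data rows, matching line numbers in the CSV minus the header."""
    errors: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing required column(s): {', '.join(missing)}"]

    def rownums(mask) -> str:
        idx = np.flatnonzero(np.asarray(mask))[:10] + 1
        return ", ".join(map(str, idx))

    value = pd.to_numeric(df["value"], errors="coerce")
    conc = pd.to_numeric(df["concentration"], errors="coerce")
    tp = pd.to_numeric(df["timepoint_h"], errors="coerce")

    bad = value.isna() | (value < 0)
    if bad.any():
        errors.append(f"non-numeric or negative value at row(s): {rownums(bad)}")
    bad = conc.isna() | (conc < 0)
    if bad.any():
        errors.append(f"non-numeric or negative concentration at row(s): {rownums(bad)}")
    bad = tp.isna() | (tp < 0)
    if bad.any():
        errors.append(f"non-numeric or negative timepoint_h at row(s): {rownums(bad)}")

    bad = ~df["readout_type"].isin(READOUT_TYPES)
    if bad.any():
        errors.append(
            f"unknown readout_type at row(s): {rownums(bad)} "
            f"(expected one of {READOUT_TYPES})"
        )

    is_reserved = df["drug"].isin(RESERVED_DRUGS)
    bad = is_reserved & (conc != 0)
    if bad.any():
        errors.append(
            f"control/untreated_t0 rows must have concentration 0; row(s): {rownums(bad)}"
        )
    bad = ~is_reserved & (conc == 0)
    if bad.any():
        errors.append(
            f"treated rows must have concentration > 0; row(s): {rownums(bad)}"
        )

    for coord, hi in (("row", 26), ("col", 48)):
        v = pd.to_numeric(df[coord], errors="coerce")
        bad = v.isna() | (v < 1) | (v > hi) | (v != v.round())
        if bad.any():
            errors.append(f"invalid {coord} at row(s): {rownums(bad)}")

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        first = df.loc[dup, list(KEY_COLUMNS)].iloc[0]
        errors.append(
            f"duplicated measurement key at row(s): {rownums(dup)} "
            f"(first duplicate: plate={first['plate_id']} "
            f"well={well_label(int(first['row']), int(first['col']))} "
            f"t={first['timepoint_h']} readout={first['readout_type']})"
        )
    return errors


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a tidy well table; raises ValidationError on violations."""
    df = pd.read_csv(path)
    errors = validate_dataset(df)
    if errors:
        raise ValidationError(errors)
    df["bio_rep"] = df["bio_rep"].astype(int)
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)
    for c in ("concentration", "timepoint_h", "value"):
        df[c] = df[c].astype(float)
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a validated tidy well table as CSV (raises on violations)."""
    errors = validate_dataset(df)
    if errors:
        raise ValidationError(errors)
    df.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))
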