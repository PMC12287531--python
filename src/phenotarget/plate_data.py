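"""Data model and file I/O for plate-reader measurements.

Plate data travel as long-format ("tidy") CSV: one row per well, with the
well role (sample / vehicle_control / background / blank) made explicit so
that downstream normalization never has to guess the plate layout.
Concentrations are stored internally in nM; the reader accepts a
``concentration_unit`` column (nM, uM/µM, M) and converts on ingest.

Derived tables (viability summaries, rankings, fits) are plain
:class:`pandas.DataFrame` objects written as UTF-8 TSV with 6 significant
digits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import PlateFormatError, PlateIntegrityError

ROLES = ("sample", "vehicle_control", "background", "blank")
CULTURES = ("monolayer", "spheroid", "organoid")

#: exact column set of the plate CSV dialect
PLATE_COLUMNS = (
    "plate_id",
    "well",
    "role",
    "compound_id",
    "concentration",
    "concentration_unit",
    "model_id",
    "culture",
    "timepoint_h",
    "replicate",
    "raw_signal",
)

_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "um": 1e3, "M": 1e9}
_WELL_RE = re.compile(r"^([A-Z]+)([0-9]+)$")

#: columns of a viability table (one row per compound/model/dose/timepoint)
VIABILITY_COLUMNS = (
    "compound_id",
    "model_id",
    "culture",
    "concentration_nm",
    "timepoint_h",
    "mean_viability",
    "sd",
    "n",
)


@dataclass(frozen=True)
class WellRecord:
    """One physical well on a plate.

    ``well`` is (row letter(s), 1-based column); ``concentration_nm`` is 0
    exactly when the well is not a sample well (controls carry no compound).
    """

    plate_id: str
    well: tuple[str, int]
    role: str
    compound_id: str
    concentration_nm: float
    model_id: str
    culture: str
    timepoint_h: float
    replicate: int
    raw_signal: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PlateIntegrityError(f"unknown well role {self.role!r}")
        if self.raw_signal < 0:
            raise ValueError(f"negative raw signal {self.raw_signal} in well "
                             f"{self.plate_id}/{well_label(self.well)}")
        if self.role in ("vehicle_control", "background") and self.compound_id:
            raise PlateIntegrityError(
                f"{self.role} well {well_label(self.well)} must have empty compound_id")
        is_sample = self.role == "sample"
        if is_sample and self.concentration_nm <= 0:
            raise PlateIntegrityError(
                f"sample well {well_label(self.well)} requires concentration > 0")
        if not is_sample and self.concentration_nm != 0:
            raise PlateIntegrityError(
                f"{self.role} well {well_label(self.well)} must have concentration 0")


def parse_well(label: str) -> tuple[str, int]:
    """Parse ``'A1'`` -> ``('A', 1)``; raise :class:`PlateFormatError` otherwise."""
    m = _WELL_RE.match(str(label).strip())
    if not m or int(m.group(2)) < 1:
        raise PlateFormatError(f"bad well address {label!r} (expected e.g. A1..H12)")
    return m.group(1), int(m.group(2))


def well_label(well: tuple[str, int]) -> str:
    return f"{well[0]}{well[1]}"


def _to_nanomolar(value: float, unit: str) -> float:
    unit = str(unit).strip()
    if unit not in _UNIT_TO_NM:
        raise PlateFormatError(f"unknown concentration_unit {unit!r}")
    return float(value) * _UNIT_TO_NM[unit]


def read_plate_csv(path) -> list[WellRecord]:
    """Read a long-format plate CSV into validated :class:`WellRecord` objects.

    Raises
    ------
    PlateFormatError
        if a canonical column is missing or an extra column is present.
    PlateIntegrityError
        if (plate_id, well) repeats or a role invariant is violated.
    ValueError
        for negative raw signals.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str,
                                  "compound_id": str, "model_id": str,
                                  "culture": str, "concentration_unit": str},
                     keep_default_na=False)
    have, want = set(df.columns), set(PLATE_COLUMNS)
    missing = want - have
    if missing:
        raise PlateFormatError(f"missing column(s): {', '.join(sorted(missing))}")
    unknown = have - want
    if unknown:
        raise PlateFormatError(f"unknown column(s): {', '.join(sorted(unknown))}")

    records: list[WellRecord] = []
    seen: set[tuple[str, tuple[str, int]]] = set()
    for row in df.itertuples(index=False):
        well = parse_well(row.well)
        key = (row.plate_id, well)
        if key in seen:
            raise PlateIntegrityError(
                f"duplicate well {well_label(well)} on plate {row.plate_id}")
        seen.add(key)
        records.append(WellRecord(
            plate_id=row.plate_id,
            well=well,
            role=row.role,
            compound_id=row.compound_id,
            concentration_nm=_to_nanomolar(row.concentration, row.concentration_unit),
            model_id=row.model_id,
            culture=row.culture,
            timepoint_h=float(row.timepoint_h),
            replicate=int(row.replicate),
            raw_signal=float(row.raw_signal),
        ))
    return records


def records_to_frame(records: Iterable[WellRecord]) -> pd.DataFrame:
    """Flatten WellRecords to a DataFrame (well rendered as its label)."""
    rows = [{
        "plate_id": r.plate_id,
        "well": well_label(r.well),
        "role": r.role,
        "compound_id": r.compound_id,
        "concentration": r.concentration_nm,
        "concentration_unit": "nM",
        "model_id": r.model_id,
        "culture": r.culture,
        "timepoint_h": r.timepoint_h,
        "replicate": r.replicate,
        "raw_signal": r.raw_signal,
    } for r in records]
    return pd.DataFrame(rows, columns=list(PLATE_COLUMNS))


def write_plate_csv(records: Iterable[WellRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_table(table: pd.DataFrame, path) -> None:
    """Write any tabular result as TSV with 6 significant digits.

    Read-back with :func:`read_table` reproduces values to that precision.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty table")
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def is_viability_table(df: pd.DataFrame) -> bool:
    return set(VIABILITY_COLUMNS) <= set(df.columns)


__all__ = [
    "WellRecord", "ROLES", "CULTURES", "PLATE_COLUMNS", "VIABILITY_COLUMNS",
    "parse_well", "well_label", "read_plate_csv", "write_plate_csv",
    "records_to_frame", "write_table", "read_table", "is_viability_table",
]
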