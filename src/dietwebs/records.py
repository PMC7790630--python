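"""Diet-record data model and tabular (CSV) interchange format.

A :class:`DietRecord` is one predator-prey dietary observation: which study
it came from, where and when the sample was taken, and the two stomach-content
diet metrics used throughout the package:

* ``fraction_occurrence`` — proportion of sampled stomachs/scats of the
  predator that contained the prey at least once;
* ``fraction_diet_weight`` — proportion of total stomach-content mass
  attributable to the prey (gravimetric).

Both metrics are stored internally as proportions in ``[0, 1]``; source
files that report percentages are converted at read time (``percent_mode``).
Longitudes are normalized to ``[-180, 180)`` (degrees east positive) so that
all downstream sector arithmetic uses a single convention.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CANONICAL_COLUMNS",
    "METHODS",
    "DietRecord",
    "RowRejection",
    "ReadResult",
    "normalize_longitude",
    "validate_record",
    "read_records",
    "write_records",
]

#: Canonical CSV header, in order. Missing values are empty fields.
CANONICAL_COLUMNS = (
    "record_id",
    "source_id",
    "predator_name",
    "prey_name",
    "latitude",
    "longitude",
    "month",
    "fraction_occurrence",
    "fraction_diet_weight",
    "method",
)

#: Recognized sampling methodologies.
METHODS = ("stomach", "stomach_flush", "scat", "other")


def normalize_longitude(longitude: float) -> float:
    """Map a longitude in degrees onto the half-open interval ``[-180, 180)``.

    Idempotent: values already in range are returned unchanged.
    """
    lon = math.fmod(longitude, 360.0)
    if lon >= 180.0:
        lon -= 360.0
    elif lon < -180.0:
        lon += 360.0
    # fmod(-0.0) and the 180.0 boundary both land exactly on -180.0 here
    return lon + 0.0


@dataclass(frozen=True)
class DietRecord:
    """One predator-prey dietary observation.

    Parameters
    ----------
    record_id
        Opaque unique identifier within a dataset.
    source_id
        Identifier of the contributing study (one per published or
        unpublished study); the sampling unit for accumulation curves.
    predator_name, prey_name
        Reported taxon names; later replaced by trophic-group names by
        :func:`dietwebs.webs.map_taxa`.
    latitude, longitude
        Decimal degrees; latitude in ``[-90, 90]``, longitude normalized to
        ``[-180, 180)``.
    month
        Collection month 1-12, or ``None`` when unreported.
    fraction_occurrence, fraction_diet_weight
        Diet metrics as proportions in ``[0, 1]``, or ``None`` when the
        study did not report them.
    method
        One of ``stomach``, ``stomach_flush``, ``scat``, ``other``.
    """

    record_id: str
    source_id: str
    predator_name: str
    prey_name: str
    latitude: float
    longitude: float
    month: int | None = None
    fraction_occurrence: float | None = None
    fraction_diet_weight: float | None = None
    method: str = "other"


@dataclass(frozen=True)
class RowRejection:
    """Diagnostic for a row that failed validation at read time."""

    row_number: int
    record_id: str
    reason: str


@dataclass
class ReadResult:
    """Validated records plus the per-row rejection report."""

    records: list[DietRecord]
    rejections: list[RowRejection]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def validate_record(record: DietRecord) -> list[str]:
    """Return the list of invariant violations for ``record`` (empty if valid)."""
    problems: list[str] = []
    if not record.source_id:
        problems.append("source_id is empty")
    if not record.predator_name or not record.prey_name:
        problems.append("predator_name and prey_name must both be non-empty")
    if not -90.0 <= record.latitude <= 90.0:
        problems.append(f"latitude {record.latitude} outside [-90, 90]")
    if not -180.0 <= record.longitude < 180.0:
        problems.append(f"longitude {record.longitude} outside [-180, 180)")
    if record.month is not None and not 1 <= record.month <= 12:
        problems.append(f"month {record.month} outside 1-12")
    for name in ("fraction_occurrence", "fraction_diet_weight"):
        value = getattr(record, name)
        if value is not None and not 0.0 <= value <= 1.0:
            problems.append(f"{name} {value} outside [0, 1]")
    if record.method not in METHODS:
        problems.append(f"unknown method {record.method!r}")
    return problems


class FormatError(ValueError):
    """Raised when a record file is structurally unreadable (bad header)."""


def _parse_float(text: str, field: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"{field} {text!r} is not a number") from exc


def _parse_row(
    row: dict[str, str], percent_mode: bool
) -> DietRecord:
    latitude = _parse_float(row["latitude"], "latitude")
    longitude = normalize_longitude(_parse_float(row["longitude"], "longitude"))

    month_text = row["month"].strip()
    month: int | None = None
    if month_text:
        try:
            month = int(month_text)
        except ValueError as exc:
            raise ValueError(f"month {month_text!r} is not an integer") from exc

    metrics: dict[str, float | None] = {}
    for field in ("fraction_occurrence", "fraction_diet_weight"):
        text = row[field].strip()
        if not text:
            metrics[field] = None
            continue
        value = _parse_float(text, field)
        if percent_mode:
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{field} {value} outside [0, 100] (percent mode)")
            value /= 100.0
        metrics[field] = value

    method = row["method"].strip() or "other"

    return DietRecord(
        record_id=row["record_id"].strip(),
        source_id=row["source_id"].strip(),
        predator_name=row["predator_name"].strip(),
        prey_name=row["prey_name"].strip(),
        latitude=latitude,
        longitude=longitude,
        month=month,
        fraction_occurrence=metrics["fraction_occurrence"],
        fraction_diet_weight=metrics["fraction_diet_weight"],
        method=method,
    )


def read_records(
    path: str | Path,
    *,
    percent_mode: bool = False,
    column_map: dict[str, str] | None = None,
) -> ReadResult:
    """Read and validate diet records from a canonical-schema CSV file.

    Rows failing validation are not fatal: they are dropped and reported in
    :attr:`ReadResult.rejections` with the row number, record id, and reason.
    Longitudes given in ``[0, 360)`` are normalized to ``[-180, 180)``.

    Parameters
    ----------
    path
        CSV file whose header declares the canonical column names.
    percent_mode
        If true, the file's diet metrics are percentages (0-100) and are
        divided by 100 on read.
    column_map
        Optional ``{file column -> canonical column}`` renaming, adapting a
        foreign export schema to the canonical one.

    Raises
    ------
    FormatError
        If a mandatory column is absent from the header.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        if column_map:
            header = [column_map.get(name, name) for name in header]
        missing = [c for c in CANONICAL_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"missing mandatory columns: {', '.join(missing)}")

        records: list[DietRecord] = []
        rejections: list[RowRejection] = []
        seen_ids: set[str] = set()
        for row_number, raw in enumerate(reader, start=2):
            if column_map:
                raw = {column_map.get(k, k): v for k, v in raw.items()}
            record_id = (raw.get("record_id") or "").strip()
            try:
                record = _parse_row(raw, percent_mode)
            except ValueError as exc:
                rejections.append(RowRejection(row_number, record_id, str(exc)))
                continue
            problems = validate_record(record)
            if record.record_id in seen_ids:
                problems.append(f"duplicate record_id {record.record_id!r}")
            if problems:
                rejections.append(
                    RowRejection(row_number, record_id, "; ".join(problems))
                )
                continue
            seen_ids.add(record.record_id)
            records.append(record)
    return ReadResult(records=records, rejections=rejections)


def _format_value(value: float | int | None) -> str:
    if value is None:
        return ""
    return repr(value) if isinstance(value, float) else str(value)


def write_records(records: Iterable[DietRecord], path: str | Path) -> Path:
    """Write records to a canonical-schema CSV file (UTF-8, header row).

    Round trip: ``read_records(write_records(r)).records == r`` for validated
    records. Floats are written with full precision (``repr``).
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CANONICAL_COLUMNS)
        for record in records:
            writer.writerow(
                [
                    record.record_id,
                    record.source_id,
                    record.predator_name,
                    record.prey_name,
                    _format_value(record.latitude),
                    _format_value(record.longitude),
                    _format_value(record.month),
                    _format_value(record.fraction_occurrence),
                    _format_value(record.fraction_diet_weight),
                    record.method,
                ]
            )
    return path


def relabel(record: DietRecord, **changes) -> DietRecord:
    """Return a copy of ``record`` with the given fields replaced."""
    return replace(record, **changes)
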