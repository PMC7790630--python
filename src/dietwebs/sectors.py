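"""Longitude-sector assignment with dateline wraparound.

The default scheme is the four major Southern Ocean sectors, delimited by
meridians and corresponding approximately to the ocean basins:

========  ==============  =========================
Sector    Bounds          Half-open interval(s)
========  ==============  =========================
Atlantic     55°W-55°E    ``[-55, 55)``
Indian       55°E-145°E   ``[55, 145)``
West Pacific 145°E-115°W  ``[145, 180) ∪ [-180, -115)``
East Pacific 115°W-55°W   ``[-115, -55)``
========  ==============  =========================

Intervals are half-open ``[west, east)`` proceeding eastward on the circle,
so a record exactly on 55°E belongs to the Indian sector; any consistent
convention preserves the partition property. A sector whose western bound
exceeds its eastern bound wraps across the dateline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from dietwebs.records import DietRecord

__all__ = ["Sector", "SectorScheme", "SOUTHERN_OCEAN_SECTORS", "assign_sector", "split_by_sector"]


@dataclass(frozen=True)
class Sector:
    """A named half-open longitude interval ``[west, east)`` on the circle."""

    name: str
    west: float
    east: float

    @property
    def width(self) -> float:
        """Angular width in degrees; wrapping sectors handled modulo 360."""
        return (self.east - self.west) % 360.0 or 360.0

    def contains(self, longitude: float) -> bool:
        if self.west <= self.east:
            return self.west <= longitude < self.east
        return longitude >= self.west or longitude < self.east


@dataclass(frozen=True)
class SectorScheme:
    """An ordered set of sectors that partitions the full circle.

    Raises ``ValueError`` at construction if the intervals overlap or leave
    gaps (checked analytically: widths must sum to 360° and no longitude may
    fall in two sectors).
    """

    sectors: tuple[Sector, ...]

    def __post_init__(self) -> None:
        if not self.sectors:
            raise ValueError("scheme needs at least one sector")
        total = sum(s.width for s in self.sectors)
        if abs(total - 360.0) > 1e-9:
            raise ValueError(f"sector widths sum to {total}, expected 360")
        # widths sum to 360, so any double-coverage implies a gap elsewhere;
        # probing just west of and at every boundary detects both
        probes = []
        for s in self.sectors:
            probes.extend([s.west, s.east, s.west - 1e-6, s.east - 1e-6])
        for lon in probes:
            lon = ((lon + 180.0) % 360.0) - 180.0
            hits = [s.name for s in self.sectors if s.contains(lon)]
            if len(hits) != 1:
                raise ValueError(
                    f"longitude {lon} covered by {hits or 'no sector'}; "
                    "scheme must partition the circle"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sectors)

    def __iter__(self):
        return iter(self.sectors)


#: The four Southern Ocean sectors (bounds in degrees east).
SOUTHERN_OCEAN_SECTORS = SectorScheme(
    sectors=(
        Sector("Atlantic", -55.0, 55.0),
        Sector("Indian", 55.0, 145.0),
        Sector("West Pacific", 145.0, -115.0),
        Sector("East Pacific", -115.0, -55.0),
    )
)


def assign_sector(
    longitude: float, scheme: SectorScheme = SOUTHERN_OCEAN_SECTORS
) -> str:
    """Return the name of the unique sector containing ``longitude``.

    The longitude must already be normalized to ``[-180, 180)``; callers
    holding raw coordinates should pass them through
    :func:`dietwebs.records.normalize_longitude` first.
    """
    if not -180.0 <= longitude < 180.0:
        raise ValueError(f"longitude {longitude} not normalized to [-180, 180)")
    for sector in scheme:
        if sector.contains(longitude):
            return sector.name
    raise AssertionError("scheme invariant violated: no sector matched")


def split_by_sector(
    records: Iterable[DietRecord], scheme: SectorScheme = SOUTHERN_OCEAN_SECTORS
) -> dict[str, list[DietRecord]]:
    """Partition records by sector of their own coordinates.

    Every record lands in exactly one sector's list; sectors with no records
    are present with an empty list, so the result always has one key per
    sector in scheme order.
    """
    parts: dict[str, list[DietRecord]] = {name: [] for name in scheme.names}
    for record in records:
        parts[assign_sector(record.longitude, scheme)].append(record)
    return parts
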