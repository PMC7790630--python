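"""Dataset refinement: summer-only, Southern-Ocean-only, taxon-quality filters.

Three independent, order-insensitive predicates restrict a diet dataset to
the austral-summer Southern Ocean:

* **season** — keep only records collected in the retained months (default
  November-March, i.e. excluding the winter months April-October); records
  with no collection month are dropped by default since their season cannot
  be certified.
* **region** — keep only records at or south of a latitude ceiling (default
  40°S), plus an explicit exclusion list for manual geographic judgments
  (e.g. coastal continental samples) that cannot be computed from the record
  alone.
* **taxa** — drop records touching excluded taxa (nonliving items, names
  with too little taxonomic resolution such as "Fish"), along with the
  associated links.

:func:`apply_refinement` composes the three and produces an audit report
attributing each dropped record to the first rule it violated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from dietwebs.records import DietRecord

__all__ = [
    "RefinementConfig",
    "RefinementReport",
    "filter_season",
    "filter_region",
    "filter_taxa",
    "apply_refinement",
]

#: Filter application order for drop attribution.
RULES = ("season", "region", "taxa")


@dataclass(frozen=True)
class RefinementConfig:
    """Parameters of the three refinement filters.

    Defaults encode the austral-summer, south-of-40°S restriction:
    ``retained_months={11, 12, 1, 2, 3}`` and ``latitude_max=-40`` (records
    must satisfy ``latitude <= latitude_max``).
    """

    retained_months: frozenset[int] = frozenset({11, 12, 1, 2, 3})
    latitude_max: float = -40.0
    excluded_taxa: frozenset[str] = frozenset()
    excluded_records: frozenset[str] = frozenset()
    drop_missing_month: bool = True

    def __post_init__(self) -> None:
        months = frozenset(self.retained_months)
        if not months <= frozenset(range(1, 13)):
            raise ValueError(f"retained_months {sorted(months)} not within 1-12")
        object.__setattr__(self, "retained_months", months)
        object.__setattr__(self, "excluded_taxa", frozenset(self.excluded_taxa))
        object.__setattr__(self, "excluded_records", frozenset(self.excluded_records))

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "retained_months": sorted(self.retained_months),
            "latitude_max": self.latitude_max,
            "excluded_taxa": sorted(self.excluded_taxa),
            "excluded_records": sorted(self.excluded_records),
            "drop_missing_month": self.drop_missing_month,
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RefinementConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(
            retained_months=frozenset(payload.get("retained_months", {11, 12, 1, 2, 3})),
            latitude_max=float(payload.get("latitude_max", -40.0)),
            excluded_taxa=frozenset(payload.get("excluded_taxa", ())),
            excluded_records=frozenset(payload.get("excluded_records", ())),
            drop_missing_month=bool(payload.get("drop_missing_month", True)),
        )


def _season_ok(record: DietRecord, config: RefinementConfig) -> bool:
    if record.month is None:
        return not config.drop_missing_month
    return record.month in config.retained_months


def _region_ok(record: DietRecord, config: RefinementConfig) -> bool:
    return (
        record.latitude <= config.latitude_max
        and record.record_id not in config.excluded_records
    )


def _taxa_ok(record: DietRecord, config: RefinementConfig) -> bool:
    return (
        record.predator_name not in config.excluded_taxa
        and record.prey_name not in config.excluded_taxa
    )


_PREDICATES = {"season": _season_ok, "region": _region_ok, "taxa": _taxa_ok}


def filter_season(
    records: Sequence[DietRecord], config: RefinementConfig = RefinementConfig()
) -> list[DietRecord]:
    """Keep records collected in a retained month (austral summer by default)."""
    return [r for r in records if _season_ok(r, config)]


def filter_region(
    records: Sequence[DietRecord], config: RefinementConfig = RefinementConfig()
) -> list[DietRecord]:
    """Keep records at or south of the latitude ceiling and not manually excluded."""
    return [r for r in records if _region_ok(r, config)]


def filter_taxa(
    records: Sequence[DietRecord], config: RefinementConfig = RefinementConfig()
) -> list[DietRecord]:
    """Drop records whose predator or prey is on the excluded-taxa list."""
    return [r for r in records if _taxa_ok(r, config)]


@dataclass
class RefinementReport:
    """Audit of a refinement pass.

    ``drops`` maps each rule name to the number of records it removed, where
    a record violating several rules is attributed to the first violated
    rule in the order season, region, taxa. ``dropped`` lists
    ``(record_id, rule, reason)`` triples.
    """

    n_input: int
    n_retained: int
    drops: dict[str, int] = field(default_factory=dict)
    dropped: list[tuple[str, str, str]] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["record_id", "rule", "reason"])
            writer.writerows(self.dropped)
        return path


def _drop_reason(record: DietRecord, rule: str, config: RefinementConfig) -> str:
    if rule == "season":
        if record.month is None:
            return "collection month unknown"
        return f"month {record.month} outside retained months"
    if rule == "region":
        if record.record_id in config.excluded_records:
            return "manually excluded record"
        return f"latitude {record.latitude} north of {config.latitude_max}"
    offender = (
        record.predator_name
        if record.predator_name in config.excluded_taxa
        else record.prey_name
    )
    return f"excluded taxon {offender!r}"


def apply_refinement(
    records: Sequence[DietRecord], config: RefinementConfig = RefinementConfig()
) -> tuple[list[DietRecord], RefinementReport]:
    """Apply the season, region, and taxa filters and produce an audit report.

    The filters are independent predicates, so the surviving set does not
    depend on application order; the report attributes each drop to the
    first violated rule in the fixed order season → region → taxa, giving
    ``n_input == n_retained + sum(drops.values())`` exactly.
    """
    survivors: list[DietRecord] = []
    report = RefinementReport(
        n_input=len(records), n_retained=0, drops={rule: 0 for rule in RULES}
    )
    for record in records:
        violated = next(
            (rule for rule in RULES if not _PREDICATES[rule](record, config)), None
        )
        if violated is None:
            survivors.append(record)
        else:
            report.drops[violated] += 1
            report.dropped.append(
                (record.record_id, violated, _drop_reason(record, violated, config))
            )
    report.n_retained = len(survivors)
    return survivors, report
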