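"""Taxon aggregation and cumulative weighted directed food webs.

A food web here is *cumulative*: it pools trophic interactions across space
and time within a region, recording that two groups can interact, not the
flux at any instant. Edges point prey → predator (the direction of energy
flow) and carry, per distinct (prey, predator) pair:

* ``weight_occurrence`` — mean fraction of occurrence over the contributing
  records that report it (or ``None`` if none do);
* ``weight_diet`` — mean fraction of diet by weight, likewise;
* ``n_records`` — the number of contributing records, so that summing
  ``n_records`` over edges recovers the grouped-record count exactly.

Two group resolutions are supported: a fine scheme (~50 trophic groups,
single species where data allow) and a coarse scheme (~15 broad functional
groups). Coarse webs are built by re-labeling records to coarse groups and
re-averaging the pooled data — averaging data, not averages.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from dietwebs.records import DietRecord

__all__ = ["GroupScheme", "FoodWeb", "map_taxa", "build_web", "coarsen"]


@dataclass(frozen=True)
class GroupScheme:
    """Mapping from reported taxon names to trophic groups.

    Parameters
    ----------
    mapping
        ``taxon name -> group name``; every mapped taxon belongs to exactly
        one group.
    group_class
        ``group name -> broad class tag`` (e.g. ``zooplankton``,
        ``cephalopod``, ``mesopelagic fish``, ``seabird``, ``seal``).
    mid_trophic
        ``group name -> bool``; flags the mid-trophic groups (zooplankton
        through demersal fish) whose out-degree strengths are ranked.
    declared_size
        Optional declared group count (50 for the fine scheme, 15 for the
        coarse one); validated against the actual number of groups.
    """

    mapping: Mapping[str, str]
    group_class: Mapping[str, str] = field(default_factory=dict)
    mid_trophic: Mapping[str, bool] = field(default_factory=dict)
    declared_size: int | None = None

    def __post_init__(self) -> None:
        groups = set(self.mapping.values())
        if self.declared_size is not None and len(groups) != self.declared_size:
            raise ValueError(
                f"scheme declares {self.declared_size} groups but maps {len(groups)}"
            )
        stray = set(self.group_class) - groups | set(self.mid_trophic) - groups
        if stray:
            raise ValueError(f"class/mid-trophic tags for unmapped groups: {sorted(stray)}")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.mapping.values())))

    def mid_trophic_groups(self) -> tuple[str, ...]:
        return tuple(sorted(g for g, flag in self.mid_trophic.items() if flag))

    # -- serialization: taxon, group, class, mid_trophic CSV ---------------

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["taxon", "group", "class", "mid_trophic"])
            for taxon in sorted(self.mapping):
                group = self.mapping[taxon]
                writer.writerow(
                    [
                        taxon,
                        group,
                        self.group_class.get(group, ""),
                        "true" if self.mid_trophic.get(group, False) else "false",
                    ]
                )
        return path

    @classmethod
    def from_csv(cls, path: str | Path, declared_size: int | None = None) -> "GroupScheme":
        mapping: dict[str, str] = {}
        group_class: dict[str, str] = {}
        mid_trophic: dict[str, bool] = {}
        with Path(path).open(newline="", encoding="utf-8") as handle:
            for row in csv.DictReader(handle):
                taxon, group = row["taxon"].strip(), row["group"].strip()
                mapping[taxon] = group
                if row.get("class", "").strip():
                    group_class[group] = row["class"].strip()
                mid_trophic[group] = row.get("mid_trophic", "").strip().lower() in (
                    "true",
                    "1",
                    "yes",
                )
        return cls(mapping, group_class, mid_trophic, declared_size)


@dataclass
class FoodWeb:
    """A directed weighted food web over trophic groups.

    Thin wrapper around a :class:`networkx.DiGraph` whose edges run
    prey → predator and carry ``weight_occurrence``, ``weight_diet``
    (mean proportions, possibly ``None``) and ``n_records``.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        """(prey, predator) pairs in deterministic sorted order."""
        return sorted(self.graph.edges)

    def edge_data(self, prey: str, predator: str) -> dict:
        return dict(self.graph.edges[prey, predator])

    def has_edge(self, prey: str, predator: str) -> bool:
        return self.graph.has_edge(prey, predator)

    # -- exports -----------------------------------------------------------

    def to_edge_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "prey": prey,
                "predator": predator,
                "weight_occurrence": data.get("weight_occurrence"),
                "weight_diet": data.get("weight_diet"),
                "n_records": data.get("n_records"),
            }
            for (prey, predator), data in (
                ((e, self.graph.edges[e]) for e in self.edges())
            )
        ]
        return pd.DataFrame(
            rows,
            columns=["prey", "predator", "weight_occurrence", "weight_diet", "n_records"],
        )

    def write_edgelist_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_edge_dataframe().to_csv(path, index=False)
        return path

    def write_graphml(self, path: str | Path) -> Path:
        """GraphML export; ``None`` weights are omitted (GraphML cannot hold null)."""
        path = Path(path)
        clean = nx.DiGraph()
        clean.add_nodes_from(self.graph.nodes)
        for prey, predator, data in self.graph.edges(data=True):
            attrs = {k: v for k, v in data.items() if v is not None}
            clean.add_edge(prey, predator, **attrs)
        nx.write_graphml(clean, path)
        return path


def map_taxa(
    records: Sequence[DietRecord], scheme: GroupScheme
) -> tuple[list[DietRecord], list[tuple[str, str]]]:
    """Replace reported taxon names by trophic-group names.

    Records whose predator or prey taxon is absent from the scheme are
    dropped and reported, not raised: incomplete taxonomies are the norm in
    collated diet databases.

    Returns
    -------
    grouped, unmapped
        ``grouped`` — records with ``predator_name``/``prey_name`` replaced
        by group names; ``unmapped`` — ``(record_id, taxon)`` pairs for each
        dropped record (one entry per missing taxon).
    """
    grouped: list[DietRecord] = []
    unmapped: list[tuple[str, str]] = []
    for record in records:
        missing = [
            taxon
            for taxon in (record.predator_name, record.prey_name)
            if taxon not in scheme.mapping
        ]
        if missing:
            unmapped.extend((record.record_id, taxon) for taxon in missing)
            continue
        grouped.append(
            replace(
                record,
                predator_name=scheme.mapping[record.predator_name],
                prey_name=scheme.mapping[record.prey_name],
            )
        )
    return grouped, unmapped


def _mean_or_none(values: list[float]) -> float | None:
    return sum(values) / len(values) if values else None


def build_web(
    records: Sequence[DietRecord],
    metric: str = "occurrence",
    require_metric: bool = True,
) -> FoodWeb:
    """Build a cumulative weighted directed web from grouped records.

    One edge per distinct (prey group, predator group) pair with at least
    one contributing record. Both weights are always computed as the
    unweighted arithmetic mean of the metric over the contributing records
    that report it; ``metric`` selects which of the two governs edge
    retention when ``require_metric`` is true (pairs with no non-missing
    value for that metric are then omitted entirely, mirroring the exclusion
    of links lacking occurrence data from the sector webs).

    An empty input yields an empty web, not an error. Self-loops (a group
    preying on itself) are ordinary edges.
    """
    if metric not in ("occurrence", "diet_weight"):
        raise ValueError(f"metric must be 'occurrence' or 'diet_weight', got {metric!r}")
    key = "fraction_occurrence" if metric == "occurrence" else "fraction_diet_weight"

    pairs: dict[tuple[str, str], list[DietRecord]] = {}
    for record in records:
        pairs.setdefault((record.prey_name, record.predator_name), []).append(record)

    web = FoodWeb()
    for (prey, predator), members in sorted(pairs.items()):
        gating = [getattr(r, key) for r in members if getattr(r, key) is not None]
        if require_metric and not gating:
            continue
        occ = [r.fraction_occurrence for r in members if r.fraction_occurrence is not None]
        diet = [r.fraction_diet_weight for r in members if r.fraction_diet_weight is not None]
        web.graph.add_edge(
            prey,
            predator,
            weight_occurrence=_mean_or_none(occ),
            weight_diet=_mean_or_none(diet),
            n_records=len(members),
        )
    return web


def coarsen(
    records: Sequence[DietRecord],
    coarse_mapping: Mapping[str, str],
    metric: str = "diet_weight",
) -> FoodWeb:
    """Aggregate fine-group records into a coarse functional-group web.

    Records are re-labeled fine group → coarse group and the web is rebuilt
    from the pooled records with ``require_metric=False``: weights are
    recomputed from data, not by averaging fine-edge means, and edges with
    no diet-weight value anywhere are kept with ``weight_diet=None``
    (rendered dashed downstream — the interaction is known to occur but has
    no gravimetric datum).

    Raises
    ------
    KeyError
        If a fine group present in the records is absent from
        ``coarse_mapping`` (a configuration error, unlike unmapped raw taxa).
    """
    relabeled: list[DietRecord] = []
    for record in records:
        try:
            relabeled.append(
                replace(
                    record,
                    predator_name=coarse_mapping[record.predator_name],
                    prey_name=coarse_mapping[record.prey_name],
                )
            )
        except KeyError as exc:
            raise KeyError(
                f"fine group {exc.args[0]!r} missing from coarse mapping"
            ) from None
    return build_web(relabeled, metric=metric, require_metric=False)
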