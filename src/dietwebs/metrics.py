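"""Network structure statistics for weighted directed food webs.

For a web with ``S`` trophic groups and ``L`` realized predator-prey links:

* **connectance** ``C = L / S**2`` — the fraction of all possible directed
  links that are realized, with self-links counted as possible (the
  denominator is S², not S(S−1));
* **link density** ``LD = L / S`` — links per trophic group.

For an individual group, the out-degree is the number of groups feeding on
it, and the out-degree *strength* is the sum of the weights on those
outgoing edges — for a prey group, the weighted total of predation pressure
upon it. Strengths are computed under either diet metric; edges missing the
chosen metric contribute zero and are tallied separately.

``S`` counts groups participating in at least one retained edge: isolated
groups are absent by web construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from dietwebs.webs import FoodWeb, GroupScheme

__all__ = [
    "NetworkSummary",
    "network_summary",
    "out_strength",
    "in_strength",
    "strength_table",
]

_METRIC_KEY = {"occurrence": "weight_occurrence", "diet_weight": "weight_diet"}


@dataclass(frozen=True)
class NetworkSummary:
    """Whole-web structure statistics: S, L, C = L/S², LD = L/S."""

    S: int
    L: int
    C: float
    LD: float


def network_summary(web: FoodWeb) -> NetworkSummary:
    """Compute S, L, connectance, and link density for a non-empty web."""
    S, L = web.n_nodes, web.n_edges
    if S == 0:
        raise ValueError("summary undefined for an empty web")
    return NetworkSummary(S=S, L=L, C=L / S**2, LD=L / S)


def _metric_key(metric: str) -> str:
    try:
        return _METRIC_KEY[metric]
    except KeyError:
        raise ValueError(
            f"metric must be 'occurrence' or 'diet_weight', got {metric!r}"
        ) from None


def out_strength(web: FoodWeb, group: str, metric: str = "occurrence") -> float:
    """Sum of the chosen metric's weights over edges leaving ``group``.

    Edges whose weight for the metric is missing contribute 0 (use
    :func:`strength_table` for per-group missing-edge tallies). A group with
    no outgoing edges has strength 0. Raises ``KeyError`` for a group not in
    the web.
    """
    key = _metric_key(metric)
    if group not in web.graph:
        raise KeyError(f"group {group!r} not in web")
    return sum(
        data[key] or 0.0 for _, _, data in web.graph.out_edges(group, data=True)
    )


def in_strength(web: FoodWeb, group: str, metric: str = "occurrence") -> float:
    """Sum of the chosen metric's weights over edges entering ``group``."""
    key = _metric_key(metric)
    if group not in web.graph:
        raise KeyError(f"group {group!r} not in web")
    return sum(
        data[key] or 0.0 for _, _, data in web.graph.in_edges(group, data=True)
    )


def strength_table(
    web: FoodWeb,
    scheme: GroupScheme,
    sort_metric: str = "occurrence",
) -> pd.DataFrame:
    """Out-degree and out-strengths of the mid-trophic groups present in the web.

    One row per mid-trophic group (per the scheme's flags) that participates
    in the web, with columns:

    ``group``, ``out_degree`` (number of predator groups consuming it),
    ``out_strength_occurrence``, ``out_strength_diet`` (NaN when no outgoing
    edge carries that metric), ``n_missing_occurrence`` / ``n_missing_diet``
    (outgoing edges lacking the metric — the coverage note).

    Rows are sorted by descending strength under ``sort_metric``, ties
    broken alphabetically by group name.
    """
    sort_key = (
        "out_strength_occurrence"
        if _metric_key(sort_metric) == "weight_occurrence"
        else "out_strength_diet"
    )
    rows = []
    for group in scheme.mid_trophic_groups():
        if group not in web.graph:
            continue
        edges = list(web.graph.out_edges(group, data=True))
        occ = [d["weight_occurrence"] for _, _, d in edges if d["weight_occurrence"] is not None]
        diet = [d["weight_diet"] for _, _, d in edges if d["weight_diet"] is not None]
        rows.append(
            {
                "group": group,
                "out_degree": len(edges),
                "out_strength_occurrence": sum(occ) if occ else float("nan"),
                "out_strength_diet": sum(diet) if diet else float("nan"),
                "n_missing_occurrence": len(edges) - len(occ),
                "n_missing_diet": len(edges) - len(diet),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "group",
            "out_degree",
            "out_strength_occurrence",
            "out_strength_diet",
            "n_missing_occurrence",
            "n_missing_diet",
        ],
    )
    if not table.empty:
        table = table.sort_values(
            [sort_key, "group"], ascending=[False, True], na_position="last"
        ).reset_index(drop=True)
    return table
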