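"""Network summary statistics, strengths, and the brute-force oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dietwebs.metrics import (
    in_strength,
    network_summary,
    out_strength,
    strength_table,
)
from dietwebs.webs import FoodWeb, GroupScheme, build_web

from conftest import make_record, random_toy_web


def brute_force_summary(web: FoodWeb) -> tuple[int, int, float, float]:
    """Exhaustively enumerate possible directed links (incl. self-links)."""
    nodes = list(web.graph.nodes)
    realized = sum(
        1 for u in nodes for v in nodes if web.graph.has_edge(u, v)
    )
    S = len(nodes)
    return S, realized, realized / S**2, realized / S


def brute_force_out_strength(web: FoodWeb, group: str, key: str) -> float:
    total = 0.0
    for prey, predator, data in web.graph.edges(data=True):
        if prey == group and data[key] is not None:
            total += data[key]
    return total


class TestNetworkSummary:
    def test_complete_two_node_web(self):
        web = FoodWeb()
        for u in "ab":
            for v in "ab":
                web.graph.add_edge(u, v, weight_occurrence=0.5, weight_diet=None, n_records=1)
        summary = network_summary(web)
        assert (summary.S, summary.L) == (2, 4)
        assert summary.C == 1.0
        assert summary.LD == 2.0

    def test_empty_web_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            network_summary(FoodWeb())

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            web = random_toy_web(rng)
            S, L, C, LD = brute_force_summary(web)
            summary = network_summary(web)
            assert (summary.S, summary.L, summary.C, summary.LD) == (S, L, C, LD)


class TestStrengths:
    def test_no_outgoing_edges_means_zero(self):
        web = build_web([make_record("R0", prey="krill", predator="penguin", occ=0.5)])
        assert out_strength(web, "penguin") == 0.0

    def test_sum_of_two_weights(self):
        records = [
            make_record("R0", prey="krill", predator="penguin", occ=0.78),
            make_record("R1", prey="krill", predator="seal", occ=0.98),
        ]
        web = build_web(records)
        assert out_strength(web, "krill") == pytest.approx(1.76)

    def test_unknown_group_is_error(self):
        web = build_web([make_record("R0", occ=0.5)])
        with pytest.raises(KeyError):
            out_strength(web, "orca")

    def test_missing_weight_contributes_zero(self):
        records = [
            make_record("R0", prey="krill", predator="penguin", occ=0.5, diet=None),
            make_record("R1", prey="krill", predator="seal", occ=0.25, diet=0.9),
        ]
        web = build_web(records)
        assert out_strength(web, "krill", "diet_weight") == pytest.approx(0.9)

    def test_global_conservation_identity(self, rng):
        for _ in range(10):
            web = random_toy_web(rng)
            total_weight = sum(
                d["weight_occurrence"]
                for *_, d in web.graph.edges(data=True)
                if d["weight_occurrence"] is not None
            )
            out_total = math.fsum(out_strength(web, g) for g in web.nodes)
            in_total = math.fsum(in_strength(web, g) for g in web.nodes)
            assert out_total == pytest.approx(total_weight, abs=1e-12)
            assert in_total == pytest.approx(total_weight, abs=1e-12)

    def test_strength_bounded_by_degree(self, rng):
        web = random_toy_web(rng)
        for group in web.nodes:
            degree = web.graph.out_degree(group)
            strength = out_strength(web, group)
            assert 0.0 <= strength <= degree + 1e-12


class TestStrengthTable:
    SCHEME = GroupScheme(
        mapping={t: t for t in ["krill", "silverfish", "penguin", "seal"]},
        mid_trophic={"krill": True, "silverfish": True, "penguin": False, "seal": False},
    )

    def test_only_mid_trophic_rows_sorted_by_strength(self):
        records = [
            make_record("R0", prey="krill", predator="penguin", occ=0.9, diet=0.8),
            make_record("R1", prey="krill", predator="seal", occ=0.8, diet=0.7),
            make_record("R2", prey="silverfish", predator="penguin", occ=0.3, diet=0.2),
        ]
        table = strength_table(build_web(records), self.SCHEME)
        assert list(table["group"]) == ["krill", "silverfish"]
        assert table.loc[0, "out_degree"] == 2
        assert table.loc[0, "out_strength_occurrence"] == pytest.approx(1.7)
        assert table.loc[0, "out_strength_diet"] == pytest.approx(1.5)

    def test_alphabetical_tie_break(self):
        records = [
            make_record("R0", prey="silverfish", predator="penguin", occ=0.5),
            make_record("R1", prey="krill", predator="penguin", occ=0.5),
        ]
        table = strength_table(build_web(records), self.SCHEME)
        assert list(table["group"]) == ["krill", "silverfish"]

    def test_dominant_group_ranks_first_under_both_metrics(self):
        records = [
            make_record("R0", prey="krill", predator="penguin", occ=0.95, diet=0.9),
            make_record("R1", prey="krill", predator="seal", occ=0.9, diet=0.85),
            make_record("R2", prey="silverfish", predator="penguin", occ=0.2, diet=0.1),
            make_record("R3", prey="silverfish", predator="seal", occ=0.1, diet=0.05),
        ]
        web = build_web(records)
        by_occ = strength_table(web, self.SCHEME, sort_metric="occurrence")
        by_diet = strength_table(web, self.SCHEME, sort_metric="diet_weight")
        assert by_occ.loc[0, "group"] == "krill"
        assert by_diet.loc[0, "group"] == "krill"

    def test_missing_metric_reported_as_nan_with_coverage(self):
        records = [make_record("R0", prey="krill", predator="penguin", occ=0.5, diet=None)]
        table = strength_table(build_web(records), self.SCHEME)
        assert np.isnan(table.loc[0, "out_strength_diet"])
        assert table.loc[0, "n_missing_diet"] == 1
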