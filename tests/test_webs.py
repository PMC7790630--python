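"""Taxon-to-group mapping, web construction, and coarsening."""

from __future__ import annotations

import numpy as np
import pytest

from dietwebs.webs import FoodWeb, GroupScheme, build_web, coarsen, map_taxa

from conftest import make_record, random_records

FINE_SCHEME = GroupScheme(
    mapping={
        "Euphausia superba": "Antarctic krill",
        "Pleuragramma antarctica": "Antarctic silverfish",
        "Electrona antarctica": "myctophids",
        "Bathylagus": "bathylagids",
        "Pygoscelis antarcticus": "chinstrap penguin",
    },
    mid_trophic={
        "Antarctic krill": True,
        "Antarctic silverfish": True,
        "myctophids": True,
        "bathylagids": True,
        "chinstrap penguin": False,
    },
)


class TestGroupScheme:
    def test_declared_size_validated(self):
        with pytest.raises(ValueError, match="declares 50"):
            GroupScheme(mapping={"a": "A"}, declared_size=50)

    def test_csv_round_trip(self, tmp_path):
        path = FINE_SCHEME.to_csv(tmp_path / "scheme.csv")
        loaded = GroupScheme.from_csv(path)
        assert loaded.mapping == FINE_SCHEME.mapping
        assert loaded.mid_trophic_groups() == FINE_SCHEME.mid_trophic_groups()


class TestMapTaxa:
    def test_species_mapped_to_its_group(self):
        grouped, unmapped = map_taxa(
            [make_record("R0", prey="Euphausia superba")], FINE_SCHEME
        )
        assert grouped[0].prey_name == "Antarctic krill"
        assert grouped[0].predator_name == "chinstrap penguin"
        assert unmapped == []

    def test_unmapped_taxon_dropped_and_reported(self):
        grouped, unmapped = map_taxa(
            [make_record("R0", prey="Xenobalanus")], FINE_SCHEME
        )
        assert grouped == []
        assert unmapped == [("R0", "Xenobalanus")]

    def test_grouped_count_is_input_minus_unmapped(self):
        records = [make_record(f"R{i}", prey="Euphausia superba") for i in range(6)]
        records += [make_record(f"Rx{i}", prey="Mystery") for i in range(2)]
        grouped, unmapped = map_taxa(records, FINE_SCHEME)
        assert len(grouped) == len(records) - len(unmapped)


class TestBuildWeb:
    def test_mean_of_two_occurrence_values(self):
        records = [
            make_record("R0", prey="krill", predator="penguin", occ=0.4),
            make_record("R1", prey="krill", predator="penguin", occ=0.6),
        ]
        web = build_web(records)
        assert web.edges() == [("krill", "penguin")]
        assert web.edge_data("krill", "penguin")["weight_occurrence"] == pytest.approx(0.5)
        assert web.edge_data("krill", "penguin")["n_records"] == 2

    def test_missing_occurrence_excluded_when_required(self):
        records = [make_record("R0", occ=None)]
        assert build_web(records, require_metric=True).n_edges == 0
        web = build_web(records, require_metric=False)
        assert web.n_edges == 1
        assert web.edge_data(*web.edges()[0])["weight_occurrence"] is None

    def test_edge_weights_match_brute_force_means(self, rng):
        records = random_records(rng, n=50)
        web = build_web(records, require_metric=False)
        for prey, predator in web.edges():
            members = [
                r
                for r in records
                if r.prey_name == prey and r.predator_name == predator
            ]
            occ = [r.fraction_occurrence for r in members if r.fraction_occurrence is not None]
            data = web.edge_data(prey, predator)
            assert data["n_records"] == len(members)
            if occ:
                assert data["weight_occurrence"] == pytest.approx(np.mean(occ))
            else:
                assert data["weight_occurrence"] is None

    def test_record_conservation_into_edges(self, rng):
        records = random_records(rng, n=80)
        web = build_web(records, require_metric=False)
        total = sum(web.edge_data(*e)["n_records"] for e in web.edges())
        assert total == len(records)

    def test_empty_input_gives_empty_web(self):
        web = build_web([])
        assert web.n_nodes == web.n_edges == 0

    def test_self_loops_are_ordinary_edges(self):
        records = [make_record("R0", prey="squid", predator="squid", occ=0.2)]
        web = build_web(records)
        assert web.has_edge("squid", "squid")

    def test_nodes_are_exactly_groups_on_retained_edges(self):
        records = [
            make_record("R0", prey="krill", predator="penguin", occ=0.5),
            make_record("R1", prey="squid", predator="seal", occ=None),
        ]
        web = build_web(records, require_metric=True)
        assert web.nodes == ("krill", "penguin")


class TestCoarsen:
    COARSE = {
        "Antarctic krill": "zooplankton",
        "Antarctic silverfish": "pelagic fish",
        "myctophids": "mesopelagic fish",
        "bathylagids": "mesopelagic fish",
        "chinstrap penguin": "penguins",
    }

    def test_pooled_before_averaging(self):
        # myctophids and bathylagids both coarsen to mesopelagic fish:
        # the coarse weight averages the pooled records, not the fine means
        grouped, _ = map_taxa(
            [
                make_record("R0", prey="Electrona antarctica", diet=0.2),
                make_record("R1", prey="Electrona antarctica", diet=0.4),
                make_record("R2", prey="Bathylagus", diet=0.9),
            ],
            FINE_SCHEME,
        )
        web = coarsen(grouped, self.COARSE)
        weight = web.edge_data("mesopelagic fish", "penguins")["weight_diet"]
        assert weight == pytest.approx((0.2 + 0.4 + 0.9) / 3)  # not (0.3 + 0.9)/2

    def test_mean_of_three_diet_weights(self):
        grouped, _ = map_taxa(
            [
                make_record(f"R{i}", prey="Euphausia superba", diet=w)
                for i, w in enumerate([0.3, 0.6, 0.9])
            ],
            FINE_SCHEME,
        )
        web = coarsen(grouped, self.COARSE)
        assert web.edge_data("zooplankton", "penguins")["weight_diet"] == pytest.approx(0.6)

    def test_missing_diet_kept_but_flagged(self):
        grouped, _ = map_taxa(
            [make_record("R0", prey="Euphausia superba", diet=None)], FINE_SCHEME
        )
        web = coarsen(grouped, self.COARSE)
        assert web.edge_data("zooplankton", "penguins")["weight_diet"] is None

    def test_coarse_edge_count_equals_distinct_pair_enumeration(self, rng):
        records = random_records(rng, n=60)
        coarse_map = {
            "krill": "zooplankton",
            "copepods": "zooplankton",
            "amphipods": "zooplankton",
            "myctophids": "fish",
            "squid": "cephalopods",
            "penguin": "birds",
            "albatross": "birds",
            "seal": "mammals",
            "whale": "mammals",
        }
        web = coarsen(records, coarse_map)
        expected_pairs = {
            (coarse_map[r.prey_name], coarse_map[r.predator_name]) for r in records
        }
        assert set(web.edges()) == expected_pairs
        fine_web = build_web(records, require_metric=False)
        assert web.n_edges <= fine_web.n_edges

    def test_unmapped_fine_group_is_configuration_error(self):
        with pytest.raises(KeyError, match="missing from coarse mapping"):
            coarsen([make_record("R0", prey="krill")], {"krill": "zooplankton"})


class TestExports:
    def test_edgelist_csv_and_graphml(self, tmp_path, rng):
        web = build_web(random_records(rng, n=30), require_metric=False)
        csv_path = web.write_edgelist_csv(tmp_path / "web.csv")
        assert csv_path.read_text().startswith("prey,predator,weight_occurrence")
        import networkx as nx

        graphml_path = web.write_graphml(tmp_path / "web.graphml")
        loaded = nx.read_graphml(graphml_path)
        assert loaded.number_of_edges() == web.n_edges
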