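"""Shared fixtures: record factories and random toy-web generators.

All randomness is seeded; hypothesis runs derandomized so the suite is
reproducible in any environment.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dietwebs.records import DietRecord
from dietwebs.webs import FoodWeb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    record_id: str,
    prey: str = "Euphausia superba",
    predator: str = "Pygoscelis antarcticus",
    occ: float | None = 0.5,
    diet: float | None = None,
    lat: float = -60.0,
    lon: float = 0.0,
    month: int | None = 1,
    source: str = "S1",
    method: str = "stomach",
) -> DietRecord:
    return DietRecord(
        record_id=record_id,
        source_id=source,
        predator_name=predator,
        prey_name=prey,
        latitude=lat,
        longitude=lon,
        month=month,
        fraction_occurrence=occ,
        fraction_diet_weight=diet,
        method=method,
    )


def random_records(rng: np.random.Generator, n: int = 50) -> list[DietRecord]:
    """Valid records with random pairs, metrics (some missing), and months."""
    prey_pool = ["krill", "copepods", "myctophids", "squid", "amphipods"]
    predator_pool = ["penguin", "seal", "whale", "albatross"]
    records = []
    for i in range(n):
        occ = float(rng.random()) if rng.random() > 0.2 else None
        diet = float(rng.random()) if rng.random() > 0.4 else None
        records.append(
            DietRecord(
                record_id=f"R{i:04d}",
                source_id=f"S{int(rng.integers(0, 8)):02d}",
                predator_name=str(rng.choice(predator_pool)),
                prey_name=str(rng.choice(prey_pool)),
                latitude=float(rng.uniform(-78, -41)),
                longitude=float(rng.uniform(-180, 180)),
                month=int(rng.choice([11, 12, 1, 2, 3])),
                fraction_occurrence=occ,
                fraction_diet_weight=diet,
                method="stomach",
            )
        )
    return records


def random_toy_web(rng: np.random.Generator, max_nodes: int = 10) -> FoodWeb:
    """A random weighted directed web with up to ``max_nodes`` nodes.

    Self-loops allowed; some weights missing, mirroring partial reporting.
    """
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"g{i}" for i in range(n)]
    web = FoodWeb()
    for prey in nodes:
        for predator in nodes:
            if rng.random() < 0.3:
                occ = float(rng.random()) if rng.random() > 0.15 else None
                diet = float(rng.random()) if rng.random() > 0.3 else None
                web.graph.add_edge(
                    prey,
                    predator,
                    weight_occurrence=occ,
                    weight_diet=diet,
                    n_records=int(rng.integers(1, 6)),
                )
    if web.n_edges == 0:
        web.graph.add_edge(
            nodes[0], nodes[1], weight_occurrence=0.5, weight_diet=0.5, n_records=1
        )
    return web


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201209)
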