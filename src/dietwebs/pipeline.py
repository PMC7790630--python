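"""End-to-end orchestration: records → refinement → sectors → webs → stats.

:func:`run_pipeline` is the programmatic entry point that the examples
scripts wrap. Given a :class:`PipelineConfig` it runs every stage for each
sector and for the pooled dataset, writes all tabular artifacts under the
output directory, and returns the in-memory results. Outputs are
deterministic: tables are sorted on stable keys before writing, all
randomness flows from the configured seed, and the run log records a config
hash plus per-stage record counts so two runs can be diffed byte for byte.

Artifacts per region (four sectors + ``southern_ocean`` pooled):

* ``<region>_records.csv`` — refined, taxon-mapped records
* ``<region>_fine_web.csv`` / ``.graphml`` — fine-group web edge list
* ``<region>_coarse_web.csv`` — functional-group web edge list
* ``<region>_strengths.csv`` — mid-trophic out-degree strength table
* ``<region>_accumulation.csv`` — accumulation curve + fit

plus dataset-wide ``summary.csv`` (S, L, C, LD, observation and interaction
counts per region), ``rejections.csv``, ``refinement_report.csv``,
``unmapped_taxa.csv``, and ``run_log.json``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from dietwebs.metrics import network_summary, strength_table
from dietwebs.records import DietRecord, read_records, write_records
from dietwebs.refinement import RefinementConfig, apply_refinement
from dietwebs.sampling_bias import accumulation_curve, fit_negative_exponential
from dietwebs.sectors import SOUTHERN_OCEAN_SECTORS, SectorScheme, split_by_sector
from dietwebs.webs import GroupScheme, build_web, coarsen, map_taxa

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

POOLED = "southern_ocean"


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Inputs may be given in memory (``records``/``fine_scheme``/...) or as
    paths (``records_path``/``fine_scheme_path``); in-memory objects win.
    ``coarse_mapping`` maps fine group → coarse functional group.
    """

    output_dir: str | Path
    records: Sequence[DietRecord] | None = None
    records_path: str | Path | None = None
    fine_scheme: GroupScheme | None = None
    fine_scheme_path: str | Path | None = None
    coarse_mapping: Mapping[str, str] | None = None
    sector_scheme: SectorScheme = SOUTHERN_OCEAN_SECTORS
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    require_occurrence: bool = True
    percent_mode: bool = False
    n_perm: int = 200
    seed: int = 0

    def resolve_records(self) -> tuple[list[DietRecord], list]:
        if self.records is not None:
            return list(self.records), []
        if self.records_path is None:
            raise ValueError("config supplies neither records nor records_path")
        result = read_records(self.records_path, percent_mode=self.percent_mode)
        return result.records, result.rejections

    def resolve_scheme(self) -> GroupScheme:
        if self.fine_scheme is not None:
            return self.fine_scheme
        if self.fine_scheme_path is None:
            raise ValueError("config supplies neither fine_scheme nor fine_scheme_path")
        return GroupScheme.from_csv(self.fine_scheme_path)

    def content_hash(self) -> str:
        """Stable hash of the run-defining configuration."""
        scheme = self.resolve_scheme()
        payload = {
            "refinement": {
                "retained_months": sorted(self.refinement.retained_months),
                "latitude_max": self.refinement.latitude_max,
                "excluded_taxa": sorted(self.refinement.excluded_taxa),
                "excluded_records": sorted(self.refinement.excluded_records),
                "drop_missing_month": self.refinement.drop_missing_month,
            },
            "sectors": [(s.name, s.west, s.east) for s in self.sector_scheme],
            "mapping": sorted(scheme.mapping.items()),
            "coarse_mapping": sorted((self.coarse_mapping or {}).items()),
            "require_occurrence": self.require_occurrence,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    """In-memory results of a run, keyed by region name."""

    webs: dict
    coarse_webs: dict
    summaries: pd.DataFrame
    strengths: dict
    accumulations: dict
    run_log: dict
    output_dir: Path


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorator


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write all artifacts to ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, rejections = _stage("read")(config.resolve_records)()
    scheme = config.resolve_scheme()

    refined, refinement_report = _stage("refinement")(apply_refinement)(
        records, config.refinement
    )
    grouped, unmapped = _stage("taxon mapping")(map_taxa)(refined, scheme)
    by_sector = _stage("sector split")(split_by_sector)(grouped, config.sector_scheme)

    regions: dict[str, list[DietRecord]] = dict(by_sector)
    regions[POOLED] = grouped

    webs, coarse_webs, strengths, accumulations = {}, {}, {}, {}
    summary_rows = []
    stage_counts = {
        "input": len(records),
        "rejected_rows": len(rejections),
        "refined": len(refined),
        "grouped": len(grouped),
        "unmapped": len(unmapped),
        "per_sector": {name: len(recs) for name, recs in by_sector.items()},
    }

    for region, region_records in regions.items():
        slug = region.replace(" ", "_").lower()
        write_records(
            sorted(region_records, key=lambda r: r.record_id),
            out / f"{slug}_records.csv",
        )

        if not region_records:
            summary_rows.append(
                {
                    "region": region, "n_observations": 0, "S": 0, "L": 0,
                    "C": float("nan"), "LD": float("nan"), "flag": "no data",
                }
            )
            continue

        web = _stage("fine web")(build_web)(
            region_records, metric="occurrence", require_metric=config.require_occurrence
        )
        webs[region] = web
        web.write_edgelist_csv(out / f"{slug}_fine_web.csv")
        web.write_graphml(out / f"{slug}_fine_web.graphml")

        if config.coarse_mapping:
            cweb = _stage("coarse web")(coarsen)(region_records, config.coarse_mapping)
            coarse_webs[region] = cweb
            cweb.write_edgelist_csv(out / f"{slug}_coarse_web.csv")

        if web.n_nodes:
            summary = network_summary(web)
            summary_rows.append(
                {
                    "region": region,
                    "n_observations": len(region_records),
                    "S": summary.S,
                    "L": summary.L,
                    "C": summary.C,
                    "LD": summary.LD,
                    "flag": "",
                }
            )
        else:
            summary_rows.append(
                {
                    "region": region, "n_observations": len(region_records),
                    "S": 0, "L": 0, "C": float("nan"), "LD": float("nan"),
                    "flag": "no data",
                }
            )
            continue

        table = _stage("strengths")(strength_table)(web, scheme)
        strengths[region] = table
        table.to_csv(out / f"{slug}_strengths.csv", index=False)

        acc = _stage("accumulation")(accumulation_curve)(
            region_records, n_perm=config.n_perm, seed=config.seed
        )
        if acc.x.size >= 3:
            acc.fit = fit_negative_exponential(acc.x, acc.mean_count)
        accumulations[region] = acc
        acc.to_csv(out / f"{slug}_accumulation.csv")

    summaries = pd.DataFrame(summary_rows).sort_values("region").reset_index(drop=True)
    summaries.to_csv(out / "summary.csv", index=False)

    pd.DataFrame(
        [(r.row_number, r.record_id, r.reason) for r in rejections],
        columns=["row_number", "record_id", "reason"],
    ).to_csv(out / "rejections.csv", index=False)
    refinement_report.to_csv(out / "refinement_report.csv")
    pd.DataFrame(unmapped, columns=["record_id", "taxon"]).to_csv(
        out / "unmapped_taxa.csv", index=False
    )

    run_log = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_perm": config.n_perm,
        "counts": stage_counts,
        "refinement_drops": refinement_report.drops,
    }
    (out / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True), encoding="utf-8"
    )

    return PipelineResult(
        webs=webs,
        coarse_webs=coarse_webs,
        summaries=summaries,
        strengths=strengths,
        accumulations=accumulations,
        run_log=run_log,
        output_dir=out,
    )
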