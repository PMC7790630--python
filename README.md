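# dietwebs

Build and compare regional food webs from predator-diet observation
records.

Collated diet databases — thousands of stomach-content and scat analyses
from hundreds of studies — are the most direct field evidence for who eats
whom in a marine ecosystem. `dietwebs` turns such records into
**sector-specific, cumulative, weighted directed food webs** and the
statistics ecologists use to compare them. It was built with the Southern
Ocean in mind (four longitude sectors south of 40°S, austral-summer
records, a krill-versus-fish mid-trophic contrast between basins), but
every scheme — months, latitude ceiling, sector bounds, taxon groupings —
is configuration.

The pipeline:

1. **records** — read/validate/write a canonical CSV of diet records, each
   carrying the two classical diet metrics: *fraction of occurrence* (share
   of stomachs containing the prey) and *fraction of diet by weight*
   (gravimetric share of stomach contents).
2. **refinement** — summer-only, south-of-40°S-only, and taxon-quality
   filters with a per-record audit report.
3. **sectors** — assign records to half-open longitude sectors (default:
   Atlantic 55°W–55°E, Indian 55°E–145°E, West Pacific 145°E–115°W with
   dateline wraparound, East Pacific 115°W–55°W).
4. **webs** — aggregate taxa into trophic groups and build webs with edges
   prey → predator, weighted by the mean of a diet metric over contributing
   records; coarsen ~50 fine groups into ~15 broad functional groups by
   re-averaging pooled records.
5. **metrics** — for a web with S groups and L links: connectance
   C = L/S² (self-links count as possible), link density LD = L/S, and
   per-group weighted out-degree strength
   s(g) = Σ_{g → predator} w(g, predator) — the total weighted predation
   pressure on prey group g.
6. **sampling_bias** — source-randomized species accumulation curves with
   an exact hypergeometric expectation
   E[count at x] = Σ_g [1 − C(n−n_g, x)/C(n, x)] and a negative-exponential
   summary fit S(x) = S_max(1 − e^(−kx)).
7. **synthetic** — a seeded generator that emulates how such databases
   arise (studies → stomachs → occurrence fractions → Dirichlet weight
   splits → per-metric missingness), so the whole pipeline is testable
   without external data.

## Worked example

`examples/strength_rankings.py` simulates two contrasting single-sector
worlds and ranks mid-trophic groups by out-degree strength:

```
krill-dominated world — mid-trophic out-degree strengths
            group  out_degree  out_strength_occurrence  out_strength_diet
     krill-analog           5                 4.181267           1.845191
silverfish-analog           5                 1.616095           0.521769
 myctophid-analog           5                 1.351152           0.816169
  amphipod-analog           5                 0.979068           0.460177
   copepod-analog           5                 0.695529           0.642773

fish-dominated world — mid-trophic out-degree strengths
            group  out_degree  out_strength_occurrence  out_strength_diet
silverfish-analog           5                 4.157336           2.782172
 myctophid-analog           5                 1.487109           1.098165
  amphipod-analog           5                 1.289749           0.494085
   copepod-analog           5                 0.929600           0.591958
     krill-analog           5                 0.315784           0.091803
```

Every group is eaten by all 5 predator groups (out_degree 5), but the
*strengths* separate the worlds: the krill analog, configured to occur in
~80% of stomachs of every predator, accumulates strength ≈ 4.2 of a
possible 5.0 and tops both metrics; in the fish-dominated world the
silverfish analog takes that role and the rare krill analog drops to ≈ 0.3.
This is the regional contrast the pipeline is designed to expose from raw
records.

Other examples: `simulate_and_refine.py` (record I/O and filter audit),
`build_sector_webs.py` (per-sector S/L/C/LD), `coarse_functional_webs.py`
(functional-group aggregation with missing-weight edges),
`accumulation_diagnostics.py` (Monte-Carlo curve vs exact expectation plus
fit), `full_pipeline.py` (one call, full artifact bundle, byte-identical
re-runs).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch: it simulates the two-sector
synthetic world from the given seed, runs refinement, taxon mapping,
sector splitting, fine and coarse web construction, network metrics,
strength tables, and accumulation diagnostics, and writes the results
summary JSON to `--out`.

## External validation data

One test (`tests/test_acceptance.py::test_table1_reproduction_from_scar_snapshot`)
validates the pipeline against the published per-sector summaries of the
circumpolar diet database snapshot it was designed around. That database
is not redistributable here; to run the check, export it to the canonical
record CSV as `data/external/scar_diet_snapshot.csv` and supply the
~50-group taxon mapping as `data/external/fine_group_scheme.csv`
(columns `taxon,group,class,mid_trophic`). Without those files the test
fails with instructions — by design, since the comparison cannot be made
from synthetic data.
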