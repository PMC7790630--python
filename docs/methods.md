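# Methods

This note records the models, conventions, and numerical choices behind
`dietwebs`, and what its synthetic tests do and do not establish.

## Data model and conventions

A diet record is one predator–prey dietary observation from one source
study, with a location, an optional month, and up to two diet metrics.
*Fraction of occurrence* is the share of examined stomachs/scats containing
the prey at least once; *fraction of diet by weight* is the gravimetric
share of stomach contents. Both are stored as proportions in [0, 1];
percentage-scaled files are converted once, at read time. When
`percent_mode` is set, **all** metric values in the file are divided by
100 (validated to lie in [0, 100]); dividing only values above 1 would
silently mix scales for genuine sub-1% entries, so the flag applies
file-wide.

Longitudes use a single convention, degrees east in [-180, 180), applied
idempotently at read time. Sector intervals are half-open [west, east)
proceeding eastward, so a record exactly on a boundary meridian belongs to
the sector east of it; the choice is arbitrary but consistent, and any
consistent convention preserves the partition property (every record in
exactly one sector). A sector whose western bound exceeds its eastern bound
wraps across the dateline (the default West Pacific sector,
145°E–115°W).

## Refinement

Three independent predicates restrict the dataset: months (default
November–March, the austral summer; i.e. April–October excluded), latitude
(default ≤ −40°), and taxon quality (an explicit exclusion list for
nonliving items and names too coarse to place, e.g. "Fish", dropped
together with their links). Records with no collection month are dropped by
default: their season cannot be certified, and a summer-only web should not
contain records that might be winter ones. The policy is configurable
(`drop_missing_month=False`) for sensitivity analyses.

Geographic and taxonomic judgments that cannot be computed from a record
alone (coastal samples to exclude, out-of-range prey taxa) are externalized
to explicit configuration lists (`excluded_records`, `excluded_taxa`).
This makes an inherently manual curation step reproducible: the judgment
lives in a versionable config file, not in code.

Because the filters are pure predicates, they commute; the audit report
nevertheless attributes each dropped record to the *first* violated rule in
the fixed order season → region → taxa, so that
`n_input = n_retained + Σ drops` holds exactly.

## Web construction

Webs are *cumulative*: they pool interactions over space and time within a
region and record that two groups can interact, not instantaneous fluxes.
Edges run prey → predator. For each distinct (prey group, predator group)
pair, the edge weight under a metric is the **unweighted arithmetic mean of
that metric over the contributing records that report it** — not
study-level means averaged, not sample-size-weighted. With heterogeneous
and partially reported study sizes, the record-level mean is the simplest
estimator that uses every datum once; alternatives can be layered on top of
the edge lists, which also carry per-edge record counts.

For occurrence-weighted sector webs, pairs with no occurrence value at all
are omitted (`require_metric=True`): an edge that cannot be weighted cannot
participate in a weighted analysis. For the coarse functional-group webs
the opposite choice is made (`require_metric=False`): the interaction is
real even when no gravimetric datum exists, so the edge is kept with a
missing weight (rendered dashed in diagrams). Coarse-web weights are
recomputed from the pooled records rather than by averaging fine-edge
means — averaging data, not averages — so a coarse edge backed by 20
records in one fine pair and 2 in another is not distorted by the sparse
pair.

Self-loops (a group preying on itself, e.g. cephalopods on cephalopods)
are ordinary edges. This is consistent with the connectance denominator:
C = L/S² counts all S² directed pairs, self-pairs included. S counts
groups participating in at least one retained edge; isolated groups are
absent by construction, and no per-sector S is forced to reconcile
externally reported C and LD values (which need not be mutually consistent
after rounding).

Taxon-to-group mappings are shipped as configuration tables
(`taxon,group,class,mid_trophic` CSV), never hard-coded: group membership
is a curatorial product, not a computation.

## Network statistics

Out-degree of a group = number of predator groups consuming it; out-degree
strength = sum of outgoing edge weights under a metric, so
0 ≤ strength ≤ out-degree. Edges missing the metric contribute zero to the
strength and are tallied separately (`n_missing_*` columns), so a low
strength from poor data coverage is distinguishable from a low strength
from weak interactions. Strength tables cover the mid-trophic groups
(zooplankton through demersal fish — the groups that channel energy from
producers to top predators), sorted by descending strength with
alphabetical tie-break for determinism.

## Accumulation curves

The sampling unit is the source study: databases grow study-by-study, so
the operative question is the marginal prey-group coverage of one more
study. Sampling is without replacement within a permutation (classical
sample-based accumulation), which gives the exact expectation

    E[count at x] = Σ_g [1 − C(n − n_g, x) / C(n, x)],

the bracket being the hypergeometric probability that at least one of the
n_g sources containing group g falls in a random x-subset of the n
sources. This closed form is implemented independently of the Monte-Carlo
estimator and serves as its oracle in tests.

The mean curve (not per-permutation curves) is summarized by least squares
with S(x) = S_max(1 − e^(−kx)); S_max estimates reachable richness, k the
per-source saturation rate. The exact parameterization of "a negative
exponential" varies across the accumulation-curve literature; this form is
the common two-parameter choice and is documented here rather than asserted
as canonical. Initialization is fixed (S_max₀ = max observed count,
k₀ = 1) so the fit is deterministic. Degenerate inputs are flagged, not
raised: a flat curve (every source sees the same groups) drives k → ∞ and
is returned as a boundary fit with S_max at the constant level; optimizer
failure returns the initial-guess parameters with `converged=False` and the
optimizer's message.

## Synthetic generator

The generator emulates the data-generating process of a collated diet
database, not an ecosystem. Each source study examines one predator and n
stomachs (default 20–60, a typical seabird/seal diet-study size); each
prey occurs in each stomach independently with configured probability p,
and the emitted occurrence fraction is the count/n estimator — simulated at
stomach level precisely so it carries the estimator's true binomial noise
(variance p(1−p)/n), which matters for effort and power experiments. Diet
weights are a Dirichlet split over the prey that occurred, with
concentration proportional to the occurrence probabilities (default total
concentration 10), so frequent prey also tend to dominate by mass without
the two metrics being deterministically linked. Missingness is independent
per metric (defaults: 5% for occurrence, 30% for diet weight — occurrence
is near-universally reported in diet studies while gravimetric analysis
often is not). Records are only emitted for pairs with ≥1 occurrence, since
absence is unobservable in stomach contents.

Two stated worlds encode the krill-versus-fish regional contrast: a
krill-dominated world (krill analog at p = 0.8 for every one of 5
predators; other prey at 0.15–0.3) and a fish-dominated world (silverfish
analog at 0.85, krill analog at 0.05). Ten sources per world. These values
were chosen once to give a clear but noise-exposed separation (per-edge
estimates still fluctuate with binomial and Dirichlet noise) and are not
tuned against test outcomes.

What a green synthetic test establishes: the pipeline's estimators recover
the configured structure (edge weights are consistent estimators of p,
dominant groups rank first, curves match their closed form). What it does
not: anything about real taxonomy, spatial clustering of sampling,
correlated missingness, study-size heterogeneity beyond the configured
range, or mis-reported taxa — real-database pathologies the refinement and
mapping stages mitigate but the generator does not model.

## Pipeline determinism

All tables are sorted on stable keys before writing; all randomness flows
from one configured seed; the run log records a SHA-256 hash of the
run-defining configuration plus per-stage record counts. Two runs with the
same config and inputs produce byte-identical artifacts (tested).

## Known limitations

- Edge weights ignore study sample sizes; a 5-stomach and a 500-stomach
  study count equally in the mean. The per-edge `n_records` column enables
  reweighting downstream, but no alternative estimator is built in.
- Empty regions yield "no data" summary rows; webs, strengths, and curves
  are only produced for populated regions.
- The accumulation fit is on the mean curve; no uncertainty is propagated
  from the permutation spread into (S_max, k).
- The external-validation path expects the real database already exported
  to the canonical record schema; no native-schema importer is included
  beyond a thin column-mapping hook in `read_records`.
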