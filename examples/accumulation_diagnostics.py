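"""Quantify sampling effort with a source-randomized accumulation curve.

How many distinct prey groups do the first x source studies reveal, on
average over random study orderings? A curve still climbing at x = n says
more studies would keep uncovering diet breadth; a flat tail says coverage
is saturated. The Monte-Carlo estimate is checked against the exact
hypergeometric expectation, and the mean curve is summarized by a
negative-exponential fit S(x) = S_max(1 - e^(-kx)).
"""

import numpy as np

from dietwebs import (
    accumulation_curve,
    accumulation_expectation,
    fit_negative_exponential,
)
from dietwebs.records import DietRecord

# a small heterogeneous world: 8 studies, each seeing a subset of 12 groups
rng = np.random.default_rng(5)
records = []
for s in range(8):
    groups = rng.choice([f"prey-{g}" for g in range(12)],
                        size=rng.integers(2, 7), replace=False)
    for i, g in enumerate(groups):
        records.append(DietRecord(
            record_id=f"S{s}-{i}", source_id=f"S{s}",
            predator_name="predator", prey_name=str(g),
            latitude=-60.0, longitude=0.0, month=1, fraction_occurrence=0.5,
        ))

curve = accumulation_curve(records, n_perm=1000, seed=5)
exact = accumulation_expectation(records)
print("x  mean(MC)  exact    SE")
for x, mc, ex, se in zip(curve.x, curve.mean_count, exact, curve.standard_error()):
    print(f"{x}  {mc:7.3f}  {ex:6.3f}  {se:.4f}")

fit = fit_negative_exponential(curve.x, curve.mean_count)
print(f"\nfit: S_max={fit.s_max:.2f}, k={fit.k:.3f}, rss={fit.rss:.4f}, "
      f"converged={fit.converged}")
print(f"observed groups: {curve.mean_count[-1]:.0f}; the asymptote estimates "
      "the richness further studies would approach.")
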