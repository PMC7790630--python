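"""Sampling-effort diagnostics: species accumulation curves and their fit.

The sampling unit is the *source study*, not the individual record: a
collated diet database grows by studies, so the natural question is how many
additional prey groups another study would reveal. The curve is built by
randomly permuting the distinct sources, accumulating the union of their
prey-group sets, and averaging the cumulative distinct-group count over
permutations (classical sample-based accumulation, without replacement).

Because sampling is without replacement, the expected curve has an exact
hypergeometric closed form,

    E[count at x] = Σ_g [ 1 − C(n − n_g, x) / C(n, x) ],

where ``n`` is the number of sources and ``n_g`` the number containing
group ``g`` (the bracket is the probability group ``g`` appears in a random
x-subset of sources). :func:`accumulation_expectation` computes this and
serves as the analytical oracle for the Monte-Carlo estimator.

The mean curve is summarized by least squares with the negative exponential

    S(x) = S_max · (1 − e^(−k·x)),

whose asymptote ``S_max`` estimates the prey-group richness reachable with
unbounded effort and whose rate ``k`` measures how fast each additional
source closes the gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import comb

from dietwebs.records import DietRecord

__all__ = [
    "AccumulationResult",
    "FitResult",
    "accumulation_curve",
    "accumulation_expectation",
    "fit_negative_exponential",
]


@dataclass(frozen=True)
class FitResult:
    """Fitted negative-exponential parameters with diagnostics.

    ``converged`` is False when the optimizer failed or hit a degenerate
    (flat-curve) boundary; ``message`` says why. Parameters are still the
    best available estimate in either case, never silently absent.
    """

    s_max: float
    k: float
    rss: float
    converged: bool
    message: str = ""


@dataclass
class AccumulationResult:
    """Mean cumulative prey-group count versus number of sources sampled.

    ``x[i]`` sources yield on average ``mean_count[i]`` distinct prey
    groups; ``sd_count`` is the across-permutation standard deviation
    (zero at ``x = n``, where every ordering has seen everything).
    """

    x: np.ndarray
    mean_count: np.ndarray
    sd_count: np.ndarray
    n_perm: int
    seed: int | None
    fit: FitResult | None = None

    @property
    def n_sources(self) -> int:
        return int(self.x[-1])

    def standard_error(self) -> np.ndarray:
        """Monte-Carlo standard error of ``mean_count`` at each x."""
        return self.sd_count / math.sqrt(self.n_perm)

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"n_sources": self.x, "mean_count": self.mean_count, "sd_count": self.sd_count}
        )
        frame.attrs["n_perm"] = self.n_perm
        frame.attrs["seed"] = self.seed
        return frame

    def to_csv(self, path) -> None:
        """Curve as CSV; n_perm, seed, and any fit recorded in '#' header lines."""
        lines = [f"# n_perm={self.n_perm}", f"# seed={self.seed}"]
        if self.fit is not None:
            lines.append(
                f"# fit_s_max={self.fit.s_max!r} fit_k={self.fit.k!r} "
                f"rss={self.fit.rss!r} converged={self.fit.converged}"
            )
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("\n".join(lines) + "\n")
            self.to_dataframe().to_csv(handle, index=False)


def _sources_to_groups(records) -> dict[str, frozenset[str]]:
    by_source: dict[str, set[str]] = {}
    for record in records:
        by_source.setdefault(record.source_id, set()).add(record.prey_name)
    return {s: frozenset(g) for s, g in by_source.items()}


def accumulation_curve(
    records, n_perm: int = 1000, seed: int | None = None
) -> AccumulationResult:
    """Source-randomized accumulation curve over grouped diet records.

    For each of ``n_perm`` random orderings of the distinct sources, the
    cumulative number of distinct prey groups is recorded after each source;
    the mean and standard deviation over orderings are reported per x.
    Deterministic given ``seed``. ``mean_count`` is non-decreasing and is
    exactly the total distinct prey-group count at ``x = n`` regardless of
    seed.

    Raises ``ValueError`` if the records contain no sources.
    """
    groups_by_source = _sources_to_groups(records)
    sources = sorted(groups_by_source)
    n = len(sources)
    if n == 0:
        raise ValueError("no sources in records; accumulation undefined")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    rng = np.random.default_rng(seed)
    counts = np.empty((n_perm, n), dtype=np.int64)
    for p in range(n_perm):
        order = rng.permutation(n)
        seen: set[str] = set()
        for i, idx in enumerate(order):
            seen |= groups_by_source[sources[idx]]
            counts[p, i] = len(seen)

    return AccumulationResult(
        x=np.arange(1, n + 1),
        mean_count=counts.mean(axis=0),
        sd_count=counts.std(axis=0, ddof=0),
        n_perm=n_perm,
        seed=seed,
    )


def accumulation_expectation(records) -> np.ndarray:
    """Exact expected accumulation curve (hypergeometric closed form).

    Returns ``E[count]`` at ``x = 1..n``; agrees with the mean of
    :func:`accumulation_curve` over all ``n!`` orderings, making it the
    permutation-free oracle for the Monte-Carlo estimator.
    """
    groups_by_source = _sources_to_groups(records)
    n = len(groups_by_source)
    if n == 0:
        raise ValueError("no sources in records; accumulation undefined")

    presence: dict[str, int] = {}
    for groups in groups_by_source.values():
        for g in groups:
            presence[g] = presence.get(g, 0) + 1

    x = np.arange(1, n + 1)
    expected = np.zeros(n, dtype=float)
    for n_g in presence.values():
        # P(group absent from a random x-subset) = C(n - n_g, x) / C(n, x)
        absent = comb(n - n_g, x) / comb(n, x)
        expected += 1.0 - absent
    return expected


def _model(x: np.ndarray, s_max: float, k: float) -> np.ndarray:
    return s_max * (1.0 - np.exp(-k * x))


def fit_negative_exponential(
    x: np.ndarray, y: np.ndarray
) -> FitResult:
    """Least-squares fit of ``S(x) = S_max (1 − e^(−kx))`` to a curve.

    Initialization is fixed and documented — ``S_max₀ = max(y)``, ``k₀ = 1``
    — so the fit is deterministic. A flat curve (zero variance) drives
    ``k → ∞``; it is detected up front and returned as a flagged boundary
    fit with ``s_max`` equal to the constant level. Optimizer failure
    yields a flagged result carrying the initial-guess parameters, never an
    exception.

    Requires at least 3 points (two parameters plus one residual).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 curve points to fit 2 parameters")

    if np.allclose(y, y[0], rtol=0.0, atol=1e-12):
        level = float(y[0])
        rss = float(np.sum((y - level) ** 2))
        return FitResult(
            s_max=level,
            k=float("inf"),
            rss=rss,
            converged=False,
            message="flat curve: boundary fit, k unbounded",
        )

    p0 = (float(np.max(y)), 1.0)
    try:
        popt, _ = curve_fit(_model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        rss = float(np.sum((y - _model(x, *p0)) ** 2))
        return FitResult(
            s_max=p0[0], k=p0[1], rss=rss, converged=False, message=str(exc)
        )
    s_max, k = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - _model(x, s_max, k)) ** 2))
    return FitResult(s_max=s_max, k=k, rss=rss, converged=True)
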