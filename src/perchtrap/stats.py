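"""Evaluation statistics for the trap's field validation, implemented from
first principles: one-sided Fisher's exact test by hypergeometric
enumeration, a Monte-Carlo chi-square goodness-of-fit against a 50:50
split, Holm's step-down adjustment, the event-level sensitivity summary,
and the battery-drain power estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

__all__ = [
    "CountTable2x2",
    "PairCounts",
    "BatterySpec",
    "fisher_exact_one_sided",
    "mc_goodness_of_fit",
    "holm_adjust",
    "sensitivity_summary",
    "power_estimate",
]


@dataclass(frozen=True)
class CountTable2x2:
    """2x2 count table [[a, b], [c, d]]; rows = sites, columns = outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class PairCounts:
    """Detection counts at two sites, tested against an even split."""

    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0 or self.n1 + self.n2 < 1:
            raise ValueError("counts must be non-negative with n1 + n2 >= 1")


@dataclass(frozen=True)
class BatterySpec:
    n_cells: int
    volts_per_cell: float
    capacity_mAh: float
    days_lasted: float

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.volts_per_cell <= 0 or self.capacity_mAh < 0:
            raise ValueError("cells and voltage must be positive, capacity non-negative")
        if self.days_lasted <= 0:
            raise ValueError("days_lasted must be positive")


def fisher_exact_one_sided(table: CountTable2x2, direction: str = "greater") -> float:
    """One-sided Fisher's exact p by enumeration of all tables with the
    observed margins.

    Conditional on the margins, the top-left cell A follows a
    hypergeometric law.  ``direction='greater'`` returns P(A >= a)
    (association in the direction of a larger top-left cell),
    ``'less'`` returns P(A <= a).
    """
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    r1 = table.a + table.b
    r2 = table.c + table.d
    c1 = table.a + table.c
    n = table.total
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("Fisher's exact test requires all margins to be positive")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    denom = comb(n, c1)
    if direction == "greater":
        support = range(table.a, hi + 1)
    else:
        support = range(lo, table.a + 1)
    return sum(comb(r1, k) * comb(r2, c1 - k) for k in support) / denom


def mc_goodness_of_fit(
    pair: PairCounts,
    n_reps: int = 1_000_000,
    seed: int = 0,
    chunk: int = 200_000,
) -> float:
    """Monte-Carlo chi-square goodness-of-fit p-value for an even split.

    The observed statistic is the chi-square of (n1, n2) against expected
    (n/2, n/2); the null distribution is simulated by drawing replicate
    counts Binomial(n, 0.5).  The estimator is (m + 1) / (B + 1) where m
    counts replicate statistics >= observed — never exactly zero, matching
    standard simulated-p-value practice.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = pair.n1 + pair.n2
    e = n / 2.0
    rng = np.random.default_rng(seed)
    hits = 0
    left = n_reps
    # the replicate statistic 2*(X - n/2)^2 / (n/2) is monotone in |X - n/2|,
    # so compare deviations; small slack keeps exact ties counted
    dev_obs = abs(pair.n1 - e) - 1e-9
    while left > 0:
        m = min(chunk, left)
        x = rng.binomial(n, 0.5, size=m)
        hits += int(np.count_nonzero(np.abs(x - e) >= dev_obs))
        left -= m
    return (hits + 1) / (n_reps + 1)


def binomial_gof_exact(pair: PairCounts) -> float:
    """Exact P(chi-square stat >= observed) under Binomial(n, 0.5), by full
    enumeration of the binomial support.  Reference oracle for
    :func:`mc_goodness_of_fit` (no +1 smoothing)."""
    n = pair.n1 + pair.n2
    e = n / 2.0
    dev_obs = abs(pair.n1 - e)
    total = 0.0
    for k in range(n + 1):
        if abs(k - e) >= dev_obs - 1e-12:
            total += comb(n, k)
    return total / 2.0**n


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm's step-down family-wise adjustment, returned in input order.

    Sort ascending; the i-th smallest becomes max over j <= i of
    (m - j + 1) * p_(j), capped at 1.
    """
    ps = list(p_values)
    if any(not (0 <= p <= 1) for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def sensitivity_summary(tp: int, fn: int) -> float:
    """Event-level detection sensitivity TP / (TP + FN).

    Raises :class:`ValueError` when TP + FN = 0 (no perching events: the
    sensitivity is undefined, as at a site where nothing ever perched).
    """
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no perching events (TP + FN = 0)")
    return tp / (tp + fn)


def power_estimate(spec: BatterySpec) -> float:
    """Average power draw in mW implied by a battery pack lasting a period:
    n_cells * V * mAh / (days * 24 h)."""
    return spec.n_cells * spec.volts_per_cell * spec.capacity_mAh / (spec.days_lasted * 24.0)
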