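"""Candidate cost functions and interval sets for functional pruning.

Functional pruning (FPOP, pDPA) stores, for each candidate last changepoint
tau, the function ``mu -> Cost_tau(mu)`` in closed coefficient form together
with the set of mu values where that candidate currently achieves the
pointwise minimum ``Cost*(mu)``.  A candidate is pruned the moment its set
becomes empty: no future data can revive it because every candidate gains
the same ``gamma(y_t, mu)`` each step.

Intervals are closed, with ``+-inf`` sentinels; ties at shared boundaries
belong to the candidate with smaller tau (a measure-zero convention that
cannot change any minimum but makes output deterministic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "IntervalSet",
    "CandidateCost",
    "GaussianCandidate",
    "PoissonCandidate",
    "intersect",
    "complement_of_union",
]


# ---------------------------------------------------------------------------
# Interval sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalSet:
    """A union of disjoint closed intervals ``[lo, hi]`` inside a domain.

    The empty set is represented by an empty interval list.  ``lo`` may be
    ``-inf`` and ``hi`` may be ``+inf``.
    """

    intervals: tuple[tuple[float, float], ...]

    @classmethod
    def from_pairs(cls, pairs) -> "IntervalSet":
        cleaned = []
        for lo, hi in pairs:
            if hi < lo:
                raise ValueError(f"interval [{lo}, {hi}] has hi < lo")
            cleaned.append((float(lo), float(hi)))
        cleaned.sort()
        for (a, b), (c, _) in zip(cleaned, cleaned[1:]):
            if c <= b:
                raise ValueError("intervals must be pairwise disjoint")
        return cls(tuple(cleaned))

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(())

    @classmethod
    def full(cls, domain=( -math.inf, math.inf)) -> "IntervalSet":
        return cls(((float(domain[0]), float(domain[1])),))

    @property
    def is_empty(self) -> bool:
        return not self.intervals

    def contains(self, mu: float) -> bool:
        return any(lo <= mu <= hi for lo, hi in self.intervals)

    def measure(self) -> float:
        return sum(hi - lo for lo, hi in self.intervals)


def _intersect_pairs(a: Sequence[tuple[float, float]],
                     b: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Intersection of two sorted disjoint interval lists (two-pointer sweep)."""
    out: list[tuple[float, float]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Exact intersection of two interval sets."""
    return IntervalSet(tuple(_intersect_pairs(a.intervals, b.intervals)))


def _complement_pairs(pairs: Sequence[tuple[float, float]],
                      domain: tuple[float, float]) -> list[tuple[float, float]]:
    """``domain`` minus the union of ``pairs`` (pairs need not be disjoint)."""
    lo_d, hi_d = float(domain[0]), float(domain[1])
    merged: list[list[float]] = []
    for lo, hi in sorted(pairs):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    out: list[tuple[float, float]] = []
    cursor = lo_d
    for lo, hi in merged:
        if hi < lo_d or lo > hi_d:
            continue
        if lo > cursor:
            out.append((cursor, lo))
        cursor = max(cursor, hi)
        if cursor >= hi_d:
            break
    if cursor < hi_d:
        out.append((cursor, hi_d))
    return out


def complement_of_union(sets: Sequence[IntervalSet],
                        domain: tuple[float, float] = (-math.inf, math.inf)) -> IntervalSet:
    """The domain minus the union of the given interval sets.

    This initialises the optimality set of a freshly added candidate: the
    new candidate is optimal exactly where no existing candidate's level set
    reaches the new flat level.  If the union covers the domain the result
    is empty and the new candidate is pruned straight away.
    """
    pairs = [iv for s in sets for iv in s.intervals]
    return IntervalSet(tuple(_complement_pairs(pairs, domain)))


# ---------------------------------------------------------------------------
# Candidate cost functions
# ---------------------------------------------------------------------------

class CandidateCost:
    """The function ``mu -> Cost_tau(mu)`` for one candidate last change."""

    tau: int
    set: IntervalSet

    def add_observation(self, y: float) -> "CandidateCost":
        """Return the candidate with ``gamma(y, mu)`` added for every mu."""
        raise NotImplementedError

    def __call__(self, mu) -> np.ndarray:
        raise NotImplementedError

    def minimum(self) -> tuple[float, float]:
        """Return ``(mu_hat, min value)``."""
        raise NotImplementedError

    def level_set(self, threshold: float) -> IntervalSet:
        """The exact set ``{mu in D : Cost_tau(mu) <= threshold}``."""
        raise NotImplementedError


@dataclass(frozen=True)
class GaussianCandidate(CandidateCost):
    """Quadratic candidate ``a mu^2 + b mu + c`` for the Gaussian mean loss.

    Adding an observation y (with noise s.d. sigma) adds
    ``(y - mu)^2 / (2 sigma^2)``, so ``a`` increases by ``1/(2 sigma^2)``:
    strictly increasing in the number of absorbed points.
    """

    tau: int
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    sigma: float = 1.0
    set: IntervalSet = IntervalSet.full()

    def add_observation(self, y: float) -> "GaussianCandidate":
        w = 1.0 / (2.0 * self.sigma**2)
        return replace(self, a=self.a + w, b=self.b - 2.0 * w * y,
                       c=self.c + w * y * y)

    def __call__(self, mu):
        mu = np.asarray(mu, dtype=float)
        return self.a * mu * mu + self.b * mu + self.c

    def minimum(self) -> tuple[float, float]:
        if self.a > 0:
            mu_hat = -self.b / (2.0 * self.a)
            return mu_hat, self.c - self.b * self.b / (4.0 * self.a)
        # flat function: value c everywhere; report mu 0 by convention
        return 0.0, self.c

    def level_set(self, threshold: float) -> IntervalSet:
        if self.a == 0.0:
            if self.c <= threshold:
                return IntervalSet.full()
            return IntervalSet.empty()
        disc = self.b * self.b - 4.0 * self.a * (self.c - threshold)
        if disc < 0.0:
            return IntervalSet.empty()
        if disc == 0.0:
            r = -self.b / (2.0 * self.a)
            return IntervalSet(((r, r),))
        half = math.sqrt(disc) / (2.0 * self.a)
        mid = -self.b / (2.0 * self.a)
        return IntervalSet(((mid - half, mid + half),))


def _poisson_level_roots(m: float, s: float, offset: float, threshold: float
                         ) -> tuple[float, float] | None:
    """Roots of ``m mu - s log mu + offset = threshold`` around the minimiser.

    The function is convex on (0, inf) for s > 0 and increasing for s = 0;
    each side is monotone so bisection is exact in the limit.  Returns the
    closed interval of the level set or None if empty.
    """
    if s <= 0.0:
        # increasing linear function m*mu + offset, domain (0, inf)
        if offset > threshold:
            return None
        if m <= 0.0:
            return (0.0, math.inf)
        return (0.0, (threshold - offset) / m)

    mu_hat = s / m
    fmin = offset + s - s * math.log(mu_hat)
    if fmin > threshold:
        return None
    if fmin == threshold:
        return (mu_hat, mu_hat)

    def f(mu: float) -> float:
        return m * mu - s * math.log(mu) + offset - threshold

    # bracket the left root in (0, mu_hat]: f -> +inf as mu -> 0+
    lo = mu_hat
    while f(lo) <= 0.0:
        lo /= 2.0
        if lo < 1e-300:
            break
    left = _bisect(f, lo, mu_hat)
    # bracket the right root in [mu_hat, inf): f -> +inf as mu -> inf
    hi = mu_hat if mu_hat > 0 else 1.0
    while f(hi) <= 0.0:
        hi *= 2.0
        if hi > 1e300:  # pragma: no cover - astronomically large thresholds
            break
    right = _bisect(lambda mu: -f(mu), mu_hat, hi)
    return (left, right)


def _bisect(f, lo: float, hi: float, rel_tol: float = 1e-10) -> float:
    """Root of monotone f on [lo, hi] with f(lo) >= 0 >= f(hi)."""
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo <= rel_tol * max(1.0, abs(mid)):
            break
        if f(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PoissonCandidate(CandidateCost):
    """Candidate ``count * mu - sum_y * log(mu) + offset`` for Poisson counts."""

    tau: int
    count: float = 0.0
    sum_y: float = 0.0
    offset: float = 0.0
    set: IntervalSet = IntervalSet.full((0.0, math.inf))

    def add_observation(self, y: float) -> "PoissonCandidate":
        return replace(self, count=self.count + 1.0, sum_y=self.sum_y + y)

    def __call__(self, mu):
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            return self.count * mu - self.sum_y * np.log(mu) + self.offset

    def minimum(self) -> tuple[float, float]:
        if self.count == 0.0:
            return 1.0, self.offset
        if self.sum_y <= 0.0:
            # decreasing towards mu -> 0+, infimum offset attained in the limit
            return 0.0, self.offset
        mu_hat = self.sum_y / self.count
        return mu_hat, self.offset + self.sum_y - self.sum_y * math.log(mu_hat)

    def level_set(self, threshold: float) -> IntervalSet:
        if self.count == 0.0:
            if self.offset <= threshold:
                return IntervalSet.full((0.0, math.inf))
            return IntervalSet.empty()
        roots = _poisson_level_roots(self.count, self.sum_y, self.offset, threshold)
        if roots is None:
            return IntervalSet.empty()
        return IntervalSet((roots,))
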