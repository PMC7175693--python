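"""Piecewise-constant test signals and exhaustive brute-force optima.

The default :class:`SignalSpec` is the benchmark design used throughout the
test-suite and diagnostics: n = 100 Gaussian observations with changepoints
at t = 20, 40, 60, 80, segment means alternating 0 and 5, and unit noise —
i.e. mean shifts of five noise standard deviations.  The alternating-means
and sigma = 1 choices are this package's defaults for that design.

The brute-force functions enumerate every admissible changepoint placement
and are the ground truth the dynamic-programming solvers are tested
against; they refuse inputs large enough to make enumeration meaningless.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from .costs import CostModel, TimeSeries

__all__ = [
    "SignalSpec",
    "generate",
    "brute_force_penalised",
    "brute_force_constrained",
]

#: generator recorded in serialised specs so averaged diagnostics can be re-run
_GENERATOR = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class SignalSpec:
    """Specification of a piecewise-constant Gaussian signal."""

    n: int = 100
    changepoints: tuple = (20, 40, 60, 80)
    means: tuple = (0.0, 5.0, 0.0, 5.0, 0.0)
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        cps = tuple(int(c) for c in self.changepoints)
        object.__setattr__(self, "changepoints", cps)
        object.__setattr__(self, "means", tuple(float(m) for m in self.means))
        if self.n < 1:
            raise ValueError("n must be positive")
        if any(not (1 <= c <= self.n - 1) for c in cps):
            raise ValueError("changepoints must lie in 1..n-1")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("changepoints must be strictly increasing")
        if len(self.means) != len(cps) + 1:
            raise ValueError("need one segment mean per segment "
                             f"({len(cps) + 1}), got {len(self.means)}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def mean_vector(self) -> np.ndarray:
        bounds = (0,) + self.changepoints + (self.n,)
        lengths = np.diff(bounds)
        return np.repeat(self.means, lengths)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "changepoints": list(self.changepoints),
            "means": list(self.means),
            "sigma": self.sigma,
            "seed": self.seed,
            "generator": _GENERATOR,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignalSpec":
        return cls(n=d["n"], changepoints=tuple(d["changepoints"]),
                   means=tuple(d["means"]), sigma=d["sigma"], seed=d["seed"])


def generate(spec: SignalSpec) -> TimeSeries:
    """Draw one series from the spec, deterministically given its seed."""
    rng = np.random.default_rng(spec.seed)
    values = spec.mean_vector() + rng.normal(0.0, spec.sigma, spec.n)
    return TimeSeries.from_values(values)


def _cost_matrix(series: TimeSeries, model: CostModel) -> np.ndarray:
    n = series.n
    cost = np.zeros((n + 1, n + 1))
    for s in range(n):
        for t in range(s + 1, n + 1):
            cost[s, t] = model.segment_cost(series, s, t)
    return cost


def _score(cost: np.ndarray, cps: tuple, n: int) -> float:
    bounds = (0,) + cps + (n,)
    return sum(cost[s, t] for s, t in zip(bounds, bounds[1:]))


def brute_force_penalised(series: TimeSeries, model: CostModel, beta: float
                          ) -> tuple[float, np.ndarray]:
    """Exact penalised optimum by enumerating all 2^(n-1) segmentations.

    Returns ``(F_n, changepoints)`` where ``F_n = min sum_j C_j + beta k``;
    ties go to the lexicographically smallest changepoint set.
    """
    n = series.n
    if n > 16:
        raise ValueError(f"refusing exhaustive enumeration for n={n} > 16")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    cost = _cost_matrix(series, model)
    best_val = np.inf
    best_cps: tuple = ()
    for k in range(0, n):
        for cps in itertools.combinations(range(1, n), k):
            val = _score(cost, cps, n) + beta * k
            if val < best_val or (val == best_val and cps < best_cps):
                best_val = val
                best_cps = cps
    return float(best_val), np.array(best_cps, dtype=int)


def brute_force_constrained(series: TimeSeries, model: CostModel, k: int
                            ) -> tuple[float, np.ndarray]:
    """Exact k-changepoint optimum by enumerating all k-subsets of 1..n-1."""
    n = series.n
    if k < 0 or k > n - 1:
        raise ValueError(f"k={k} infeasible for n={n}")
    if n > 16 or comb(n - 1, k) > 200_000:
        raise ValueError(f"refusing enumeration of C({n - 1},{k}) placements")
    cost = _cost_matrix(series, model)
    if k == 0:
        return float(cost[0, n]), np.array([], dtype=int)
    best_val = np.inf
    best_cps: tuple = ()
    for cps in itertools.combinations(range(1, n), k):
        val = _score(cost, cps, n)
        if val < best_val or (val == best_val and cps < best_cps):
            best_val = val
            best_cps = cps
    return float(best_val), np.array(best_cps, dtype=int)
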