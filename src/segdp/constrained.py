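"""Exact solvers for the constrained changepoint problem.

For each ``k = 1..K`` these solvers compute ``C_{k,t}``, the minimal total
segment cost of ``y_1..y_t`` using exactly k changepoints, via::

    C_{k,t} = min_{tau in {k,...,t-1}} [ C_{k-1,tau} + C(y_{tau+1:t}) ]

with ``C_{0,t}`` the cost of a single segment.  ``segment_neighbourhood``
runs the recursion unpruned; ``snip`` applies inequality-based pruning
(condition C2) per k; ``pdpa`` applies functional pruning (condition C1)
by tracking candidate costs as functions of the segment parameter mu.  All
three return identical costs and segmentations.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .costs import CostModel, GaussianMeanCost, PoissonMeanCost, TimeSeries
from .piecewise import (IntervalSet, PoissonCandidate, _complement_pairs,
                        complement_of_union, intersect)

_REALS = (-math.inf, math.inf)

__all__ = [
    "ConstrainedResult",
    "segment_neighbourhood",
    "snip",
    "pdpa",
    "backtrack_constrained",
]


@dataclass
class ConstrainedResult:
    """Output of a constrained solver.

    Attributes
    ----------
    C : array, shape (K+1, n+1)
        ``C[k, t]`` is the minimal cost of segmenting ``y_1..y_t`` with k
        changepoints, for ``t >= k`` (``inf`` where undefined).  Row 0 holds
        single-segment costs.
    backpointers : int array, shape (K+1, n+1)
        ``tau*_k(t)``, the optimal last changepoint (-1 where undefined).
    segmentations : dict[int, np.ndarray]
        For each k, the ordered changepoint vector of length k.
    candidate_counts : int array, shape (K+1, n+1)
        ``|R_{k,t}|`` at minimisation time (0 where not applicable).
    K : int
    beta-free: the constrained problem carries no penalty.
    candidate_sets : dict[int, list] or None
        When requested, per-k lists of candidate tuples per step.
    prune_step : int array, shape (K+1, n+1), or None
        For pruned solvers, ``prune_step[k, tau]`` is the last step at which
        tau was live in the level-k recursion (``n`` if never pruned).
    """

    C: np.ndarray
    backpointers: np.ndarray
    segmentations: dict
    candidate_counts: np.ndarray
    K: int
    method: str
    candidate_sets: dict | None = field(default=None, repr=False)
    prune_step: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.C.shape[1] - 1

    @property
    def final_costs(self) -> np.ndarray:
        """``C[k, n]`` for k = 0..K (input to model selection over k)."""
        return self.C[:, -1].copy()


def backtrack_constrained(backpointers: np.ndarray, k: int) -> np.ndarray:
    """Recover the k-changepoint segmentation: tau_k = tau*_k(n), then
    tau_l = tau*_l(tau_{l+1}) for l = k-1..1."""
    K = backpointers.shape[0] - 1
    n = backpointers.shape[1] - 1
    if not (1 <= k <= K):
        raise ValueError(f"k={k} outside 1..{K}")
    cps = []
    t = n
    for level in range(k, 0, -1):
        tau = int(backpointers[level, t])
        if tau < 0 or tau >= t:
            raise ValueError(f"corrupt backpointer at level {level}, t={t}")
        cps.append(tau)
        t = tau
    out = np.array(cps[::-1], dtype=int)
    if np.any(np.diff(out) <= 0) or out[0] < 1:
        raise ValueError("backtracked changepoints are not strictly increasing")
    return out


def _init_tables(series: TimeSeries, model: CostModel, K: int):
    n = series.n
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= n:
        raise ValueError(f"K={K} changepoints need at least K+1={K + 1} points")
    model.validate_series(series)
    C = np.full((K + 1, n + 1), np.inf)
    bp = np.full((K + 1, n + 1), -1, dtype=int)
    counts = np.zeros((K + 1, n + 1), dtype=int)
    C[0, 0] = 0.0
    for t in range(1, n + 1):
        C[0, t] = model.segment_cost(series, 0, t)
    return C, bp, counts


def _finish(C, bp, counts, K, method, sets=None, prune_step=None
            ) -> ConstrainedResult:
    segs = {k: backtrack_constrained(bp, k) for k in range(1, K + 1)}
    return ConstrainedResult(C=C, backpointers=bp, segmentations=segs,
                             candidate_counts=counts, K=K, method=method,
                             candidate_sets=sets, prune_step=prune_step)


def segment_neighbourhood(series: TimeSeries, model: CostModel, K: int,
                          keep_candidate_sets: bool = False) -> ConstrainedResult:
    """Unpruned dynamic programming over (k, t)."""
    n = series.n
    C, bp, counts = _init_tables(series, model, K)
    taus_all = np.arange(n + 1)
    sets = {k: [None] * (k + 1) for k in range(1, K + 1)} if keep_candidate_sets else None
    for k in range(1, K + 1):
        C[k, k] = C[k - 1, k]  # empty last segment seed; never backtracked
        bp[k, k] = k - 1
        for t in range(k + 1, n + 1):
            taus = taus_all[k:t]
            vals = C[k - 1, k:t] + model.segment_costs(series, taus, t)
            i = int(np.argmin(vals))
            C[k, t] = vals[i]
            bp[k, t] = k + i
            counts[k, t] = t - k
            if sets is not None:
                sets[k].append(tuple(range(k, t)))
    return _finish(C, bp, counts, K, "segneigh", sets)


def snip(series: TimeSeries, model: CostModel, K: int,
         kappa: float | None = None,
         keep_candidate_sets: bool = False) -> ConstrainedResult:
    """Segment Neighbourhood with Inequality Pruning.

    Per k, a candidate s is dropped for good once
    ``C_{k-1,s} + C(y_{s+1:t}) + kappa > C_{k-1,t}``: with C2, a last change
    at t then beats a last change at s for every future time.  The freshly
    available position t itself is always admitted.
    """
    if kappa is None:
        kappa = model.kappa
    n = series.n
    C, bp, counts = _init_tables(series, model, K)
    sets = {k: [None] * (k + 1) for k in range(1, K + 1)} if keep_candidate_sets else None
    prune_step = np.full((K + 1, n + 1), n, dtype=int)
    for k in range(1, K + 1):
        C[k, k] = C[k - 1, k]
        bp[k, k] = k - 1
        R = np.array([k], dtype=int)
        for t in range(k + 1, n + 1):
            vals = C[k - 1, R] + model.segment_costs(series, R, t)
            i = int(np.argmin(vals))
            C[k, t] = vals[i]
            bp[k, t] = R[i]
            counts[k, t] = R.size
            if sets is not None:
                sets[k].append(tuple(int(v) for v in R))
            keep = vals + kappa < C[k - 1, t]
            prune_step[k, R[~keep]] = t
            R = np.append(R[keep], t)
    return _finish(C, bp, counts, K, "snip", sets, prune_step)


def pdpa(series: TimeSeries, model: CostModel, K: int,
         keep_candidate_sets: bool = False) -> ConstrainedResult:
    """Pruned dynamic programming (functional pruning) over (k, t).

    Per k the candidate tau carries ``Cost_{k,t}^tau(mu) = C_{k-1,tau} +
    sum_{i=tau+1..t} gamma(y_i, mu)`` plus its optimality set; the level
    threshold when data point t arrives is ``C_{k-1,t}``, the flat level at
    which a new candidate at tau = t enters.
    """
    if isinstance(model, GaussianMeanCost):
        return _pdpa_gaussian(series, model, K, keep_candidate_sets)
    if isinstance(model, PoissonMeanCost):
        return _pdpa_generic(series, model, K, keep_candidate_sets)
    raise TypeError(
        f"functional pruning needs a C1 family with interval-computable level "
        f"sets; {model.family!r} is not supported")


def _pdpa_gaussian(series: TimeSeries, model: GaussianMeanCost, K: int,
                   keep_candidate_sets: bool) -> ConstrainedResult:
    y = series.values
    n = series.n
    w = 0.5 / (model.sigma * model.sigma)
    C, bp, counts = _init_tables(series, model, K)
    sets_trace = {k: [None] * (k + 1) for k in range(1, K + 1)} if keep_candidate_sets else None
    prune_step = np.full((K + 1, n + 1), n, dtype=int)

    for k in range(1, K + 1):
        C[k, k] = C[k - 1, k]
        bp[k, k] = k - 1
        taus = [k]
        A = [0.0]
        B = [0.0]
        Coef = [float(C[k - 1, k])]
        opt_sets: list[list[tuple[float, float]]] = [[(-math.inf, math.inf)]]
        for t in range(k + 1, n + 1):
            yt = y[t - 1]
            db = -2.0 * w * yt
            dc = w * yt * yt
            m = len(taus)
            counts[k, t] = m
            if sets_trace is not None:
                sets_trace[k].append(tuple(taus))
            best = math.inf
            best_i = 0
            for i in range(m):
                a = A[i] + w
                b = B[i] + db
                c = Coef[i] + dc
                A[i] = a
                B[i] = b
                Coef[i] = c
                v = c - b * b / (4.0 * a)
                if v < best:
                    best = v
                    best_i = i
            C[k, t] = best
            bp[k, t] = taus[best_i]

            thr = float(C[k - 1, t])
            level_ivs: list[tuple[float, float]] = []
            nt: list[int] = []
            nA: list[float] = []
            nB: list[float] = []
            nC: list[float] = []
            ns: list[list[tuple[float, float]]] = []
            for i in range(m):
                a = A[i]
                b = B[i]
                c = Coef[i]
                disc = b * b - 4.0 * a * (c - thr)
                if disc < 0.0:
                    prune_step[k, taus[i]] = t
                    continue
                half = math.sqrt(disc) / (2.0 * a)
                mid = -b / (2.0 * a)
                lo_i = mid - half
                hi_i = mid + half
                level_ivs.append((lo_i, hi_i))
                trimmed = [
                    (max(lo, lo_i), min(hi, hi_i))
                    for lo, hi in opt_sets[i]
                    if lo <= hi_i and hi >= lo_i
                ]
                if trimmed:
                    nt.append(taus[i])
                    nA.append(a)
                    nB.append(b)
                    nC.append(c)
                    ns.append(trimmed)
                else:
                    prune_step[k, taus[i]] = t
            comp = _complement_pairs(level_ivs, _REALS)
            if comp and t < n:
                nt.append(t)
                nA.append(0.0)
                nB.append(0.0)
                nC.append(thr)
                ns.append(comp)
            elif t < n:
                prune_step[k, t] = t
            taus, A, B, Coef, opt_sets = nt, nA, nB, nC, ns
    return _finish(C, bp, counts, K, "pdpa", sets_trace, prune_step)


def _pdpa_generic(series: TimeSeries, model: PoissonMeanCost, K: int,
                  keep_candidate_sets: bool) -> ConstrainedResult:
    y = series.values
    n = series.n
    domain = model.domain
    C, bp, counts = _init_tables(series, model, K)
    sets_trace = {k: [None] * (k + 1) for k in range(1, K + 1)} if keep_candidate_sets else None
    prune_step = np.full((K + 1, n + 1), n, dtype=int)

    for k in range(1, K + 1):
        C[k, k] = C[k - 1, k]
        bp[k, k] = k - 1
        cands = [PoissonCandidate(tau=k, offset=float(C[k - 1, k]),
                                  set=IntervalSet.full(domain))]
        for t in range(k + 1, n + 1):
            cands = [c.add_observation(y[t - 1]) for c in cands]
            counts[k, t] = len(cands)
            if sets_trace is not None:
                sets_trace[k].append(tuple(c.tau for c in cands))
            vals = [c.minimum()[1] for c in cands]
            i = int(np.argmin(vals))
            C[k, t] = vals[i]
            bp[k, t] = cands[i].tau

            thr = float(C[k - 1, t])
            levels = [c.level_set(thr) for c in cands]
            survivors = []
            for c, lev in zip(cands, levels):
                new_set = intersect(c.set, lev)
                if not new_set.is_empty:
                    survivors.append(dataclasses.replace(c, set=new_set))
                else:
                    prune_step[k, c.tau] = t
            comp = complement_of_union(levels, domain)
            if not comp.is_empty and t < n:
                survivors.append(PoissonCandidate(tau=t, offset=thr, set=comp))
            elif t < n:
                prune_step[k, t] = t
            cands = survivors
    return _finish(C, bp, counts, K, "pdpa", sets_trace, prune_step)
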