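"""Exact solvers for the penalised changepoint problem.

All three algorithms minimise the same objective over segmentations of
``y_1..y_n``::

    F(n) = min_{k, tau} sum_j [ C(y_{tau_j+1 : tau_{j+1}}) + beta ] - beta

via the dynamic-programming recursion ``F(t) = min_{0 <= tau < t} [F(tau) +
C(y_{tau+1:t}) + beta]`` with ``F(0) = -beta``.  They differ only in how the
candidate set of last-changepoint positions ``R_t`` is pruned:

* ``optimal_partitioning`` — no pruning, ``|R_t| = t``;
* ``pelt`` — inequality-based pruning (condition C2): tau is dropped once
  ``F(tau) + C(y_{tau+1:t}) + kappa > F(t)``;
* ``fpop`` — functional pruning (condition C1): each candidate's cost is
  kept as a function of the segment parameter mu and dropped once it is
  optimal for no mu.

All three return identical optima; the candidate counts they record are the
interesting diagnostic.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .costs import CostModel, GaussianMeanCost, PoissonMeanCost, TimeSeries
from .piecewise import CandidateCost, PoissonCandidate, _complement_pairs

_REALS = (-math.inf, math.inf)

__all__ = [
    "PenalisedResult",
    "optimal_partitioning",
    "pelt",
    "fpop",
    "backtrack_penalised",
]


@dataclass
class PenalisedResult:
    """Output of a penalised solver.

    Attributes
    ----------
    F : array, shape (n+1,)
        Optimal penalised costs; ``F[0] = -beta``.
    last_change : int array, shape (n+1,)
        Backpointers ``tau*_t`` (entry 0 is unused and set to -1).
    changepoints : int array
        The recovered changepoint vector for the full series, each in
        ``1..n-1``, strictly increasing.
    candidate_counts : int array, shape (n+1,)
        ``|R_t|`` — the number of candidates minimised over at each step
        (entry 0 unused).  Equals ``t`` for Optimal Partitioning.
    beta : float
        Penalty per changepoint.
    method : str
    candidate_sets : list or None
        When requested, ``candidate_sets[t]`` is the tuple of candidate
        positions in ``R_t`` at minimisation time.
    prune_step : int array or None
        For pruned solvers, ``prune_step[tau]`` is the last step at which
        candidate tau was live (``n`` if never pruned; ``tau`` itself if the
        candidate was pruned straight away on creation).  Since a candidate
        never re-enters, ``R_t = {tau : tau < t and prune_step[tau] >= t}``,
        which makes stepwise set-inclusion checks O(n) in memory.
    """

    F: np.ndarray
    last_change: np.ndarray
    changepoints: np.ndarray
    candidate_counts: np.ndarray
    beta: float
    method: str
    candidate_sets: list | None = field(default=None, repr=False)
    prune_step: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.F.size - 1

    @property
    def optimal_cost(self) -> float:
        return float(self.F[-1])


def backtrack_penalised(last_change: np.ndarray) -> np.ndarray:
    """Recover the changepoint vector from backpointers: cp(t) = (cp(tau*_t), tau*_t)."""
    n = len(last_change) - 1
    cps: list[int] = []
    t = n
    while t > 0:
        tau = int(last_change[t])
        if tau >= t:
            raise ValueError(f"corrupt backpointer last_change[{t}]={tau} >= {t}")
        if tau > 0:
            cps.append(tau)
        t = tau
    return np.array(cps[::-1], dtype=int)


def _check_inputs(series: TimeSeries, model: CostModel, beta: float) -> None:
    if beta < 0:
        raise ValueError(f"penalty beta must be non-negative, got {beta}")
    model.validate_series(series)


def optimal_partitioning(series: TimeSeries, model: CostModel, beta: float,
                         keep_candidate_sets: bool = False) -> PenalisedResult:
    """Unpruned dynamic programming over the last changepoint position."""
    _check_inputs(series, model, beta)
    n = series.n
    F = np.empty(n + 1)
    F[0] = -beta
    last = np.full(n + 1, -1, dtype=int)
    counts = np.zeros(n + 1, dtype=int)
    taus_all = np.arange(n + 1)
    sets: list | None = [None] if keep_candidate_sets else None
    for t in range(1, n + 1):
        taus = taus_all[:t]
        vals = F[:t] + model.segment_costs(series, taus, t) + beta
        i = int(np.argmin(vals))
        F[t] = vals[i]
        last[t] = i
        counts[t] = t
        if sets is not None:
            sets.append(tuple(range(t)))
    return PenalisedResult(F=F, last_change=last,
                           changepoints=backtrack_penalised(last),
                           candidate_counts=counts, beta=beta,
                           method="op", candidate_sets=sets)


def pelt(series: TimeSeries, model: CostModel, beta: float,
         kappa: float | None = None,
         keep_candidate_sets: bool = False) -> PenalisedResult:
    """Optimal partitioning with inequality-based pruning.

    After computing ``F(t)``, every candidate tau with
    ``F(tau) + C(y_{tau+1:t}) + kappa > F(t)`` is removed for good, and the
    position ``t`` itself is admitted (its empty segment has cost 0, so the
    ``<=`` test always keeps it).  Exact whenever C2 holds for ``kappa``;
    the default kappa is the model's (0 for all C1 families).
    """
    _check_inputs(series, model, beta)
    if kappa is None:
        kappa = model.kappa
    n = series.n
    F = np.empty(n + 1)
    F[0] = -beta
    last = np.full(n + 1, -1, dtype=int)
    counts = np.zeros(n + 1, dtype=int)
    sets: list | None = [None] if keep_candidate_sets else None
    prune_step = np.full(n + 1, n, dtype=int)
    R = np.array([0], dtype=int)
    for t in range(1, n + 1):
        costs = model.segment_costs(series, R, t)
        vals = F[R] + costs + beta
        i = int(np.argmin(vals))
        F[t] = vals[i]
        last[t] = R[i]
        counts[t] = R.size
        if sets is not None:
            sets.append(tuple(int(v) for v in R))
        keep = F[R] + costs + kappa <= F[t]
        prune_step[R[~keep]] = t
        R = np.append(R[keep], t)
    return PenalisedResult(F=F, last_change=last,
                           changepoints=backtrack_penalised(last),
                           candidate_counts=counts, beta=beta,
                           method="pelt", candidate_sets=sets,
                           prune_step=prune_step)


# ---------------------------------------------------------------------------
# FPOP
# ---------------------------------------------------------------------------

def fpop(series: TimeSeries, model: CostModel, beta: float,
         keep_candidate_sets: bool = False) -> PenalisedResult:
    """Functional-pruning optimal partitioning.

    Candidate tau carries ``Cost_t^tau(mu) = F(tau) + beta + sum gamma(y_i, mu)``
    together with the interval set where it attains the pointwise minimum
    ``Cost*_t(mu)``.  At each step every candidate absorbs ``gamma(y_t, mu)``,
    ``F(t)`` is read off as the smallest candidate minimum, each optimality
    set is intersected with the level set ``{mu : Cost_t^tau(mu) <= F(t) +
    beta}``, empty candidates are pruned, and a new candidate at ``t``
    (flat at ``F(t) + beta``) is seeded on whatever part of the domain no
    level set covers — pruned straight away if that is empty.
    """
    _check_inputs(series, model, beta)
    if isinstance(model, GaussianMeanCost):
        return _fpop_gaussian(series, model, beta, keep_candidate_sets)
    if isinstance(model, PoissonMeanCost):
        return _fpop_generic(series, model, beta, keep_candidate_sets)
    raise TypeError(
        f"functional pruning needs a C1 family with interval-computable level "
        f"sets; {model.family!r} is not supported")


def _fpop_gaussian(series: TimeSeries, model: GaussianMeanCost, beta: float,
                   keep_candidate_sets: bool) -> PenalisedResult:
    # Hot loop: candidates live in parallel plain-python lists; each
    # optimality set is a list of [lo, hi] pairs.  Kept in insertion order,
    # i.e. increasing tau, so argmin ties resolve to the smallest tau.
    y = series.values
    n = series.n
    w = 0.5 / (model.sigma * model.sigma)
    F = np.empty(n + 1)
    F[0] = -beta
    last = np.full(n + 1, -1, dtype=int)
    counts = np.zeros(n + 1, dtype=int)
    sets_trace: list | None = [None] if keep_candidate_sets else None
    prune_step = np.full(n + 1, n, dtype=int)

    taus = [0]
    A = [0.0]
    B = [0.0]
    C = [F[0] + beta]
    opt_sets: list[list[tuple[float, float]]] = [[(-math.inf, math.inf)]]

    for t in range(1, n + 1):
        yt = y[t - 1]
        db = -2.0 * w * yt
        dc = w * yt * yt
        m = len(taus)
        counts[t] = m
        if sets_trace is not None:
            sets_trace.append(tuple(taus))

        best = math.inf
        best_i = 0
        for i in range(m):
            a = A[i] + w
            b = B[i] + db
            c = C[i] + dc
            A[i] = a
            B[i] = b
            C[i] = c
            v = c - b * b / (4.0 * a)
            if v < best:
                best = v
                best_i = i
        F[t] = best
        last[t] = taus[best_i]

        thr = best + beta
        level_ivs: list[tuple[float, float]] = []
        new_taus: list[int] = []
        new_A: list[float] = []
        new_B: list[float] = []
        new_C: list[float] = []
        new_sets: list[list[tuple[float, float]]] = []
        for i in range(m):
            a = A[i]
            b = B[i]
            c = C[i]
            disc = b * b - 4.0 * a * (c - thr)
            if disc < 0.0:
                # level set empty => candidate set empty => pruned
                prune_step[taus[i]] = t
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
                new_taus.append(taus[i])
                new_A.append(a)
                new_B.append(b)
                new_C.append(c)
                new_sets.append(trimmed)
            else:
                prune_step[taus[i]] = t

        # new candidate at tau = t on the complement of the level-set union
        comp = _complement_pairs(level_ivs, _REALS)
        if comp:
            new_taus.append(t)
            new_A.append(0.0)
            new_B.append(0.0)
            new_C.append(thr)
            new_sets.append(comp)
        elif t <= n:
            prune_step[t] = t  # pruned straight away
        taus, A, B, C, opt_sets = new_taus, new_A, new_B, new_C, new_sets

    return PenalisedResult(F=F, last_change=last,
                           changepoints=backtrack_penalised(last),
                           candidate_counts=counts, beta=beta,
                           method="fpop", candidate_sets=sets_trace,
                           prune_step=prune_step)


def _fpop_generic(series: TimeSeries, model: PoissonMeanCost, beta: float,
                  keep_candidate_sets: bool) -> PenalisedResult:
    """FPOP over :class:`CandidateCost` objects (Poisson loss)."""
    from .piecewise import IntervalSet, complement_of_union, intersect

    n = series.n
    y = series.values
    domain = model.domain
    F = np.empty(n + 1)
    F[0] = -beta
    last = np.full(n + 1, -1, dtype=int)
    counts = np.zeros(n + 1, dtype=int)
    sets_trace: list | None = [None] if keep_candidate_sets else None
    prune_step = np.full(n + 1, n, dtype=int)

    cands: list[CandidateCost] = [
        PoissonCandidate(tau=0, offset=F[0] + beta,
                         set=IntervalSet.full(domain))
    ]
    for t in range(1, n + 1):
        cands = [c.add_observation(y[t - 1]) for c in cands]
        counts[t] = len(cands)
        if sets_trace is not None:
            sets_trace.append(tuple(c.tau for c in cands))
        vals = [c.minimum()[1] for c in cands]
        i = int(np.argmin(vals))
        F[t] = vals[i]
        last[t] = cands[i].tau

        thr = F[t] + beta
        levels = [c.level_set(thr) for c in cands]
        survivors = []
        for c, lev in zip(cands, levels):
            new_set = intersect(c.set, lev)
            if not new_set.is_empty:
                survivors.append(dataclasses.replace(c, set=new_set))
            else:
                prune_step[c.tau] = t
        comp = complement_of_union(levels, domain)
        if not comp.is_empty:
            survivors.append(PoissonCandidate(tau=t, offset=thr, set=comp))
        else:
            prune_step[t] = t
        cands = survivors

    return PenalisedResult(F=F, last_change=last,
                           changepoints=backtrack_penalised(last),
                           candidate_counts=counts, beta=beta,
                           method="fpop", candidate_sets=sets_trace,
                           prune_step=prune_step)
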