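"""Segment cost functions for changepoint detection.

A segmentation of ``y_1..y_n`` with changepoints ``tau_1 < ... < tau_k``
splits the series into segments ``y_{tau_{j-1}+1..tau_j}``.  Each loss
family defines a pointwise cost ``gamma(y, mu)`` and the induced segment
cost ``C(y_{s+1:t}) = min_mu sum gamma(y_i, mu)`` (condition C1), which is
evaluated in O(1) from prefix sums.  Every C1 cost is also kappa-subadditive
across a split with kappa = 0 (condition C2), which is what inequality-based
pruning (PELT, SNIP) relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "CostModel",
    "GaussianMeanCost",
    "PoissonMeanCost",
    "get_cost_model",
]


@dataclass(frozen=True)
class TimeSeries:
    """An ordered univariate signal with prefix sums for O(1) segment costs.

    Data are 1-based in the changepoint convention: the segment ``(s, t]``
    contains ``values[s+1..t]``, i.e. ``values[s:t]`` in 0-based numpy
    slicing.  ``prefix_sum[t] - prefix_sum[s]`` is the sum of that segment.
    """

    values: np.ndarray
    prefix_sum: np.ndarray = field(repr=False)
    prefix_sumsq: np.ndarray = field(repr=False)

    @classmethod
    def from_values(cls, values) -> "TimeSeries":
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError("series must contain at least one observation")
        if not np.all(np.isfinite(arr)):
            raise ValueError("series contains non-finite values")
        ps = np.concatenate([[0.0], np.cumsum(arr)])
        pss = np.concatenate([[0.0], np.cumsum(arr * arr)])
        return cls(values=arr, prefix_sum=ps, prefix_sumsq=pss)

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.values.size


class CostModel:
    """Base class for loss families satisfying condition C1.

    Subclasses implement the pointwise cost ``gamma(y, mu)``, the closed-form
    segment cost, and a vectorised variant used by the DP solvers.  ``kappa``
    is the C2 constant; it is 0 for every C1 family.
    """

    family: str = "abstract"
    kappa: float = 0.0
    #: parameter domain as (lo, hi); endpoints may be +-inf
    domain: tuple[float, float] = (-np.inf, np.inf)

    def pointwise_cost(self, y: float, mu: float) -> float:
        raise NotImplementedError

    def segment_cost(self, series: TimeSeries, s: int, t: int) -> float:
        """Cost of the segment ``y_{s+1..t}`` (0 <= s < t <= n)."""
        raise NotImplementedError

    def segment_costs(self, series: TimeSeries, taus: np.ndarray, t: int) -> np.ndarray:
        """Vectorised ``segment_cost(series, tau, t)`` over an array of taus."""
        raise NotImplementedError

    def validate_series(self, series: TimeSeries) -> None:
        """Raise if the series is outside the family's support."""

    def _check_indices(self, series: TimeSeries, s: int, t: int) -> None:
        if not (0 <= s < t <= series.n):
            raise IndexError(f"invalid segment indices s={s}, t={t} for n={series.n}")


@dataclass(frozen=True)
class GaussianMeanCost(CostModel):
    """Change in mean of Gaussian data with known variance ``sigma**2``.

    gamma(y, mu) = (y - mu)^2 / (2 sigma^2); the segment cost is the residual
    sum of squares about the segment mean divided by 2 sigma^2 (negative
    log-likelihood up to a data-independent term linear in segment length).
    """

    sigma: float = 1.0
    family: str = "gaussian_mean"
    kappa: float = 0.0
    domain: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def pointwise_cost(self, y: float, mu: float) -> float:
        if not np.isfinite(mu):
            raise ValueError(f"mu={mu} outside parameter domain {self.domain}")
        return (y - mu) ** 2 / (2.0 * self.sigma**2)

    def segment_cost(self, series: TimeSeries, s: int, t: int) -> float:
        self._check_indices(series, s, t)
        ssq = series.prefix_sumsq[t] - series.prefix_sumsq[s]
        sm = series.prefix_sum[t] - series.prefix_sum[s]
        return (ssq - sm * sm / (t - s)) / (2.0 * self.sigma**2)

    def segment_costs(self, series: TimeSeries, taus: np.ndarray, t: int) -> np.ndarray:
        ssq = series.prefix_sumsq[t] - series.prefix_sumsq[taus]
        sm = series.prefix_sum[t] - series.prefix_sum[taus]
        lengths = t - taus
        # length 0 (tau == t) contributes an empty segment with cost 0
        out = np.zeros(len(np.atleast_1d(lengths)), dtype=float)
        nz = lengths > 0
        out[nz] = (ssq[nz] - sm[nz] * sm[nz] / lengths[nz]) / (2.0 * self.sigma**2)
        return out


@dataclass(frozen=True)
class PoissonMeanCost(CostModel):
    """Change in rate of Poisson counts.

    gamma(y, mu) = mu - y log(mu), the negative Poisson log-likelihood with
    the data-only log(y!) term dropped.  The parameter domain is (0, inf);
    an all-zero segment attains cost 0 in the limit mu -> 0+ and the
    segment cost returns 0 there by convention.
    """

    family: str = "poisson_mean"
    kappa: float = 0.0
    domain: tuple[float, float] = (0.0, np.inf)

    def pointwise_cost(self, y: float, mu: float) -> float:
        if not (0.0 < mu < np.inf):
            raise ValueError(f"mu={mu} outside parameter domain (0, inf)")
        return mu - y * np.log(mu)

    def validate_series(self, series: TimeSeries) -> None:
        if np.any(series.values < 0):
            raise ValueError("Poisson loss requires non-negative counts")

    def segment_cost(self, series: TimeSeries, s: int, t: int) -> float:
        self._check_indices(series, s, t)
        sm = series.prefix_sum[t] - series.prefix_sum[s]
        if sm <= 0.0:
            return 0.0
        m = t - s
        return sm - sm * np.log(sm / m)

    def segment_costs(self, series: TimeSeries, taus: np.ndarray, t: int) -> np.ndarray:
        sm = series.prefix_sum[t] - series.prefix_sum[taus]
        lengths = t - taus
        out = np.zeros(len(np.atleast_1d(lengths)), dtype=float)
        pos = (sm > 0) & (lengths > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[pos] = sm[pos] - sm[pos] * np.log(sm[pos] / lengths[pos])
        return out


_FAMILIES = {
    "gaussian": GaussianMeanCost,
    "gaussian_mean": GaussianMeanCost,
    "poisson": PoissonMeanCost,
    "poisson_mean": PoissonMeanCost,
}


def get_cost_model(family: str, **kwargs) -> CostModel:
    """Look up a cost model by family name (``gaussian`` or ``poisson``)."""
    try:
        cls = _FAMILIES[family.lower()]
    except KeyError:
        raise ValueError(
            f"unknown loss family {family!r}; choose from {sorted(set(_FAMILIES))}"
        ) from None
    return cls(**kwargs)
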