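"""Model/Results front end for changepoint segmentation.

``ChangepointModel`` holds the signal (optionally MAD-standardised) and the
loss family; ``fit`` dispatches to one of the exact dynamic-programming
solvers and returns a results object carrying the segmentation, fitted
segment means, per-step pruning diagnostics and a ``summary()`` table.

    >>> model = ChangepointModel(y, loss="gaussian", standardise="mad")
    >>> res = model.fit(method="fpop", penalty="2logn")
    >>> res.changepoints
    array([...])
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constrained import ConstrainedResult, pdpa, segment_neighbourhood, snip
from .costs import TimeSeries, get_cost_model
from .io import segment_table
from .penalised import PenalisedResult, fpop, optimal_partitioning, pelt
from .selection import mad_standardise, parse_penalty, select_k

__all__ = ["ChangepointModel", "PenalisedFit", "ConstrainedFit"]

_PENALISED = {"op": optimal_partitioning, "pelt": pelt, "fpop": fpop}
_CONSTRAINED = {"segneigh": segment_neighbourhood, "snip": snip, "pdpa": pdpa}


class ChangepointModel:
    """Piecewise-constant segmentation of a univariate ordered signal.

    Parameters
    ----------
    endog : array-like
        The observed series, in order.
    loss : {"gaussian", "poisson"}
        ``gaussian`` detects changes in mean under constant noise variance;
        ``poisson`` detects changes in rate of count data.
    standardise : {False, "mad"}
        With ``"mad"``, divide the series by a robust noise-scale estimate
        from first differences before fitting (Gaussian loss only), so a
        unit-variance ``log n``-type penalty is calibrated.
    """

    def __init__(self, endog, loss: str = "gaussian", standardise=False):
        self.endog = np.asarray(endog, dtype=float).ravel()
        series = TimeSeries.from_values(self.endog)
        self.sigma_hat: float | None = None
        if standardise in (True, "mad"):
            if loss.startswith("poisson"):
                raise ValueError("MAD standardisation applies to the Gaussian loss")
            series, self.sigma_hat = mad_standardise(series)
        elif standardise:
            raise ValueError(f"unknown standardise option {standardise!r}")
        self.series = series
        self.loss = loss
        self.cost_model = get_cost_model(loss)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, column, **kwargs
                       ) -> "ChangepointModel":
        return cls(data[column].to_numpy(), **kwargs)

    @property
    def nobs(self) -> int:
        return self.series.n

    def fit(self, method: str = "fpop", penalty="2logn", K: int | None = None,
            kappa: float | None = None, keep_candidate_sets: bool = False):
        """Run an exact solver.

        ``op``/``pelt``/``fpop`` solve the penalised problem and require a
        penalty (a beta value, or a string like ``"2logn"``);
        ``segneigh``/``snip``/``pdpa`` solve the constrained problem and
        require ``K``, the maximum number of changepoints.
        """
        method = method.lower()
        if method in _PENALISED:
            if penalty is None:
                raise ValueError(f"method {method!r} requires a penalty")
            beta = parse_penalty(penalty).value(self.nobs)
            kwargs = {"keep_candidate_sets": keep_candidate_sets}
            if method == "pelt":
                kwargs["kappa"] = kappa
            raw = _PENALISED[method](self.series, self.cost_model, beta, **kwargs)
            return PenalisedFit(self, raw)
        if method in _CONSTRAINED:
            if K is None:
                raise ValueError(f"method {method!r} requires K, the maximum "
                                 "number of changepoints")
            kwargs = {"keep_candidate_sets": keep_candidate_sets}
            if method == "snip":
                kwargs["kappa"] = kappa
            raw = _CONSTRAINED[method](self.series, self.cost_model, K, **kwargs)
            return ConstrainedFit(self, raw)
        raise ValueError(f"unknown method {method!r}; choose from "
                         f"{sorted(_PENALISED) + sorted(_CONSTRAINED)}")


class _FitBase:
    model: ChangepointModel

    def _segments(self, changepoints) -> pd.DataFrame:
        return segment_table(self.model.series, changepoints,
                             self.model.cost_model)

    def _plot(self, changepoints, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model.series.values
        ax.plot(np.arange(1, y.size + 1), y, ".", color="0.6", ms=3,
                label="signal")
        table = self._segments(changepoints)
        for _, row in table.iterrows():
            ax.hlines(row["mean"], row["start"], row["end"], color="C3", lw=2)
        for cp in np.asarray(changepoints, dtype=int):
            ax.axvline(cp + 0.5, color="C0", ls=":", lw=1)
        ax.set_xlabel("t")
        ax.set_ylabel("y")
        return ax


class PenalisedFit(_FitBase):
    """Results of an exact penalised fit (OP, PELT or FPOP)."""

    def __init__(self, model: ChangepointModel, result: PenalisedResult):
        self.model = model
        self.result = result

    @property
    def changepoints(self) -> np.ndarray:
        return self.result.changepoints

    @property
    def n_changepoints(self) -> int:
        return self.result.changepoints.size

    @property
    def beta(self) -> float:
        return self.result.beta

    @property
    def optimal_cost(self) -> float:
        return self.result.optimal_cost

    @property
    def candidate_counts(self) -> np.ndarray:
        return self.result.candidate_counts

    @property
    def params(self) -> np.ndarray:
        """Fitted segment means, one per segment."""
        return self.segments["mean"].to_numpy()

    @property
    def segments(self) -> pd.DataFrame:
        return self._segments(self.result.changepoints)

    def plot(self, ax=None):
        return self._plot(self.result.changepoints, ax=ax)

    def summary(self) -> str:
        res = self.result
        counts = res.candidate_counts[1:]
        lines = [
            "        Changepoint Detection Results (penalised)",
            "=" * 58,
            f"Method:                 {res.method.upper()}",
            f"Loss:                   {self.model.cost_model.family}",
            f"No. observations:       {self.model.nobs}",
            f"Penalty beta:           {res.beta:.6g}",
            f"MAD sigma_hat:          "
            f"{self.model.sigma_hat:.6g}" if self.model.sigma_hat is not None
            else "MAD sigma_hat:          (not standardised)",
            f"Changepoints found:     {self.n_changepoints}",
            f"Optimal cost F(n):      {res.optimal_cost:.6g}",
            f"Candidates |R_t|:       max {int(counts.max())}, "
            f"mean {counts.mean():.2f}",
            "-" * 58,
            self.segments.to_string(index=False),
            "=" * 58,
        ]
        return "\n".join(lines)


class ConstrainedFit(_FitBase):
    """Results of an exact constrained fit (SegNeigh, SNIP or pDPA)."""

    def __init__(self, model: ChangepointModel, result: ConstrainedResult):
        self.model = model
        self.result = result

    @property
    def K(self) -> int:
        return self.result.K

    @property
    def final_costs(self) -> np.ndarray:
        """``C_{k,n}`` for k = 0..K (non-increasing in k)."""
        return self.result.final_costs

    def segmentation(self, k: int) -> np.ndarray:
        if k == 0:
            return np.array([], dtype=int)
        return self.result.segmentations[k]

    def segments(self, k: int) -> pd.DataFrame:
        return self._segments(self.segmentation(k))

    def select(self, penalty) -> int:
        """Pick k by minimising ``C_{k,n} + f(k, n)``."""
        return select_k(self.final_costs, penalty, self.model.nobs)

    def plot(self, k: int, ax=None):
        return self._plot(self.segmentation(k), ax=ax)

    def summary(self, penalty=None) -> str:
        res = self.result
        lines = [
            "        Changepoint Detection Results (constrained)",
            "=" * 58,
            f"Method:                 {res.method.upper()}",
            f"Loss:                   {self.model.cost_model.family}",
            f"No. observations:       {self.model.nobs}",
            f"Max changepoints K:     {res.K}",
        ]
        if penalty is not None:
            k_hat = self.select(penalty)
            lines.append(f"Selected k:             {k_hat}")
        lines.append("-" * 58)
        lines.append("   k     C(k,n)   changepoints")
        for k in range(res.K + 1):
            cps = self.segmentation(k)
            lines.append(f"  {k:2d} {res.C[k, -1]:10.4f}   "
                         f"{np.array2string(cps, separator=',')}")
        lines.append("=" * 58)
        return "\n".join(lines)
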