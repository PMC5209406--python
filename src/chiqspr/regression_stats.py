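"""Least-squares fitting and the study's fit statistics.

The models are ordinary least squares with an intercept, fitted by a
numerically stable orthogonal decomposition (``numpy.linalg.lstsq``).
The quality statistics follow the conventions used throughout this line
of QSPR work rather than textbook multiple-regression output:

* coefficient of determination
  ``r2 = sum((y_cal - ybar)^2) / sum((y_exp - ybar)^2)``
  (for OLS with intercept this equals the usual ``1 - SSE/SST``);
* correlation coefficient ``r = sqrt(r2)`` — the positive root, which is
  not Pearson's signed coefficient but carries the same meaning here;
* Fisher ratio ``F = (n - 2) * r2 / (1 - r2)`` with the ``n - 2`` factor
  kept for *every* model, including the two-descriptor one;
* standard deviation of the fit ``s = sqrt(SSE / (n - 2))``;
* residuals ``delta_i = y_exp,i - y_cal,i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import INDEX_COLUMNS, QsprDataset

__all__ = [
    "RegressionModel",
    "FitStatistics",
    "CollinearityError",
    "DegenerateInputError",
    "ols_fit",
    "fit_statistics",
    "pearson_matrix",
]


class CollinearityError(ValueError):
    """Raised when the design matrix is (numerically) singular."""


class DegenerateInputError(ValueError):
    """Raised when the response has zero variance."""


@dataclass(frozen=True)
class FitStatistics:
    r2: float
    r: float
    F: float
    s: float
    residuals: tuple[float, ...]


@dataclass(frozen=True)
class RegressionModel:
    """A fitted (or printed) linear model logcmc = intercept + sum(coef * chi)."""

    predictors: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]
    n: int = 0
    r2: float = float("nan")
    r: float = float("nan")
    F: float = float("nan")
    s: float = float("nan")
    fitted: tuple[float, ...] = ()
    residuals: tuple[float, ...] = ()
    std_errors: tuple[float, ...] = ()  # intercept first, then slopes
    row_names: tuple[str, ...] = ()
    source: str = "refit"  # refit | printed

    def design_vector(self, indices: dict[str, float]) -> np.ndarray:
        missing = [p for p in self.predictors if p not in indices]
        if missing:
            raise KeyError(f"row is missing predictor(s) {missing}")
        return np.array([indices[p] for p in self.predictors])

    def to_report(self) -> dict:
        """JSON-serializable model report."""
        return {
            "predictors": list(self.predictors),
            "intercept": self.intercept,
            "coefficients": list(self.coefficients),
            "r2": self.r2,
            "r": self.r,
            "F": self.F,
            "s": self.s,
            "n": self.n,
            "source": self.source,
            "residuals": dict(zip(self.row_names, self.residuals)),
        }


def fit_statistics(y_exp: Sequence[float], y_cal: Sequence[float]) -> FitStatistics:
    """Fit statistics for observed vs calculated response values."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if y_exp.shape != y_cal.shape or y_exp.ndim != 1:
        raise ValueError("y_exp and y_cal must be 1-d and of equal length")
    n = y_exp.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    ybar = y_exp.mean()
    sst = float(np.sum((y_exp - ybar) ** 2))
    if sst == 0.0:
        raise DegenerateInputError("response has zero total sum of squares")
    r2 = float(np.sum((y_cal - ybar) ** 2) / sst)
    resid = y_exp - y_cal
    sse = float(np.sum(resid**2))
    s = float(np.sqrt(sse / (n - 2)))
    F = float("inf") if r2 >= 1.0 else (n - 2) * r2 / (1.0 - r2)
    return FitStatistics(r2=r2, r=float(np.sqrt(min(r2, 1.0))), F=F, s=s, residuals=tuple(resid))


def ols_fit(dataset: QsprDataset, predictors: Sequence[str]) -> RegressionModel:
    """Ordinary least squares of logcmc on one or two connectivity indices."""
    predictors = tuple(predictors)
    unknown = [p for p in predictors if p not in INDEX_COLUMNS]
    if unknown:
        raise KeyError(f"unknown predictor column(s) {unknown}")
    rows = dataset.rows
    if any(r.logcmc is None for r in rows):
        raise ValueError("all rows need a logcmc value to fit")
    n = len(rows)
    if n <= len(predictors) + 1:
        raise ValueError(f"n={n} too small for {len(predictors)} predictor(s)")

    y = np.array([r.logcmc for r in rows])
    X = np.column_stack(
        [np.ones(n)] + [np.array([r.indices[p] for r in rows]) for p in predictors]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearityError(f"design matrix for {predictors} is singular (rank {rank})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    stats = fit_statistics(y, fitted)
    # conventional standard errors, but with the study's s (n-2 denominator)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv)) * stats.s
    return RegressionModel(
        predictors=predictors,
        intercept=float(beta[0]),
        coefficients=tuple(float(b) for b in beta[1:]),
        n=n,
        r2=stats.r2,
        r=stats.r,
        F=stats.F,
        s=stats.s,
        fitted=tuple(fitted),
        residuals=stats.residuals,
        std_errors=tuple(se),
        row_names=tuple(r.name for r in rows),
        source="refit",
    )


def pearson_matrix(dataset: QsprDataset, columns: Sequence[str] | None = None) -> "pd.DataFrame":
    """Pairwise descriptor correlation magnitudes (|Pearson r|), diagonal 1."""
    import pandas as pd

    columns = tuple(columns) if columns is not None else INDEX_COLUMNS
    frame = dataset.to_frame()[list(columns)]
    if len(frame) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    constant = [c for c in columns if np.isclose(frame[c].std(), 0.0)]
    if constant:
        raise DegenerateInputError(f"correlation undefined for constant column(s) {constant}")
    return frame.corr(method="pearson").abs()
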