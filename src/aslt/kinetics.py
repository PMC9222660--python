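"""Zero- and first-order degradation kinetics.

Zero order models a quality index as A(t) = A0 − k·t; first order as
A(t) = A0·exp(−k·t). Both are fitted by ordinary least squares — first order on
the log scale — so the estimates are closed-form and deterministic. The stored
rate constant is signed so that indices that decay during storage carry k > 0
and indices that accumulate (total acid) carry k < 0, the convention used when
tabulating rate constants per temperature.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import QualityIndexSeries
from .errors import DegenerateFitError, DomainError, InsufficientDataError


class Order(str, enum.Enum):
    ZERO = "zero"
    FIRST = "first"


@dataclass(frozen=True)
class KineticFit:
    """Result of fitting one kinetic order to one series."""

    order: Order
    A0_hat: float
    k_hat: float
    R2: float
    RMSE: float
    n: int
    residuals: np.ndarray

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if self.order is Order.ZERO:
            return self.A0_hat - self.k_hat * t
        return self.A0_hat * np.exp(-self.k_hat * t)


def _fit_data(series: QualityIndexSeries, use_means: bool) -> tuple[np.ndarray, np.ndarray]:
    """Return (t, A) pairs to fit: per-time means, or expanded replicates."""
    if use_means or series.replicate_values is None:
        return series.times_d, series.values
    t = np.repeat(series.times_d, series.n_replicates)
    a = series.replicate_values.ravel()
    return t, a


def _diagnostics(a: np.ndarray, fitted: np.ndarray) -> tuple[float, float, np.ndarray]:
    residuals = a - fitted
    sse = float(np.sum(residuals**2))
    sst = float(np.sum((a - a.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateFitError("response has zero variance; R² undefined")
    # RMSE uses n, not n - p, in the denominator.
    rmse = float(np.sqrt(sse / len(a)))
    return 1.0 - sse / sst, rmse, residuals


def fit_zero_order(series: QualityIndexSeries, use_means: bool = True) -> KineticFit:
    """OLS fit of A = A0 − k·t; k_hat is minus the slope."""
    t, a = _fit_data(series, use_means)
    if len(np.unique(t)) < 3:
        raise InsufficientDataError("zero-order fit needs >= 3 distinct time points")
    res = stats.linregress(t, a)
    fitted = res.intercept + res.slope * t
    r2, rmse, residuals = _diagnostics(a, fitted)
    return KineticFit(
        order=Order.ZERO,
        A0_hat=float(res.intercept),
        k_hat=float(-res.slope),
        R2=r2,
        RMSE=rmse,
        n=len(a),
        residuals=residuals,
    )


def fit_first_order(series: QualityIndexSeries, use_means: bool = True) -> KineticFit:
    """Log-linear OLS fit of A = A0·e^(−k·t); diagnostics on the original scale."""
    t, a = _fit_data(series, use_means)
    if len(np.unique(t)) < 3:
        raise InsufficientDataError("first-order fit needs >= 3 distinct time points")
    bad = np.flatnonzero(a <= 0)
    if bad.size:
        raise DomainError(
            f"first-order kinetics needs positive values; offending time point "
            f"t={t[bad[0]]} (A={a[bad[0]]})"
        )
    res = stats.linregress(t, np.log(a))
    a0 = float(np.exp(res.intercept))
    k = float(-res.slope)
    fitted = a0 * np.exp(-k * t)
    r2, rmse, residuals = _diagnostics(a, fitted)
    return KineticFit(
        order=Order.FIRST, A0_hat=a0, k_hat=k, R2=r2, RMSE=rmse, n=len(a),
        residuals=residuals,
    )


def select_order(zero_fit: KineticFit, first_fit: KineticFit) -> Order:
    """Pick the order with the larger R²; ties go to the zero-order model."""
    if zero_fit.order is not Order.ZERO or first_fit.order is not Order.FIRST:
        raise DomainError("select_order expects a zero-order and a first-order fit")
    if zero_fit.n != first_fit.n:
        raise DomainError("fits being compared were made on different data")
    return Order.FIRST if first_fit.R2 > zero_fit.R2 else Order.ZERO


def fit_both(series: QualityIndexSeries, use_means: bool = True) -> dict:
    """Fit both orders (first order only where all values are positive)."""
    out: dict = {"zero": fit_zero_order(series, use_means)}
    try:
        out["first"] = fit_first_order(series, use_means)
        out["selected"] = select_order(out["zero"], out["first"]).value
    except DomainError:
        out["first"] = None
        out["selected"] = Order.ZERO.value
    return out
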