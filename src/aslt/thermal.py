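"""Temperature dependence of rate constants: Arrhenius and Eyring models.

The Arrhenius model is handled in two equivalent parameterizations:

* reference-centered: ln k = ln k_ref − (Ea/R)·(1/T − 1/T_ref), where T_ref is
  the mean study temperature;
* classic: k = A·exp(−Ea/(R·T)) with pre-exponential factor A.

They are linked by A = k_ref·exp(Ea/(R·T_ref)); both are carried on every fit.

The Eyring (transition-state) model regresses ln(k/T) on 1/T: the slope gives
the activation enthalpy ΔH* and the intercept, via ln(kB/h), the activation
entropy ΔS*. Under the "day" units convention k stays in d⁻¹ while kB/h keeps
its SI value — dimensionally inconsistent but the convention this analysis
tabulates; the SI convention (k converted to s⁻¹) shifts ΔS* by exactly
R·ln(86400).

Fits always use |k|: the sign of a rate constant encodes the direction of
change of the index and is reattached downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .constants import H_PLANCK, K_BOLTZMANN, R_GAS, SECONDS_PER_DAY
from .errors import DomainError, InsufficientDataError


class FitForm(str, enum.Enum):
    LOG_LINEAR = "log_linear"
    NONLINEAR = "nonlinear"


class EyringConvention(str, enum.Enum):
    #: k in d⁻¹ against kB/h in SI units (the tabulated convention)
    DAY = "day"
    #: k converted to s⁻¹ before fitting
    SI = "si"


@dataclass(frozen=True)
class RatePoint:
    """A rate constant at one storage temperature; |k| is what gets fitted."""

    temperature_K: float
    k: float

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise DomainError("temperature must be positive kelvin")
        if self.k == 0:
            raise DomainError("a zero rate constant cannot enter a log-scale fit")


@dataclass(frozen=True)
class ArrheniusFit:
    Ea: float  # J/mol
    kref_at_Tref: float  # rate at Tref, same units as the input k
    A_classic: float  # pre-exponential factor
    Tref_K: float
    form: FitForm
    R2: float
    RMSE: float  # on the ln k scale

    def rate(self, T: float | np.ndarray) -> float | np.ndarray:
        T = np.asarray(T, dtype=float)
        out = self.kref_at_Tref * np.exp(-self.Ea / R_GAS * (1.0 / T - 1.0 / self.Tref_K))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EyringFit:
    dH: float  # ΔH*, J/mol
    dS: float  # ΔS*, J/(mol·K)
    convention: EyringConvention
    R2: float
    RMSE: float  # on the ln(k/T) scale

    def rate(self, T: float | np.ndarray) -> float | np.ndarray:
        """Evaluate k(T) = T·exp(−ΔH*/(R·T) + ln(kB/h) + ΔS*/R)."""
        T = np.asarray(T, dtype=float)
        lnk = (
            np.log(T)
            - self.dH / (R_GAS * T)
            + np.log(K_BOLTZMANN / H_PLANCK)
            + self.dS / R_GAS
        )
        out = np.exp(lnk)
        if self.convention is EyringConvention.SI:
            out = out * SECONDS_PER_DAY  # back to d⁻¹
        return float(out) if out.ndim == 0 else out


def compute_tref(temps_K: Sequence[float]) -> float:
    """Reference temperature: the arithmetic mean of the study temperatures."""
    temps = np.asarray(temps_K, dtype=float)
    if temps.size == 0:
        raise InsufficientDataError("no temperatures supplied")
    return float(temps.mean())


def _check_points(points: Sequence[RatePoint]) -> tuple[np.ndarray, np.ndarray]:
    temps = np.array([p.temperature_K for p in points], dtype=float)
    ks = np.abs(np.array([p.k for p in points], dtype=float))
    if len(np.unique(temps)) < 2:
        raise InsufficientDataError(
            "Arrhenius/Eyring fits need rates at >= 2 distinct temperatures"
        )
    return temps, ks


def _lnscale_diagnostics(y: np.ndarray, fitted: np.ndarray) -> tuple[float, float]:
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    return r2, float(np.sqrt(sse / len(y)))


def fit_arrhenius(
    points: Sequence[RatePoint],
    Tref_K: float | None = None,
    form: FitForm = FitForm.LOG_LINEAR,
) -> ArrheniusFit:
    """Fit ln k = ln k_ref − (Ea/R)(1/T − 1/T_ref).

    The log-linear form is a closed-form OLS on the transformed variables; the
    nonlinear form refines it by least squares on k itself, initialized from
    the log-linear solution.
    """
    temps, ks = _check_points(points)
    if Tref_K is None:
        Tref_K = compute_tref(temps)
    x = 1.0 / temps - 1.0 / Tref_K
    y = np.log(ks)
    res = stats.linregress(x, y)
    ea = float(-res.slope * R_GAS)
    kref = float(np.exp(res.intercept))
    if form is FitForm.NONLINEAR:
        def model(T, kref_, ea_):
            return kref_ * np.exp(-ea_ / R_GAS * (1.0 / T - 1.0 / Tref_K))

        (kref, ea), _ = optimize.curve_fit(model, temps, ks, p0=[kref, ea], maxfev=10000)
        kref, ea = float(kref), float(ea)
    fitted = np.log(kref) - ea / R_GAS * x
    r2, rmse = _lnscale_diagnostics(y, fitted)
    return ArrheniusFit(
        Ea=ea,
        kref_at_Tref=kref,
        A_classic=kref * float(np.exp(ea / (R_GAS * Tref_K))),
        Tref_K=float(Tref_K),
        form=form,
        R2=r2,
        RMSE=rmse,
    )


def fit_eyring(
    points: Sequence[RatePoint],
    convention: EyringConvention = EyringConvention.DAY,
) -> EyringFit:
    """Fit ln(k/T) = −(ΔH*/R)(1/T) + ln(kB/h) + ΔS*/R by OLS."""
    temps, ks = _check_points(points)
    if convention is EyringConvention.SI:
        ks = ks / SECONDS_PER_DAY
    x = 1.0 / temps
    y = np.log(ks / temps)
    res = stats.linregress(x, y)
    dh = float(-res.slope * R_GAS)
    ds = float(R_GAS * (res.intercept - np.log(K_BOLTZMANN / H_PLANCK)))
    fitted = res.intercept + res.slope * x
    r2, rmse = _lnscale_diagnostics(y, fitted)
    return EyringFit(dH=dh, dS=ds, convention=convention, R2=r2, RMSE=rmse)


def entropy_from_point(dH: float, k: float, T: float) -> float:
    """ΔS* implied by one (k, T) pair and a known ΔH*.

    Solves the Eyring relation at a single point:
    ΔS* = R·[ln(k/T) + ΔH*/(R·T) − ln(kB/h)], with k in d⁻¹ (day convention).
    """
    if k <= 0 or T <= 0:
        raise DomainError("k and T must be positive")
    return float(
        R_GAS * (np.log(k / T) + dH / (R_GAS * T) - np.log(K_BOLTZMANN / H_PLANCK))
    )


def predict_rate(fit: ArrheniusFit | EyringFit, T: float) -> float:
    """Evaluate a fitted temperature model at T (kelvin)."""
    if T <= 0:
        raise DomainError("temperature must be positive kelvin")
    return float(fit.rate(T))
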