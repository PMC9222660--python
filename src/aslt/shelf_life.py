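"""Shelf-life prediction from combined zero-order + Arrhenius models.

Each quality index carries a prediction model (A0, kref, Ea, direction): the
index evolves as A(T, t) = A0 ∓ k(T)·t with the classic Arrhenius rate
k(T) = kref·exp(−Ea/(R·T)) (minus for indices that decay, plus for indices
that accumulate, e.g. total acid). Inverting at a critical value A_c gives the
shelf-life t = |A0 − A_c| / k(T). Evaluating all models at the shelf-life of a
chosen reference index yields the end-of-shelf-life critical values of the
remaining indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .constants import R_GAS
from .datamodel import Direction, QualityIndexSeries
from .errors import DomainError, InsufficientDataError


@dataclass(frozen=True)
class PredictionModel:
    """Per-index (A0, kref, Ea, direction) tuple; kref is the classic
    pre-exponential factor in d⁻¹-scaled index units and Ea is in J/mol."""

    index_name: str
    A0: float
    kref: float
    Ea: float
    direction: Direction

    def __post_init__(self) -> None:
        if self.kref <= 0 or self.Ea <= 0:
            raise DomainError("kref and Ea must be positive")

    def rate(self, T: float) -> float:
        """k(T) = kref·exp(−Ea/(R·T))."""
        if T <= 0:
            raise DomainError("temperature must be positive kelvin")
        return float(self.kref * np.exp(-self.Ea / (R_GAS * T)))


@dataclass(frozen=True)
class ShelfLifeEstimate:
    index_name: str
    temperature_K: float
    critical_value: float
    t_days: float


def predict_quality(model: PredictionModel, T: float, t: float) -> float:
    """Quality value after t days at temperature T."""
    if t < 0:
        raise DomainError("storage time must be >= 0")
    sign = -1.0 if model.direction is Direction.DECREASING else 1.0
    return model.A0 + sign * model.rate(T) * t


def invert_shelf_life(
    model: PredictionModel, T: float, critical: float
) -> ShelfLifeEstimate:
    """Days until the index reaches the critical value at temperature T."""
    if model.direction is Direction.DECREASING and critical > model.A0:
        raise DomainError(
            f"critical value {critical} above initial value {model.A0} "
            f"for decreasing index {model.index_name!r}"
        )
    if model.direction is Direction.INCREASING and critical < model.A0:
        raise DomainError(
            f"critical value {critical} below initial value {model.A0} "
            f"for increasing index {model.index_name!r}"
        )
    k = model.rate(T)
    if k == 0.0:
        raise DomainError("rate is zero; the critical value is unreachable")
    t = abs(model.A0 - critical) / k
    return ShelfLifeEstimate(
        index_name=model.index_name,
        temperature_K=float(T),
        critical_value=float(critical),
        t_days=float(t),
    )


def critical_values_at(
    models: Iterable[PredictionModel], T: float, t: float
) -> dict[str, float]:
    """Predicted value of every index after t days at T (index → value)."""
    models = list(models)
    if not models:
        raise InsufficientDataError("no prediction models supplied")
    return {m.index_name: predict_quality(m, T, t) for m in models}


def consensus_check(
    estimates: Sequence[ShelfLifeEstimate], tolerance: float = 0.15
) -> tuple[bool, float]:
    """Do shelf-lives from different indices agree?

    Returns (pass, spread) with spread = (max − min)/max over t_days; the check
    passes when the spread is within the tolerance (default 15%).
    """
    if not estimates:
        raise InsufficientDataError("no shelf-life estimates supplied")
    temps = {round(e.temperature_K, 9) for e in estimates}
    if len(temps) > 1:
        raise DomainError("consensus_check requires estimates at one temperature")
    days = np.array([e.t_days for e in estimates], dtype=float)
    spread = float((days.max() - days.min()) / days.max()) if days.max() > 0 else 0.0
    return spread <= tolerance, spread


def percent_change(
    series: QualityIndexSeries, mode: str = "first_to_last"
) -> float:
    """Percent change of a series relative to its initial mean.

    mode="first_to_last" compares day 0 to the final time point;
    mode="first_to_extreme" compares to the mean furthest from the initial one.
    """
    a = series.values
    first = a[0]
    if first == 0:
        raise DomainError("initial value is zero; percent change undefined")
    if mode == "first_to_last":
        ref = a[-1]
    elif mode == "first_to_extreme":
        ref = a[int(np.argmax(np.abs(a - first)))]
    else:
        raise DomainError(f"unknown mode {mode!r}")
    return float(100.0 * (first - ref) / first)
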