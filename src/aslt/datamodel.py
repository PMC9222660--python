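"""Core domain types for the shelf-life study.

A study measures a handful of quality indices (texture, CIELAB color, total
acid, sensory score) on product stored isothermally at several temperatures,
alongside e-tongue taste profiles and NIR absorbance spectra. Each type here is
a plain frozen dataclass holding numpy arrays; all temperatures are kelvin
internally and storage times are days.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError


class Direction(str, enum.Enum):
    """Declared monotone trend of a quality index during storage.

    This is metadata, not inferred from the (noisy) data: hardness, lightness
    and sensory score decrease during storage while total acid increases.
    """

    DECREASING = "decreasing"
    INCREASING = "increasing"


class Component(str, enum.Enum):
    """Which part of the product a series was measured on."""

    RADISH = "radish"
    VEGETABLE = "vegetable"
    WHOLE = "whole"


@dataclass(frozen=True)
class QualityIndexSeries:
    """One quality index followed over storage time at one temperature.

    values/sds are per-time means and standard deviations over replicates
    (units: gf for hardness/chewiness, dimensionless for L*/a*/b*/ΔE, g/kg for
    total acid, score points for sensory score).
    """

    index_name: str
    component: Component
    temperature_K: float
    times_d: np.ndarray
    values: np.ndarray
    sds: np.ndarray
    n_replicates: int
    direction: Direction
    replicate_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times_d, dtype=float)
        values = np.asarray(self.values, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        object.__setattr__(self, "times_d", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sds", sds)
        if times.ndim != 1 or len(times) == 0:
            raise ConfigError("times_d must be a non-empty 1-D array")
        if times[0] < 0:
            raise ConfigError("storage times must start at or after day 0")
        if np.any(np.diff(times) <= 0):
            raise ConfigError("times_d must be strictly increasing")
        if not (len(times) == len(values) == len(sds)):
            raise ConfigError("times_d, values and sds must have equal length")
        if np.any(sds < 0):
            raise ConfigError("standard deviations must be non-negative")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.replicate_values is not None:
            reps = np.asarray(self.replicate_values, dtype=float)
            if reps.shape != (len(times), self.n_replicates):
                raise ConfigError(
                    "replicate_values must have shape (n_times, n_replicates)"
                )
            object.__setattr__(self, "replicate_values", reps)

    def __len__(self) -> int:
        return len(self.times_d)

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.index_name, self.component.value, float(self.temperature_K))


@dataclass(frozen=True)
class ETongueProfile:
    """One e-tongue measurement: a named vector of taste-sensor responses."""

    sample_id: str
    temperature_K: float
    storage_day: float
    attributes: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.attributes) < 2:
            raise ConfigError("an e-tongue profile needs at least two attributes")
        if self.storage_day < 0:
            raise ConfigError("storage_day must be >= 0")

    @property
    def attribute_names(self) -> list[str]:
        return list(self.attributes)

    def vector(self, order: list[str] | None = None) -> np.ndarray:
        names = order if order is not None else self.attribute_names
        return np.array([self.attributes[n] for n in names], dtype=float)


@dataclass(frozen=True)
class NIRSpectrum:
    """A near-infrared absorbance spectrum on a 900–1600 nm grid."""

    sample_id: str
    wavelengths_nm: np.ndarray
    absorbances: np.ndarray
    storage_day: float
    total_acid: float | None = None
    temperature_K: float | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorbances", ab)
        if len(wl) != len(ab):
            raise ConfigError("wavelength and absorbance grids differ in length")
        if np.any(np.diff(wl) <= 0):
            raise ConfigError("wavelengths must be strictly increasing")
        if wl[0] < 900.0 - 1e-9 or wl[-1] > 1600.0 + 1e-9:
            raise ConfigError("wavelengths must lie within [900, 1600] nm")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)


class PeriodLabel(enum.IntEnum):
    """Acceptability period of a stored sample, in storage order."""

    FULLY_ACCEPTABLE = 0
    ACCEPTABLE = 1
    UNACCEPTABLE = 2


@dataclass(frozen=True)
class PeriodBoundaries:
    """Per-temperature day boundaries between acceptability periods.

    [0, b1] is fully acceptable, (b1, b2] acceptable, (b2, b3] unacceptable,
    where b3 is the end of the study at that temperature.
    """

    temperature_K: float
    b1: float
    b2: float
    b3: float

    def __post_init__(self) -> None:
        if not (0 < self.b1 < self.b2 <= self.b3):
            raise ConfigError("boundaries must satisfy 0 < b1 < b2 <= b3")

    def label(self, day: float) -> PeriodLabel:
        if day < 0 or day > self.b3:
            raise DomainError(
                f"day {day} outside the study range [0, {self.b3}]"
            )
        if day <= self.b1:
            return PeriodLabel.FULLY_ACCEPTABLE
        if day <= self.b2:
            return PeriodLabel.ACCEPTABLE
        return PeriodLabel.UNACCEPTABLE
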