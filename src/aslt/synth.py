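"""Synthetic accelerated-storage study generator.

Emulates the study design end to end so every pipeline stage is testable
without real data: three storage temperatures (25/35/45 °C) followed for
336/154/84 days sampled every 56/14/7 days with 10 replicates per point;
quality indices decaying (or accumulating, for total acid) as
A(T, t) = A0 ∓ kref·exp(−Ea/(R·T))·t with Gaussian replicate noise; e-tongue
taste clusters for the three acceptability periods with sourness rising and
umami falling across periods; and NIR spectra built from a sloped baseline
plus water/organic absorption bands near 960/1150/1450 nm whose amplitudes
grow affinely with storage day and total acid.

A series is truncated after the last time point whose true mean is still above
the index's scale floor (sensory scores stop at 1, physical indices at 0), the
way a real panel stops scoring a spoiled product; replicate draws are clipped
to the same scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .constants import R_GAS
from .datamodel import (
    Component,
    Direction,
    ETongueProfile,
    NIRSpectrum,
    PeriodBoundaries,
    PeriodLabel,
    QualityIndexSeries,
)
from .errors import ConfigError
from . import io as aslt_io


@dataclass(frozen=True)
class TrueIndexParams:
    """Ground-truth kinetic parameters for one simulated quality index."""

    index_name: str
    component: Component
    A0: float
    A_classic: float  # classic Arrhenius pre-exponential factor
    Ea: float  # J/mol
    direction: Direction
    noise_sd: float  # replicate sd in index units (absolute-noise mode)
    floor: float = 0.0
    ceiling: float = np.inf

    def rate(self, T: float) -> float:
        return self.A_classic * np.exp(-self.Ea / (R_GAS * T))

    def mean(self, T: float, t: np.ndarray) -> np.ndarray:
        sign = -1.0 if self.direction is Direction.DECREASING else 1.0
        return self.A0 + sign * self.rate(T) * np.asarray(t, dtype=float)


def default_true_indices() -> list[TrueIndexParams]:
    """The six study indices with their fitted constants as ground truth.

    Replicate noise defaults to the scale of the dispersions observed in the
    study (hardness sd ≈ 70/40 gf, L* ≈ 2.8, total acid ≈ 0.2 g/kg,
    sensory ≈ 0.3 points)."""
    return [
        TrueIndexParams("total_acid", Component.WHOLE, 4.96, 1.076e6, 47.23e3,
                        Direction.INCREASING, 0.20),
        TrueIndexParams("L*", Component.RADISH, 58.57, 1.147e10, 65.18e3,
                        Direction.DECREASING, 2.8),
        TrueIndexParams("L*", Component.VEGETABLE, 49.22, 9.220e10, 72.09e3,
                        Direction.DECREASING, 2.8),
        TrueIndexParams("hardness", Component.RADISH, 763.28, 2.221e8, 45.76e3,
                        Direction.DECREASING, 70.0),
        TrueIndexParams("hardness", Component.VEGETABLE, 277.87, 9.673e9, 58.10e3,
                        Direction.DECREASING, 40.0),
        TrueIndexParams("sensory_score", Component.WHOLE, 8.11, 3.412e10, 70.07e3,
                        Direction.DECREASING, 0.3, floor=1.0, ceiling=9.0),
    ]


#: Per-period e-tongue attribute means (fully acceptable → unacceptable).
#: Sourness rises and umami falls across periods; the other four sensors stay
#: flat, as observed.
DEFAULT_ETONGUE_MEANS: dict[str, tuple[float, float, float]] = {
    "sourness": (14.79, 16.00, 17.50),
    "astringency": (1.20, 1.20, 1.20),
    "aftertaste_A": (0.40, 0.40, 0.40),
    "umami": (2.03, 1.70, 1.31),
    "richness": (2.50, 2.50, 2.50),
    "saltiness": (6.00, 6.00, 6.00),
}

DEFAULT_ETONGUE_SDS: dict[str, float] = {
    "sourness": 0.30,
    "astringency": 0.15,
    "aftertaste_A": 0.08,
    "umami": 0.08,
    "richness": 0.20,
    "saltiness": 0.25,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters; defaults are the study conditions."""

    temperatures_K: tuple[float, ...] = (298.15, 308.15, 318.15)
    durations_d: tuple[float, ...] = (336.0, 154.0, 84.0)
    sampling_intervals_d: tuple[float, ...] = (56.0, 14.0, 7.0)
    replicates: int = 10
    indices: tuple[TrueIndexParams, ...] = field(
        default_factory=lambda: tuple(default_true_indices())
    )
    #: when set, replicate sd = noise_rel · |true mean| instead of noise_sd
    noise_rel: float | None = None
    #: e-tongue measurements per sampling day
    etongue_replicates: int = 3
    #: within-period correlation shared by all taste sensors (common-factor
    #: structure; e-tongue channels drift together on real instruments)
    etongue_corr: float = 0.6
    etongue_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ETONGUE_MEANS)
    )
    etongue_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETONGUE_SDS)
    )
    nir_samples: int = 90
    nir_grid_nm: tuple[float, float, float] = (900.0, 1600.0, 5.0)
    nir_peak_centers_nm: tuple[float, ...] = (960.0, 1150.0, 1450.0)
    nir_peak_widths_nm: tuple[float, ...] = (25.0, 40.0, 45.0)
    nir_noise_rel: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            len(self.temperatures_K)
            == len(self.durations_d)
            == len(self.sampling_intervals_d)
        ):
            raise ConfigError("temperatures, durations and intervals must align")
        for d, s in zip(self.durations_d, self.sampling_intervals_d):
            if s <= 0 or d <= 0 or (d / s) % 1 != 0:
                raise ConfigError("each duration must be divisible by its interval")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if any(sd < 0 for sd in self.etongue_sds.values()):
            raise ConfigError("e-tongue sds must be non-negative")
        if self.noise_rel is not None and self.noise_rel < 0:
            raise ConfigError("noise_rel must be non-negative")
        if not 0.0 <= self.etongue_corr < 1.0:
            raise ConfigError(
                "etongue_corr must lie in [0, 1) for a positive-definite covariance"
            )
        if set(self.etongue_means) != set(self.etongue_sds):
            raise ConfigError("etongue means and sds must cover the same attributes")

    def sampling_days(self, temp_K: float) -> np.ndarray:
        i = self.temperatures_K.index(temp_K)
        return np.arange(
            0.0, self.durations_d[i] + 1e-9, self.sampling_intervals_d[i]
        )

    def default_bounds(self) -> list[PeriodBoundaries]:
        """Acceptability-period boundaries at the accelerated temperatures."""
        return [
            PeriodBoundaries(318.15, 28.0, 56.0, 84.0),
            PeriodBoundaries(308.15, 42.0, 126.0, 154.0),
        ]


def gen_quality_study(config: SimulationConfig) -> list[QualityIndexSeries]:
    """Simulate every quality index at every storage temperature."""
    rng = np.random.default_rng(config.seed)
    out = []
    for params in config.indices:
        for temp in config.temperatures_K:
            days = config.sampling_days(temp)
            means = params.mean(temp, days)
            # stop recording once the true mean leaves the index's scale
            keep = (means > params.floor) & (means < params.ceiling)
            keep[0] = True
            n_keep = int(np.flatnonzero(keep).max()) + 1
            days, means = days[:n_keep], means[:n_keep]
            sd = (
                config.noise_rel * np.abs(means)
                if config.noise_rel is not None
                else np.full_like(means, params.noise_sd)
            )
            reps = means[:, None] + rng.standard_normal(
                (len(days), config.replicates)
            ) * sd[:, None]
            reps = np.clip(reps, params.floor, params.ceiling)
            if config.noise_rel == 0 or (
                config.noise_rel is None and params.noise_sd == 0
            ):
                values, sds = means, np.zeros_like(means)
            else:
                values = reps.mean(axis=1)
                sds = reps.std(axis=1, ddof=1)
            out.append(
                QualityIndexSeries(
                    index_name=params.index_name,
                    component=params.component,
                    temperature_K=temp,
                    times_d=days,
                    values=values,
                    sds=sds,
                    n_replicates=config.replicates,
                    direction=params.direction,
                    replicate_values=reps,
                )
            )
    return out


def gen_etongue_study(
    config: SimulationConfig, bounds: list[PeriodBoundaries] | None = None
) -> tuple[list[ETongueProfile], list[PeriodLabel]]:
    """Simulate e-tongue profiles with period-structured taste clusters.

    Each sampling day at each bounded temperature yields
    ``config.etongue_replicates`` profiles drawn from the period's multivariate
    normal (diagonal covariance); the true period labels are returned alongside.
    """
    if bounds is None:
        bounds = config.default_bounds()
    rng = np.random.default_rng(config.seed + 1)
    attrs = list(config.etongue_means)
    profiles, labels = [], []
    for b in bounds:
        days = config.sampling_days(b.temperature_K)
        days = days[days <= b.b3]
        for day in days:
            label = b.label(day)
            mu = np.array([config.etongue_means[a][int(label)] for a in attrs])
            sd = np.array([config.etongue_sds[a] for a in attrs])
            # equicorrelated noise: common factor + independent channel noise
            rho = config.etongue_corr
            for r in range(config.etongue_replicates):
                common = rng.standard_normal()
                own = rng.standard_normal(len(attrs))
                vec = mu + sd * (np.sqrt(rho) * common + np.sqrt(1.0 - rho) * own)
                profiles.append(
                    ETongueProfile(
                        sample_id=f"T{b.temperature_K:.0f}_d{day:.0f}_r{r + 1}",
                        temperature_K=b.temperature_K,
                        storage_day=float(day),
                        attributes=dict(zip(attrs, vec)),
                    )
                )
                labels.append(label)
    return profiles, labels


def gen_nir_study(
    config: SimulationConfig, quality: list[QualityIndexSeries] | None = None
) -> list[NIRSpectrum]:
    """Simulate NIR spectra tied to the total-acid kinetics.

    Storage days are drawn uniformly over the hottest storage duration; total
    acid follows its true kinetic mean at that temperature. Peak amplitudes
    are affine in day and total acid, and multiplicative noise (default 2%)
    is applied to the whole spectrum.
    """
    acid_params = next(
        (p for p in config.indices if p.index_name == "total_acid"), None
    )
    if quality is not None:
        present = {s.index_name for s in quality}
        if "total_acid" not in present:
            raise ConfigError("quality set contains no total-acid series")
    if acid_params is None:
        raise ConfigError("config carries no total-acid index parameters")
    rng = np.random.default_rng(config.seed + 2)
    temp = max(config.temperatures_K)
    duration = config.durations_d[config.temperatures_K.index(temp)]
    lo, hi, step = config.nir_grid_nm
    wl = np.arange(lo, hi + 1e-9, step)
    spectra = []
    for i in range(config.nir_samples):
        day = float(rng.uniform(0.0, duration))
        acid = float(acid_params.mean(temp, np.array([day]))[0])
        baseline = 0.20 + 1e-4 * (wl - wl[0])
        amps = (
            0.30 + 0.004 * day,
            0.20 + 0.003 * day + 0.05 * acid,
            0.50 + 0.006 * day + 0.10 * acid,
        )
        ab = baseline.copy()
        for a, c, w in zip(amps, config.nir_peak_centers_nm, config.nir_peak_widths_nm):
            ab = ab + a * np.exp(-0.5 * ((wl - c) / w) ** 2)
        ab = ab * (1.0 + config.nir_noise_rel * rng.standard_normal(len(wl)))
        spectra.append(
            NIRSpectrum(
                sample_id=f"nir_{i:03d}",
                wavelengths_nm=wl,
                absorbances=ab,
                storage_day=day,
                total_acid=acid,
                temperature_K=temp,
            )
        )
    return spectra


def gen_full_bundle(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a complete simulated study to ``out_dir``.

    Produces ``quality.csv`` (replicate-level), ``etongue.csv``, ``spectra/``
    with a manifest, and ``truth.json`` holding every true parameter; returns
    the manifest of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    quality = gen_quality_study(config)
    profiles, labels = gen_etongue_study(config)
    spectra = gen_nir_study(config, quality)

    quality_path = out_dir / "quality.csv"
    aslt_io.write_quality_replicates(quality, quality_path)
    etongue_path = out_dir / "etongue.csv"
    aslt_io.write_etongue_table(profiles, etongue_path)
    manifest_path = aslt_io.write_spectra(spectra, out_dir / "spectra")

    truth = {
        "seed": config.seed,
        "indices": [
            {
                "index": p.index_name,
                "component": p.component.value,
                "A0": p.A0,
                "A_classic": p.A_classic,
                "Ea": p.Ea,
                "direction": p.direction.value,
            }
            for p in config.indices
        ],
        "etongue_labels": [int(l) for l in labels],
        "etongue_means": config.etongue_means,
        "nir_peak_centers_nm": list(config.nir_peak_centers_nm),
    }
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {
        "quality": str(quality_path),
        "etongue": str(etongue_path),
        "spectra_manifest": str(manifest_path),
        "truth": str(truth_path),
    }
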