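"""End-to-end orchestration: kinetics → thermal models → shelf-life, plus the
taste-classification and NIR-ANN stages, with machine-readable JSON reports.

Each stage consumes the previous stage's report (or packaged fixtures) and
writes a JSON document with a ``schema_version`` field; reports are plain
dictionaries so the CLI, the analysis scripts and the tests share one code
path. Reports are deterministic given the same inputs and seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ann import ANNConfig, train_bpann
from .constants import celsius_to_kelvin
from .datamodel import Direction, PeriodBoundaries, QualityIndexSeries
from .errors import AsltError, ConfigError
from .fixtures import load_prediction_models
from .io import read_etongue_table, read_quality_table, read_spectra
from .kinetics import fit_both
from .shelf_life import (
    PredictionModel,
    consensus_check,
    critical_values_at,
    invert_shelf_life,
)
from .taste import accuracy_table, run_fda
from .thermal import (
    EyringConvention,
    RatePoint,
    compute_tref,
    fit_arrhenius,
    fit_eyring,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def _series_label(s: QualityIndexSeries) -> dict:
    return {"index": s.index_name, "component": s.component.value}


def kinetics_report(series_set: list[QualityIndexSeries], use_means: bool = True) -> dict:
    """Fit both kinetic orders to every series; mirrors the per-temperature
    rate-constant table (signed k, R², RMSE, selected order)."""
    rows = []
    for s in series_set:
        fits = fit_both(s, use_means=use_means)
        row = {
            **_series_label(s),
            "temp_C": round(s.temperature_K - 273.15, 6),
            "direction": s.direction.value,
            "selected": fits["selected"],
        }
        for order in ("zero", "first"):
            f = fits[order]
            row[order] = (
                None
                if f is None
                else {
                    "k": f.k_hat,
                    "A0": f.A0_hat,
                    "R2": f.R2,
                    "RMSE": f.RMSE,
                    "n": f.n,
                }
            )
        rows.append(row)
        logger.info(
            "kinetics %s/%s %.0f K: selected=%s",
            s.index_name, s.component.value, s.temperature_K, fits["selected"],
        )
    return {"schema_version": SCHEMA_VERSION, "stage": "kinetics", "fits": rows}


def thermal_report(kinetics: dict, model: str = "both") -> dict:
    """Fit Arrhenius/Eyring temperature models to each index's zero-order
    rate constants across temperatures (|k| fitted; sign kept as direction)."""
    groups: dict[tuple[str, str], list[dict]] = {}
    for row in kinetics["fits"]:
        groups.setdefault((row["index"], row["component"]), []).append(row)
    entries = []
    for (idx, comp), rows in groups.items():
        points = [
            RatePoint(celsius_to_kelvin(r["temp_C"]), r["zero"]["k"]) for r in rows
        ]
        temps = [p.temperature_K for p in points]
        tref = compute_tref(temps)
        entry: dict = {
            "index": idx,
            "component": comp,
            "direction": rows[0]["direction"],
            "Tref_K": tref,
            "A0": float(np.mean([r["zero"]["A0"] for r in rows])),
        }
        if model in ("arrhenius", "both"):
            af = fit_arrhenius(points, Tref_K=tref)
            entry["arrhenius"] = {
                "Ea_J_mol": af.Ea,
                "kref_at_Tref": af.kref_at_Tref,
                "A_classic": af.A_classic,
                "R2": af.R2,
                "RMSE": af.RMSE,
            }
        if model in ("eyring", "both"):
            ef = fit_eyring(points, convention=EyringConvention.DAY)
            entry["eyring"] = {
                "dH_J_mol": ef.dH,
                "dS_J_mol_K": ef.dS,
                "R2": ef.R2,
                "RMSE": ef.RMSE,
            }
        entries.append(entry)
    return {"schema_version": SCHEMA_VERSION, "stage": "thermal", "models": entries}


def models_from_thermal(thermal: dict) -> list[PredictionModel]:
    """Turn a thermal report into shelf-life prediction models."""
    models = []
    for e in thermal["models"]:
        if "arrhenius" not in e:
            raise ConfigError("thermal report lacks Arrhenius parameters")
        name = e["index"] if e["component"] == "whole" else f"{e['index']}_{e['component']}"
        models.append(
            PredictionModel(
                index_name=name,
                A0=e["A0"],
                kref=e["arrhenius"]["A_classic"],
                Ea=e["arrhenius"]["Ea_J_mol"],
                direction=Direction(e["direction"]),
            )
        )
    return models


def resolve_models(source: str) -> list[PredictionModel]:
    """``fixtures:table7`` or the path of a thermal-stage JSON report."""
    if source == "fixtures:table7":
        return load_prediction_models()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    return models_from_thermal(json.loads(path.read_text()))


def shelf_life_report(
    models: list[PredictionModel],
    temps_C: list[float],
    criticals: dict[str, float],
    consensus_tolerance: float = 0.15,
) -> dict:
    """Invert each named model at its critical value for every temperature."""
    by_name = {m.index_name: m for m in models}
    unknown = [n for n in criticals if n not in by_name]
    if unknown:
        raise ConfigError(f"no prediction model named {unknown[0]!r}")
    out = []
    for temp_c in temps_C:
        temp_k = celsius_to_kelvin(temp_c)
        ests = [
            invert_shelf_life(by_name[name], temp_k, crit)
            for name, crit in criticals.items()
        ]
        entry = {
            "temp_C": temp_c,
            "shelf_life_days": {
                e.index_name: {"t_days": e.t_days, "critical_value": e.critical_value}
                for e in ests
            },
        }
        if len(ests) > 1:
            ok, spread = consensus_check(ests, tolerance=consensus_tolerance)
            entry["consensus"] = {"pass": ok, "max_relative_spread": spread}
        out.append(entry)
    return {"schema_version": SCHEMA_VERSION, "stage": "shelf_life", "estimates": out}


def critical_values_report(
    models: list[PredictionModel], temp_C: float, days: float
) -> dict:
    values = critical_values_at(models, celsius_to_kelvin(temp_C), days)
    return {
        "schema_version": SCHEMA_VERSION,
        "stage": "critical_values",
        "temp_C": temp_C,
        "days": days,
        "values": values,
    }


def taste_report(
    etongue_path: str | Path,
    bounds_by_temp_C: dict[float, tuple[float, float, float]],
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> dict:
    """Label profiles by their per-temperature period bounds and run FDA per
    temperature, reporting the accuracy tables."""
    profiles = read_etongue_table(etongue_path)
    out = []
    for temp_c, (b1, b2, b3) in sorted(bounds_by_temp_C.items(), reverse=True):
        temp_k = celsius_to_kelvin(temp_c)
        bounds = PeriodBoundaries(temp_k, b1, b2, b3)
        subset = [p for p in profiles if abs(p.temperature_K - temp_k) < 1e-6]
        if not subset:
            continue
        labels = [bounds.label(p.storage_day) for p in subset]
        result = run_fda(subset, labels, train_fraction=train_fraction, seed=seed)
        out.append(
            {
                "temp_C": temp_c,
                "n_samples": len(subset),
                "calibration_accuracy_pct": result.calibration_accuracy_pct,
                "prediction_accuracy_pct": result.prediction_accuracy_pct,
                "table": accuracy_table(result).to_dict(orient="records"),
                "seed": seed,
            }
        )
    return {"schema_version": SCHEMA_VERSION, "stage": "taste", "fda": out}


def ann_report(manifest_path: str | Path, config: ANNConfig) -> dict:
    spectra = read_spectra(manifest_path)
    _, report = train_bpann(spectra, config)
    return {
        "schema_version": SCHEMA_VERSION,
        "stage": "ann",
        "n_samples": report.n_train + report.n_val + report.n_test,
        "split_sizes": [report.n_train, report.n_val, report.n_test],
        "r2": report.r2,
        "final_epoch": report.final_epoch,
        "seed": report.seed,
        "hidden_units": config.hidden_units,
    }


@dataclass
class RunConfig:
    """Configuration for the full pipeline over a simulated or measured study."""

    quality_path: str | Path | None = None
    etongue_path: str | Path | None = None
    spectra_manifest: str | Path | None = None
    out_dir: str | Path = "reports"
    temps_C: list[float] = field(default_factory=lambda: [25.0, 35.0, 45.0])
    criticals: dict[str, float] = field(
        default_factory=lambda: {"sensory_score": 1.0}
    )
    bounds_by_temp_C: dict[float, tuple[float, float, float]] = field(
        default_factory=lambda: {45.0: (28.0, 56.0, 84.0), 35.0: (42.0, 126.0, 154.0)}
    )
    seed: int = 0
    use_means: bool = True
    stages: tuple[str, ...] = ("kinetics", "thermal", "shelf_life", "taste", "ann")


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the enabled stages in order; returns stage → report path.

    Raises AsltError naming the failing stage; reports of completed stages
    stay on disk.
    """
    out_dir = Path(config.out_dir)
    written: dict[str, str] = {}
    stage = "setup"
    try:
        kin = thermo = None
        if "kinetics" in config.stages:
            stage = "kinetics"
            if config.quality_path is None:
                raise ConfigError("kinetics stage needs a quality table path")
            series = read_quality_table(config.quality_path)
            kin = kinetics_report(series, use_means=config.use_means)
            _write_json(kin, out_dir / "kinetics.json")
            written["kinetics"] = str(out_dir / "kinetics.json")
        if "thermal" in config.stages:
            stage = "thermal"
            if kin is None:
                raise ConfigError("thermal stage needs the kinetics stage")
            thermo = thermal_report(kin)
            _write_json(thermo, out_dir / "thermal.json")
            written["thermal"] = str(out_dir / "thermal.json")
        if "shelf_life" in config.stages:
            stage = "shelf_life"
            models = (
                models_from_thermal(thermo) if thermo is not None
                else load_prediction_models()
            )
            criticals = {
                k: v for k, v in config.criticals.items()
                if k in {m.index_name for m in models}
            }
            rep = shelf_life_report(models, config.temps_C, criticals)
            _write_json(rep, out_dir / "shelf_life.json")
            written["shelf_life"] = str(out_dir / "shelf_life.json")
        if "taste" in config.stages and config.etongue_path is not None:
            stage = "taste"
            rep = taste_report(
                config.etongue_path, config.bounds_by_temp_C, seed=config.seed
            )
            _write_json(rep, out_dir / "taste.json")
            written["taste"] = str(out_dir / "taste.json")
        if "ann" in config.stages and config.spectra_manifest is not None:
            stage = "ann"
            rep = ann_report(config.spectra_manifest, ANNConfig(seed=config.seed))
            _write_json(rep, out_dir / "ann.json")
            written["ann"] = str(out_dir / "ann.json")
    except AsltError as exc:
        raise AsltError(f"stage {stage!r} failed: {exc}") from exc
    return written
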