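"""Readers and writers for the study's delimited text formats.

Three canonical long-format layouts, comma-delimited by default (tab accepted):

* quality table — ``index,component,temp_C,day,value[,replicate]`` for
  replicate-level rows, or ``index,component,temp_C,day,mean,sd,n`` for
  pre-aggregated rows;
* e-tongue table — ``sample_id,temp_C,day,<attribute...>``;
* spectra — one two-column file (``wavelength_nm,absorbance``) per sample plus
  a manifest ``sample_id,temp_C,day,total_acid,filename``.

Temperatures in files are °C by default (``celsius=False`` reads kelvin
columns named ``temp_K``); everything is kelvin in memory.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .datamodel import Component, Direction, ETongueProfile, NIRSpectrum, QualityIndexSeries
from .errors import SchemaError, TableParseError

#: Default direction per index; anything not listed decays during storage.
DEFAULT_DIRECTIONS: dict[str, Direction] = {"total_acid": Direction.INCREASING}

_ETONGUE_META = ("sample_id", "temp_C", "temp_K", "day")


def _read_delimited(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing: written values must survive a write/read cycle bit-exactly
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, cols: Iterable[str], path) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            raise TableParseError(
                f"{path}: non-numeric value {df.loc[bad[0], c]!r} in column "
                f"{c!r} at row {int(bad[0]) + 2}"  # +2: header + 1-based
            )
        df[c] = coerced
    return df


def direction_for(index_name: str) -> Direction:
    return DEFAULT_DIRECTIONS.get(index_name, Direction.DECREASING)


def read_quality_table(
    path: str | os.PathLike,
    celsius: bool = True,
    schema: Mapping[str, str] | None = None,
    directions: Mapping[str, Direction] | None = None,
) -> list[QualityIndexSeries]:
    """Read a long-format quality table into one series per
    (index, component, temperature), sorted by storage day.

    ``schema`` optionally maps canonical column names (index, component, day,
    value, ...) to the file's actual column names. Replicate-level rows are
    aggregated to mean/sd (sample sd, ddof=1) with the replicate count
    recorded; pre-aggregated rows (mean/sd/n columns) are taken as-is.
    """
    df = _read_delimited(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    temp_col = "temp_C" if celsius else "temp_K"
    _require_columns(df, ["index", "component", temp_col, "day"], path)
    aggregated = "mean" in df.columns
    if aggregated:
        _require_columns(df, ["mean", "sd", "n"], path)
        df = _numeric(df, [temp_col, "day", "mean", "sd", "n"], path)
    else:
        _require_columns(df, ["value"], path)
        df = _numeric(df, [temp_col, "day", "value"], path)
    df["temperature_K"] = (
        df[temp_col].map(celsius_to_kelvin) if celsius else df[temp_col]
    )

    dirmap = dict(DEFAULT_DIRECTIONS)
    if directions:
        dirmap.update(directions)

    out: list[QualityIndexSeries] = []
    for (idx, comp, temp_k), grp in df.groupby(
        ["index", "component", "temperature_K"], sort=True
    ):
        grp = grp.sort_values("day")
        if aggregated:
            days = grp["day"].to_numpy(float)
            if len(np.unique(days)) != len(days):
                raise TableParseError(
                    f"{path}: duplicate pre-aggregated day in series "
                    f"({idx}, {comp}, {temp_k:g} K)"
                )
            means = grp["mean"].to_numpy(float)
            sds = grp["sd"].to_numpy(float)
            n = int(grp["n"].iloc[0])
            reps = None
        else:
            by_day = grp.groupby("day")["value"]
            days = np.array(sorted(by_day.groups), dtype=float)
            means = by_day.mean().to_numpy(float)
            sds = by_day.std(ddof=1).fillna(0.0).to_numpy(float)
            counts = by_day.count()
            n = int(counts.iloc[0])
            reps = None
            if (counts == n).all():
                reps = np.vstack([
                    by_day.get_group(d).to_numpy(float) for d in sorted(by_day.groups)
                ])
        out.append(
            QualityIndexSeries(
                index_name=str(idx),
                component=Component(str(comp)),
                temperature_K=float(temp_k),
                times_d=days,
                values=means,
                sds=sds,
                n_replicates=n,
                direction=dirmap.get(str(idx), Direction.DECREASING),
                replicate_values=reps,
            )
        )
    return out


def write_quality_table(
    series: Iterable[QualityIndexSeries], path: str | os.PathLike, celsius: bool = True
) -> None:
    """Write series as a pre-aggregated long-format table (mean/sd/n rows)."""
    rows = []
    for s in series:
        temp = kelvin_to_celsius(s.temperature_K) if celsius else s.temperature_K
        for d, m, sd in zip(s.times_d, s.values, s.sds):
            rows.append(
                {
                    "index": s.index_name,
                    "component": s.component.value,
                    ("temp_C" if celsius else "temp_K"): temp,
                    "day": d,
                    "mean": repr(float(m)),
                    "sd": repr(float(sd)),
                    "n": s.n_replicates,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_quality_replicates(
    series: Iterable[QualityIndexSeries], path: str | os.PathLike, celsius: bool = True
) -> None:
    """Write replicate-level rows (requires replicate_values on every series)."""
    rows = []
    for s in series:
        if s.replicate_values is None:
            raise TableParseError(
                f"series {s.key} carries no replicate-level values"
            )
        temp = kelvin_to_celsius(s.temperature_K) if celsius else s.temperature_K
        for i, d in enumerate(s.times_d):
            for r in range(s.n_replicates):
                rows.append(
                    {
                        "index": s.index_name,
                        "component": s.component.value,
                        ("temp_C" if celsius else "temp_K"): temp,
                        "day": d,
                        "value": repr(float(s.replicate_values[i, r])),
                        "replicate": r + 1,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_etongue_table(
    path: str | os.PathLike, celsius: bool = True
) -> list[ETongueProfile]:
    """Read a sample × taste-attribute table."""
    df = _read_delimited(path)
    temp_col = "temp_C" if celsius else "temp_K"
    _require_columns(df, ["sample_id", temp_col, "day"], path)
    attrs = [c for c in df.columns if c not in _ETONGUE_META]
    if len(attrs) < 2:
        raise SchemaError(f"{path}: fewer than two taste-attribute columns")
    df = _numeric(df, [temp_col, "day", *attrs], path)
    out = []
    for _, row in df.iterrows():
        temp_k = celsius_to_kelvin(row[temp_col]) if celsius else row[temp_col]
        out.append(
            ETongueProfile(
                sample_id=str(row["sample_id"]),
                temperature_K=float(temp_k),
                storage_day=float(row["day"]),
                attributes={a: float(row[a]) for a in attrs},
            )
        )
    return out


def write_etongue_table(
    profiles: Iterable[ETongueProfile], path: str | os.PathLike, celsius: bool = True
) -> None:
    profiles = list(profiles)
    rows = []
    for p in profiles:
        temp = kelvin_to_celsius(p.temperature_K) if celsius else p.temperature_K
        rows.append(
            {
                "sample_id": p.sample_id,
                ("temp_C" if celsius else "temp_K"): temp,
                "day": p.storage_day,
                **{k: repr(float(v)) for k, v in p.attributes.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spectra(
    manifest_path: str | os.PathLike, spectra_dir: str | os.PathLike | None = None
) -> list[NIRSpectrum]:
    """Read NIR spectra via a manifest; filenames are relative to the manifest
    directory unless ``spectra_dir`` overrides it."""
    manifest_path = Path(manifest_path)
    df = _read_delimited(manifest_path)
    _require_columns(df, ["sample_id", "day", "filename"], manifest_path)
    base = Path(spectra_dir) if spectra_dir is not None else manifest_path.parent
    out = []
    for _, row in df.iterrows():
        sp = pd.read_csv(base / str(row["filename"]))
        _require_columns(sp, ["wavelength_nm", "absorbance"], row["filename"])
        acid = row.get("total_acid")
        temp = row.get("temp_C")
        out.append(
            NIRSpectrum(
                sample_id=str(row["sample_id"]),
                wavelengths_nm=sp["wavelength_nm"].to_numpy(float),
                absorbances=sp["absorbance"].to_numpy(float),
                storage_day=float(row["day"]),
                total_acid=None if pd.isna(acid) else float(acid),
                temperature_K=None if pd.isna(temp) else celsius_to_kelvin(float(temp)),
            )
        )
    return out


def write_spectra(
    spectra: Iterable[NIRSpectrum], out_dir: str | os.PathLike, celsius: bool = True
) -> Path:
    """Write one CSV per spectrum plus ``manifest.csv``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        fname = f"{s.sample_id}.csv"
        pd.DataFrame(
            {"wavelength_nm": s.wavelengths_nm, "absorbance": s.absorbances}
        ).to_csv(out_dir / fname, index=False)
        rows.append(
            {
                "sample_id": s.sample_id,
                "temp_C": (
                    "" if s.temperature_K is None else kelvin_to_celsius(s.temperature_K)
                ),
                "day": s.storage_day,
                "total_acid": "" if s.total_acid is None else s.total_acid,
                "filename": fname,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
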