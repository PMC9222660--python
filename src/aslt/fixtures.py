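"""Packaged reference tables from the sauerkraut storage study.

Five tables ship with the package, exactly as printed (2-decimal means; no
back-computed replicates):

* ``table1`` — texture means ± sd (hardness/chewiness, radish/vegetable) at
  25/35/45 °C;
* ``table2`` — per-temperature zero/first-order rate constants with R²/RMSE;
* ``table3`` — CIELAB color means ± sd (L*/a*/b*/ΔE);
* ``table6`` — Arrhenius (Ea, kref at the mean study temperature) and Eyring
  (ΔH*, ΔS*) activation parameters;
* ``table7`` — per-index shelf-life prediction constants (A0, classic kref,
  Ea, direction).

``table1``/``table3`` load as :class:`~aslt.datamodel.QualityIndexSeries`;
the fitted-parameter tables load as DataFrames, and :func:`load_prediction_models`
turns ``table7`` into ready-to-use :class:`~aslt.shelf_life.PredictionModel`s.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datamodel import Direction
from .io import read_quality_table
from .shelf_life import PredictionModel

FIXTURE_NAMES = ("table1", "table2", "table3", "table6", "table7")

#: Boundary of each acceptability period (days), per storage temperature °C.
PERIOD_BOUNDS_C = {45: (28.0, 56.0, 84.0), 35: (42.0, 126.0, 154.0)}


def _fixture_path(name: str):
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return resources.files("aslt._tables").joinpath(f"{name}.csv")


def load_fixture(name: str):
    """Load a packaged table.

    ``table1``/``table3`` return a list of QualityIndexSeries; the others
    return a pandas DataFrame with the printed values unchanged.
    """
    path = _fixture_path(name)
    with resources.as_file(path) as p:
        if name in ("table1", "table3"):
            return read_quality_table(p, celsius=True)
        return pd.read_csv(p)


def fixture_series(name: str, index: str, component: str, temp_C: float):
    """Convenience lookup of one series in table1/table3."""
    from .constants import celsius_to_kelvin

    temp_k = celsius_to_kelvin(temp_C)
    for s in load_fixture(name):
        if s.key == (index, component, temp_k):
            return s
    raise KeyError(f"no series ({index}, {component}, {temp_C} °C) in {name}")


def load_prediction_models() -> list[PredictionModel]:
    """The six packaged shelf-life prediction models (table7)."""
    df = load_fixture("table7")
    models = []
    for _, row in df.iterrows():
        name = (
            row["index"]
            if row["component"] == "whole"
            else f"{row['index']}_{row['component']}"
        )
        models.append(
            PredictionModel(
                index_name=name,
                A0=float(row["A0"]),
                kref=float(row["kref"]),
                Ea=float(row["Ea_J_mol"]),
                direction=Direction(row["direction"]),
            )
        )
    return models
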