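import numpy as np
import pytest

from aslt.datamodel import Component, Direction, QualityIndexSeries


def make_series(
    times,
    values,
    index_name="hardness",
    component=Component.RADISH,
    temperature_K=318.15,
    direction=Direction.DECREASING,
    sds=None,
    n_replicates=1,
    replicate_values=None,
):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    return QualityIndexSeries(
        index_name=index_name,
        component=component,
        temperature_K=temperature_K,
        times_d=times,
        values=values,
        sds=np.zeros_like(values) if sds is None else np.asarray(sds, float),
        n_replicates=n_replicates,
        direction=direction,
        replicate_values=replicate_values,
    )


def ols_line(x, y):
    """Independent normal-equation OLS oracle: returns (slope, intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    return slope, ybar - slope * xbar


@pytest.fixture
def series_factory():
    return make_series
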