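"""Back-propagation network regressing NIR spectra onto chemical indices.

A single hidden layer of logistic units (default 20) with a linear 2-unit
output maps the scaled absorbance grid to total acid content and storage day
jointly. Samples are split 70/15/15 into training/validation/prediction sets;
training runs full-batch adam epochs with early stopping on validation loss.
Inputs are min-max scaled per wavelength (optionally z-scored) and targets are
z-scored internally; everything is seeded and the report is bit-reproducible
for a fixed seed and data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from sklearn.neural_network import MLPRegressor

from .datamodel import NIRSpectrum
from .errors import ConfigError, DegenerateFitError, DomainError, InsufficientDataError

TARGET_NAMES = ("total_acid", "storage_day")


@dataclass(frozen=True)
class ANNConfig:
    hidden_units: int = 20
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    max_epochs: int = 2000
    patience: int = 100
    seed: int = 0
    input_scaling: str = "minmax"  # or "zscore"
    learning_rate: float = 0.02
    #: grid decimation factor applied to the wavelength axis before training
    downsample: int = 1

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigError("train/val/test fractions must sum to 1")
        if any(f <= 0 for f in self.fractions):
            raise ConfigError("all split fractions must be positive")
        if self.hidden_units < 1:
            raise ConfigError("hidden_units must be >= 1")
        if self.input_scaling not in ("minmax", "zscore"):
            raise ConfigError("input_scaling must be 'minmax' or 'zscore'")


@dataclass(frozen=True)
class SplitReport:
    n_train: int
    n_val: int
    n_test: int
    r2: dict[str, dict[str, float]]  # split → target → R²
    final_epoch: int
    seed: int


def split_data(n: int, config: ANNConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint exhaustive seeded split: floor(f1·n), floor(f2·n), remainder."""
    if n < 10:
        raise InsufficientDataError("need at least 10 samples to split")
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(n)
    # epsilon guards against 0.70·90 = 62.999… under binary floats
    n_train = int(np.floor(config.fractions[0] * n + 1e-9))
    n_val = int(np.floor(config.fractions[1] * n + 1e-9))
    return idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :]


def evaluate_r2(predictions: Sequence[float], truths: Sequence[float]) -> float:
    """Coefficient of determination 1 − Σ(y−ŷ)²/Σ(y−ȳ)²."""
    y = np.asarray(truths, dtype=float)
    yhat = np.asarray(predictions, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise DomainError("predictions and truths must be equal-length, size >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateFitError("truths are constant; R² undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


class _Scaler:
    def __init__(self, kind: str):
        self.kind = kind

    def fit(self, x: np.ndarray) -> "_Scaler":
        if self.kind == "minmax":
            self.lo = x.min(axis=0)
            self.span = x.max(axis=0) - self.lo
            self.span[self.span == 0] = 1.0
        else:
            self.lo = x.mean(axis=0)
            self.span = x.std(axis=0)
            self.span[self.span == 0] = 1.0
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.lo) / self.span

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return x * self.span + self.lo


@dataclass
class BPANNModel:
    config: ANNConfig
    wavelengths_nm: np.ndarray
    net: MLPRegressor = field(repr=False)
    x_scaler: _Scaler = field(repr=False)
    y_scaler: _Scaler = field(repr=False)

    def predict(self, spectra: Sequence[NIRSpectrum]) -> np.ndarray:
        x = _design_matrix(spectra, self.config)[0]
        z = self.net.predict(self.x_scaler.transform(x))
        return self.y_scaler.inverse(z)


def _design_matrix(
    spectra: Sequence[NIRSpectrum], config: ANNConfig
) -> tuple[np.ndarray, np.ndarray]:
    grid = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if len(s.wavelengths_nm) != len(grid) or not np.allclose(
            s.wavelengths_nm, grid
        ):
            raise DomainError(
                f"spectrum {s.sample_id!r} is not on the common wavelength grid"
            )
    step = max(1, int(config.downsample))
    x = np.vstack([s.absorbances[::step] for s in spectra])
    return x, grid[::step]


def train_bpann(
    spectra: Sequence[NIRSpectrum], config: ANNConfig | None = None
) -> tuple[BPANNModel, SplitReport]:
    """Train the spectra → (total acid, storage day) network.

    Early stopping restores the weights with the best validation loss; the
    report carries per-split R² for both targets on their original scales.
    """
    config = config or ANNConfig()
    x, grid = _design_matrix(spectra, config)
    missing = [s.sample_id for s in spectra if s.total_acid is None]
    if missing:
        raise DomainError(f"spectra without a total-acid target: {missing[:3]}")
    y = np.column_stack(
        [[s.total_acid for s in spectra], [s.storage_day for s in spectra]]
    ).astype(float)
    for j, name in enumerate(TARGET_NAMES):
        if np.ptp(y[:, j]) == 0:
            raise DegenerateFitError(f"target {name!r} is constant; R² undefined")

    tr, va, te = split_data(len(spectra), config)
    xsc = _Scaler(config.input_scaling).fit(x[tr])
    ysc = _Scaler("zscore").fit(y[tr])
    xs, yz = xsc.transform(x), ysc.transform(y)

    net = MLPRegressor(
        hidden_layer_sizes=(config.hidden_units,),
        activation="logistic",
        solver="adam",
        learning_rate_init=config.learning_rate,
        random_state=config.seed,
        max_iter=1,
    )
    best_loss, best_state, best_epoch, stale = np.inf, None, 0, 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-epoch partial_fit convergence noise
        for epoch in range(config.max_epochs):
            net.partial_fit(xs[tr], yz[tr])
            val_loss = float(np.mean((net.predict(xs[va]) - yz[va]) ** 2))
            if val_loss < best_loss - 1e-9:
                best_loss, best_epoch, stale = val_loss, epoch, 0
                best_state = (
                    [w.copy() for w in net.coefs_],
                    [b.copy() for b in net.intercepts_],
                )
            else:
                stale += 1
                if stale >= config.patience:
                    break
    net.coefs_, net.intercepts_ = best_state

    model = BPANNModel(
        config=config, wavelengths_nm=grid, net=net, x_scaler=xsc, y_scaler=ysc
    )
    pred = ysc.inverse(net.predict(xs))
    r2 = {
        split: {
            name: evaluate_r2(pred[idx, j], y[idx, j])
            for j, name in enumerate(TARGET_NAMES)
        }
        for split, idx in (("train", tr), ("validation", va), ("test", te))
    }
    report = SplitReport(
        n_train=len(tr),
        n_val=len(va),
        n_test=len(te),
        r2=r2,
        final_epoch=best_epoch,
        seed=config.seed,
    )
    return model, report


def find_peaks(spectrum: NIRSpectrum, min_prominence: float = 0.05) -> np.ndarray:
    """Wavelengths of absorbance maxima whose prominence exceeds
    ``min_prominence`` × the spectrum's absorbance range."""
    if len(spectrum) < 5:
        raise InsufficientDataError("peak finding needs at least 5 grid points")
    span = float(np.ptp(spectrum.absorbances))
    if span == 0.0:
        return np.array([])
    idx, _ = signal.find_peaks(
        spectrum.absorbances, prominence=min_prominence * span
    )
    return spectrum.wavelengths_nm[idx]
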