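"""E-tongue taste-profile analysis: PCA exploration and Fisher discriminant
classification into acceptability periods.

Samples stored for increasing times separate in taste space mainly along
sourness (up) and umami (down). PCA summarizes that structure; a Fisher/linear
discriminant trained on a stratified two-thirds split then validates the
three-period labelling (fully acceptable / acceptable / unacceptable), reported
as calibration and prediction confusion tables with per-class accuracies.

Attributes are z-scored before either analysis: e-tongue attributes live on
heterogeneous scales (sourness ~15–18 vs umami ~1.3–2) and would otherwise
dominate the decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datamodel import ETongueProfile, PeriodBoundaries, PeriodLabel
from .errors import DegenerateFitError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Ridge added to the diagonal of a singular pooled within-class covariance.
SCATTER_RIDGE = 1e-6


def label_periods(day: float, bounds: PeriodBoundaries) -> PeriodLabel:
    """Map a storage day to its acceptability period under the given bounds."""
    return bounds.label(day)


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray  # sample × component
    loadings: np.ndarray  # attribute × component (orthonormal columns)
    explained_pct: np.ndarray  # per-component % of total variance
    attribute_names: list[str]


def _attribute_matrix(
    profiles: Sequence[ETongueProfile],
) -> tuple[np.ndarray, list[str]]:
    names = profiles[0].attribute_names
    x = np.vstack([p.vector(names) for p in profiles])
    return x, names


def _autoscale(x: np.ndarray, names: Sequence[str]) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateFitError(
            f"attribute {names[dead[0]]!r} is constant; cannot standardize"
        )
    return (x - x.mean(axis=0)) / sd


def run_pca(
    profiles: Sequence[ETongueProfile], standardize: bool = True
) -> PCAResult:
    """Principal components of the taste-attribute matrix.

    With ``standardize=True`` (default) this is the eigendecomposition of the
    attribute correlation matrix; otherwise of the covariance matrix.
    """
    if len(profiles) < 3:
        raise InsufficientDataError("PCA needs at least 3 samples")
    x, names = _attribute_matrix(profiles)
    if standardize:
        x = _autoscale(x, names)
    pca = PCA()
    scores = pca.fit_transform(x)
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        explained_pct=100.0 * pca.explained_variance_ratio_,
        attribute_names=names,
    )


@dataclass(frozen=True)
class FDAResult:
    classes: list[PeriodLabel]
    confusion_calibration: np.ndarray  # true class × predicted class
    confusion_prediction: np.ndarray
    calibration_accuracy_pct: float
    prediction_accuracy_pct: float
    per_class_calibration_pct: np.ndarray
    per_class_prediction_pct: np.ndarray
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int


def stratified_split(
    labels: np.ndarray, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class random split; train size per class is round(frac·n_c).

    One uniform draw per sample orders the samples within each class, so the
    split depends only on class membership, not on how classes are numbered
    (renaming labels yields the same partition).
    """
    rng = np.random.default_rng(seed)
    u = rng.random(len(labels))
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[np.argsort(u[idx], kind="stable")]
        n_train = int(round(train_fraction * len(idx)))
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.array(train, int)), np.sort(np.array(test, int))


class FisherDiscriminant:
    """Linear discriminant with pooled within-class covariance.

    Discriminant score of class c for sample x:
    δ_c(x) = xᵀΣ⁻¹μ_c − ½μ_cᵀΣ⁻¹μ_c + ln π_c, with π_c the training class
    frequency. Ties resolve to the lowest class index (argmax order).
    """

    def fit(self, x: np.ndarray, y: np.ndarray) -> "FisherDiscriminant":
        self.classes_ = np.unique(y)
        n, p = x.shape
        means, priors = [], []
        sw = np.zeros((p, p))
        for c in self.classes_:
            xc = x[y == c]
            if len(xc) < 2:
                raise InsufficientDataError(
                    f"class {c} has fewer than 2 training samples"
                )
            mu = xc.mean(axis=0)
            means.append(mu)
            priors.append(len(xc) / n)
            sw += (xc - mu).T @ (xc - mu)
        cov = sw / (n - len(self.classes_))
        if np.linalg.matrix_rank(cov) < p:
            logger.warning(
                "singular within-class scatter; adding ridge %g to its diagonal",
                SCATTER_RIDGE,
            )
            cov = cov + SCATTER_RIDGE * np.eye(p)
        self.means_ = np.vstack(means)
        self.priors_ = np.array(priors)
        cov_inv_mu = np.linalg.solve(cov, self.means_.T)  # p × C
        self._w = cov_inv_mu
        self._b = -0.5 * np.einsum("cp,pc->c", self.means_, cov_inv_mu) + np.log(
            self.priors_
        )
        return self

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return x @ self._w + self._b

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(x), axis=1)]


def _confusion(
    y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    m = np.zeros((len(classes), len(classes)), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        m[pos[t], pos[p]] += 1
    return m


def _per_class_pct(confusion: np.ndarray) -> np.ndarray:
    totals = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * np.diag(confusion) / totals
    return np.where(totals > 0, pct, np.nan)


def run_fda(
    profiles: Sequence[ETongueProfile],
    labels: Sequence[PeriodLabel],
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    standardize: bool = True,
) -> FDAResult:
    """Train a Fisher discriminant on a stratified split and report Table-style
    calibration (training) and prediction (held-out) confusion counts."""
    if len(profiles) != len(labels):
        raise InsufficientDataError("profiles and labels differ in length")
    x, names = _attribute_matrix(profiles)
    if standardize:
        x = _autoscale(x, names)
    y = np.array([int(l) for l in labels])
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("FDA needs at least two classes")
    train_idx, test_idx = stratified_split(y, train_fraction, seed)
    clf = FisherDiscriminant().fit(x[train_idx], y[train_idx])
    classes = clf.classes_
    cal = _confusion(y[train_idx], clf.predict(x[train_idx]), classes)
    pred = _confusion(y[test_idx], clf.predict(x[test_idx]), classes)
    return FDAResult(
        classes=[PeriodLabel(c) for c in classes],
        confusion_calibration=cal,
        confusion_prediction=pred,
        calibration_accuracy_pct=100.0 * np.trace(cal) / cal.sum(),
        prediction_accuracy_pct=100.0 * np.trace(pred) / pred.sum(),
        per_class_calibration_pct=_per_class_pct(cal),
        per_class_prediction_pct=_per_class_pct(pred),
        train_indices=train_idx,
        test_indices=test_idx,
        seed=seed,
    )


def accuracy_table(result: FDAResult) -> pd.DataFrame:
    """Render an FDA result as per-class calibration/prediction rows with a
    Total row; percentages rounded to 2 decimals, empty classes shown as "—"."""
    rows = []
    names = [c.name.replace("_", " ").title() for c in result.classes]
    for block, conf in (
        ("calibration", result.confusion_calibration),
        ("prediction", result.confusion_prediction),
    ):
        for i, cname in enumerate(names):
            total = int(conf[i].sum())
            pct = (
                "—" if total == 0 else round(100.0 * conf[i, i] / total, 2)
            )
            rows.append(
                {
                    "block": block,
                    "class": cname,
                    **{names[j]: int(conf[i, j]) for j in range(len(names))},
                    "total": total,
                    "correctly_classified_pct": pct,
                }
            )
        grand = int(conf.sum())
        rows.append(
            {
                "block": block,
                "class": "Total",
                **{names[j]: int(conf[:, j].sum()) for j in range(len(names))},
                "total": grand,
                "correctly_classified_pct": (
                    "—" if grand == 0 else round(100.0 * np.trace(conf) / grand, 2)
                ),
            }
        )
    return pd.DataFrame(rows)
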