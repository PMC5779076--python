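"""TdP risk classification from simulated metrics.

Drugs carry clinical risk categories 2 (withdrawn / class Ia–III
antiarrhythmics) through 5 (no reported TdP).  Any combination of numeric
per-drug metrics — EAD thresholds, APDs, diastolic Ca, the hERG safety
factor — can be used to train a classifier mapping metric vectors to
categories, evaluated by cross-validated mean absolute category error

    E = (1/N) * sum_i |a_i - c_i|

with ``a`` the actual and ``c`` the assigned category.

Two classifiers are exposed, mirroring the two standard choices for this
problem: linear discriminant analysis (per-category Gaussians with pooled
covariance; boundaries where the inferred densities cross) and a linear
support-vector machine (maximum-margin hyperplanes, one-vs-one for the
four-class problem).  Both are thin wrappers over scikit-learn estimators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

VALID_CATEGORIES = (2, 3, 4, 5)


def normalize_metrics(table: pd.DataFrame, control: str = "control") -> pd.DataFrame:
    """Shift each metric so the control row is 0, then scale into [-1, 1].

    Per column: subtract the control value, divide by the maximum absolute
    shifted value.  Rank order within each column is preserved (affine map).
    Columns identical to control everywhere are left at zero with a warning.
    """
    if control not in table.index:
        raise ValueError(f"control row {control!r} not present in the metric table")
    shifted = table.sub(table.loc[control], axis=1)
    out = {}
    for col in shifted.columns:
        scale = shifted[col].abs().max(skipna=True)
        if not (scale > 0):
            warnings.warn(f"metric {col!r} equals the control value everywhere", stacklevel=2)
            out[col] = shifted[col]
        else:
            out[col] = shifted[col] / scale
    return pd.DataFrame(out, index=table.index)


def mean_absolute_error(actual, assigned) -> float:
    """Mean absolute category difference between two label sequences."""
    actual = np.asarray(actual, dtype=float)
    assigned = np.asarray(assigned, dtype=float)
    if actual.shape != assigned.shape:
        raise ValueError("actual and assigned must have equal length")
    if actual.size == 0:
        raise ValueError("need at least one drug")
    return float(np.mean(np.abs(actual - assigned)))


def _align(table: pd.DataFrame, labels: pd.Series, metrics=None):
    """Common drugs with complete metric rows and a label; logs drops."""
    if metrics is not None:
        table = table[list(metrics)]
    table = table.drop(index=[i for i in ("control",) if i in table.index])
    labels = labels.dropna().astype(int)
    keep = table.dropna().index.intersection(labels.index)
    dropped = sorted(set(table.index) - set(keep))
    if dropped:
        logger.info("dropped from classification (missing metric or label): %s", dropped)
    X = table.loc[keep]
    y = labels.loc[keep]
    bad = ~y.isin(VALID_CATEGORIES)
    if bad.any():
        raise ValueError(f"risk categories outside 2..5 for: {list(y.index[bad])}")
    return X, y


class RiskClassifier:
    """Category predictor over a metric table (wrapper around sklearn)."""

    def __init__(self, estimator):
        self.estimator = estimator
        self.columns_: list | None = None
        self._constant: int | None = None
        self._centroids: pd.DataFrame | None = None

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "RiskClassifier":
        self.columns_ = list(X.columns)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            # degenerate fold: remember the single class
            self._constant = int(classes[0])
            return self
        if (counts < 2).any() and isinstance(self.estimator, LinearDiscriminantAnalysis):
            warnings.warn(
                "a risk category has fewer than 2 members; LDA falls back on the "
                "pooled covariance estimate",
                stacklevel=2,
            )
        if len(X) <= len(classes) and isinstance(self.estimator, LinearDiscriminantAnalysis):
            # too few samples to estimate any within-class covariance;
            # degrade gracefully to nearest class centroid
            self._centroids = X.groupby(y.to_numpy()).mean()
            return self
        self.estimator.fit(X.to_numpy(), y.to_numpy())
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.columns_ is None:
            raise RuntimeError("classifier is not fitted")
        if self._constant is not None:
            return np.full(len(X), self._constant)
        if self._centroids is not None:
            d = (
                X[self.columns_].to_numpy()[:, None, :]
                - self._centroids.to_numpy()[None, :, :]
            )
            nearest = np.argmin((d ** 2).sum(axis=2), axis=1)
            return self._centroids.index.to_numpy()[nearest].astype(int)
        return self.estimator.predict(X[self.columns_].to_numpy()).astype(int)


def classify_lda(table: pd.DataFrame, labels: pd.Series, metrics=None) -> RiskClassifier:
    """Fit linear discriminant analysis (empirical class priors)."""
    X, y = _align(table, labels, metrics)
    return RiskClassifier(LinearDiscriminantAnalysis()).fit(X, y)


def classify_svm(
    table: pd.DataFrame, labels: pd.Series, metrics=None, C: float = 1.0
) -> RiskClassifier:
    """Fit a linear-kernel SVM (one-vs-one multi-class, margin penalty C)."""
    X, y = _align(table, labels, metrics)
    return RiskClassifier(SVC(kernel="linear", C=C)).fit(X, y)


_FACTORIES = {
    "lda": lambda: RiskClassifier(LinearDiscriminantAnalysis()),
    "svm": lambda: RiskClassifier(SVC(kernel="linear", C=1.0)),
}


@dataclass
class CrossValidationResult:
    predictions: pd.Series  # drug -> assigned category
    mae: float
    scheme: str
    method: str


def cross_validate(
    table: pd.DataFrame,
    labels: pd.Series,
    method: str = "lda",
    scheme: str = "leave_one_out",
    seed: int | None = None,
    metrics=None,
) -> CrossValidationResult:
    """Predict every drug from a model trained without it (or its group).

    ``leave_one_out`` removes one drug at a time; ``five_group`` randomly
    partitions the drugs into five groups (seeded) and holds out one group
    at a time.  Folds whose training split lacks two categories degenerate
    to constant prediction of the remaining category (logged inside
    :class:`RiskClassifier`).
    """
    if method not in _FACTORIES:
        raise ValueError("method must be 'lda' or 'svm'")
    X, y = _align(table, labels, metrics)
    n = len(X)
    if scheme == "leave_one_out":
        folds = [[i] for i in range(n)]
    elif scheme == "five_group":
        if n < 5:
            raise ValueError("five_group cross-validation needs at least 5 drugs")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = [list(perm[g::5]) for g in range(5)]
    else:
        raise ValueError("scheme must be 'leave_one_out' or 'five_group'")

    assigned = pd.Series(index=X.index, dtype=float)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        clf = _FACTORIES[method]().fit(X.iloc[mask], y.iloc[mask])
        assigned.iloc[fold] = clf.predict(X.iloc[fold])
    assigned = assigned.astype(int)
    return CrossValidationResult(
        predictions=assigned,
        mae=mean_absolute_error(y.to_numpy(), assigned.to_numpy()),
        scheme=scheme,
        method=method,
    )
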