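"""One-vs-all soft-margin kernel SVM and cross-validated mean error.

One binary SVM (scikit-learn ``SVC``) is trained per movement class against
the rest; prediction takes the class with the highest decision value, with
exact ties broken toward the lowest class index for determinism.  Features
are z-scored with training-set statistics before fitting (TD features span
orders of magnitude — SSI vs ZC — and kernel machines are scale-sensitive).

The mean 10-fold stratified cross-validated misclassification fraction of
this classifier is the fitness minimized by the GA/PSO wrapper selectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DataError, ParameterError, ShapeError
from .features import FeatureMatrix


@dataclass(frozen=True)
class SvmSpec:
    """Kernel and regularization of the per-class binary machines.

    ``gamma`` (Gaussian kernel width) defaults to scikit-learn's ``"scale"``
    heuristic, 1 / (n_features · Var(X)); ``C`` defaults to 1.
    """

    kernel: str = "gaussian"
    C: float = 1.0
    gamma: float | str = "scale"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "gaussian"):
            raise ParameterError("kernel must be 'linear' or 'gaussian'")
        if self.C <= 0:
            raise ParameterError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ParameterError("gamma must be positive")

    @property
    def sklearn_kernel(self) -> str:
        return "rbf" if self.kernel == "gaussian" else "linear"


@dataclass
class SvmModel:
    """Trained one-vs-all ensemble: one binary SVC per class, plus the
    training standardization constants."""

    machines: list[SVC]
    class_order: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    spec: SvmSpec

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean.size:
            raise ShapeError(
                f"model expects {self.mean.size} features, got {X.shape[1]}"
            )
        Xs = (X - self.mean) / self.scale
        return np.column_stack([svc.decision_function(Xs) for svc in self.machines])

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax returns the first (lowest-index) maximum: deterministic ties
        idx = np.argmax(self.decision_values(X), axis=1)
        return self.class_order[idx]


def _standardization(X: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray]:
    if not enabled:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns carry no information
    return mean, scale


def train_ova(m: FeatureMatrix | np.ndarray, spec: SvmSpec = SvmSpec(),
              y: np.ndarray | None = None) -> SvmModel:
    """Train the one-against-all ensemble.

    Accepts either a :class:`FeatureMatrix` (labels taken from its rows) or
    a plain array plus explicit labels ``y``.
    """
    if isinstance(m, FeatureMatrix):
        X, y = m.values, m.classes
    else:
        X = np.asarray(m, dtype=float)
        if y is None:
            raise ParameterError("labels required when training on a plain array")
    classes = np.unique(y)
    if classes.size < 2:
        raise DataError("one-vs-all training needs at least 2 classes")
    mean, scale = _standardization(X, spec.standardize)
    Xs = (X - mean) / scale
    machines = []
    for cls in classes:
        svc = SVC(kernel=spec.sklearn_kernel, C=spec.C, gamma=spec.gamma)
        svc.fit(Xs, (y == cls).astype(int))
        machines.append(svc)
    return SvmModel(machines=machines, class_order=classes, mean=mean, scale=scale, spec=spec)


@dataclass
class CvResult:
    """Per-fold misclassification fractions and their mean."""

    k: int
    fold_errors: np.ndarray
    mean_error: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_error = float(np.mean(self.fold_errors))


def cv_mean_error(
    m: FeatureMatrix | np.ndarray,
    spec: SvmSpec = SvmSpec(),
    k: int = 10,
    seed: int = 0,
    y: np.ndarray | None = None,
) -> CvResult:
    """Mean misclassification fraction over ``k`` stratified folds.

    Folds partition the rows (disjoint, exhaustive); the shuffle is seeded
    so the same data, spec and seed always give the same error.
    """
    if isinstance(m, FeatureMatrix):
        X, y = m.values, m.classes
    else:
        X = np.asarray(m, dtype=float)
        if y is None:
            raise ParameterError("labels required when validating a plain array")
    if k < 2:
        raise ParameterError("k-fold cross-validation needs k >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise DataError(
            f"smallest class has {counts.min()} rows; cannot form {k} stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    errors = []
    for train_idx, val_idx in skf.split(X, y):
        model = train_ova(X[train_idx], spec, y=y[train_idx])
        pred = model.predict(X[val_idx])
        errors.append(float(np.mean(pred != y[val_idx])))
    return CvResult(k=k, fold_errors=np.asarray(errors))
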