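"""Uniform train/predict contract over the four supervised methods.

Methods: random forest (``rf``), support vector machine (``svm``), linear
discriminant analysis (``lda``) and k-nearest neighbors (``knn``), all
delegated to scikit-learn. Baseline hyperparameters are the library
defaults (rf: 100 trees; svm: RBF kernel, C=1; knn: k=5, uniform weights;
lda: no shrinkage), overridable through :class:`ModelSpec`; a small
grid-search helper covers hyperparameter exploration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .exceptions import ConfigError, ValidationError

METHODS = ("rf", "svm", "lda", "knn")

# Tables are conventionally ordered RF, SVM, KNN, LDA for pairwise columns.
CANONICAL_ORDER = ("rf", "svm", "knn", "lda")


@dataclass(frozen=True)
class ModelSpec:
    """A method tag, hyperparameter overrides, and a seed."""

    method: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}; expected one of {METHODS}")

    def to_json(self) -> str:
        return json.dumps(
            {"method": self.method, "hyperparameters": self.hyperparameters, "seed": self.seed}
        )

    @classmethod
    def from_json(cls, payload: str) -> "ModelSpec":
        d = json.loads(payload)
        return cls(d["method"], d.get("hyperparameters", {}), d.get("seed", 0))


def build_estimator(spec: ModelSpec):
    """Instantiate the sklearn estimator behind a spec, rejecting unknown
    hyperparameter keys."""
    if spec.method == "rf":
        est = RandomForestClassifier(n_estimators=100, random_state=spec.seed)
    elif spec.method == "svm":
        est = SVC(kernel="rbf", C=1.0, random_state=spec.seed)
    elif spec.method == "lda":
        est = LinearDiscriminantAnalysis()
    else:  # knn
        est = KNeighborsClassifier(n_neighbors=5, weights="uniform")
    valid = set(est.get_params())
    unknown = set(spec.hyperparameters) - valid
    if unknown:
        raise ConfigError(
            f"unknown hyperparameters for {spec.method}: {sorted(unknown)}"
        )
    est.set_params(**spec.hyperparameters)
    return est


def fit(spec: ModelSpec, features, targets):
    """Fit a model; deterministic given the spec's seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets)
    if np.unique(y).size < 2:
        raise ValidationError("training targets contain a single class")
    return build_estimator(spec).fit(X, y)


def predict(model, features) -> np.ndarray:
    """Predict labels; feature width must match training."""
    X = np.asarray(features, dtype=float)
    if X.size == 0:
        return np.empty(0, dtype=model.classes_.dtype)
    if X.ndim != 2 or X.shape[1] != model.n_features_in_:
        raise ValidationError(
            f"feature width {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match the {model.n_features_in_} features seen at fit time"
        )
    return model.predict(X)


def grid_search(spec: ModelSpec, param_grid: dict, features, targets, cv: int = 5):
    """Exhaustive hyperparameter search; returns (best_spec, cv_results)."""
    search = GridSearchCV(build_estimator(spec), param_grid, cv=cv, scoring="accuracy")
    search.fit(np.asarray(features, dtype=float), np.asarray(targets))
    best = ModelSpec(
        spec.method, {**spec.hyperparameters, **search.best_params_}, spec.seed
    )
    return best, search.cv_results_


def save_model(model, path) -> None:
    joblib.dump(model, path)


def load_model(path):
    return joblib.load(path)
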