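"""Six classifier families behind one train/score contract.

Families: NN (multilayer perceptron), XGB (extreme gradient boosting),
RF (random forest), LR (logistic regression), SVM (support vector machine),
LDA (linear discriminant analysis). All of them consume a raw abundance
matrix that may contain missing cells: a preprocessing stage (per-feature
median imputation followed by z-score standardization) is fitted on the
training fold only and travels with the trained model, so test-fold content
can never leak into the fitted state.

Scores are continuous in [0, 1] and monotone in the model's confidence for
the positive class (label 1 = disease). For the SVM the score is a logistic
squashing of the signed margin; every other family exposes a class-1
probability directly.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "HyperparameterGrid",
    "TrainedModel",
    "Preprocessor",
    "enumerate_grid",
    "train",
    "predict_scores",
    "default_spec",
    "default_grid",
]

FAMILIES = ("NN", "XGB", "RF", "LR", "SVM", "LDA")

# Declared hyperparameter spaces; a spec naming anything else is rejected.
_SPACES: dict[str, frozenset[str]] = {
    "NN": frozenset(
        {"hidden_layer_sizes", "activation", "learning_rate_init", "alpha",
         "max_iter", "batch_size"}
    ),
    "XGB": frozenset(
        {"n_estimators", "max_depth", "learning_rate", "subsample",
         "colsample_bytree", "reg_lambda", "min_child_weight"}
    ),
    "RF": frozenset(
        {"n_estimators", "max_depth", "max_features", "min_samples_split",
         "min_samples_leaf"}
    ),
    "LR": frozenset({"C", "class_weight", "fit_intercept", "max_iter"}),
    "SVM": frozenset({"kernel", "C", "gamma"}),
    "LDA": frozenset({"solver", "shrinkage"}),
}

# Default hyperparameters per family (the NN architecture: two hidden layers
# 64/32, ReLU, L2 weight decay 1e-4, <=200 seeded epochs).
_DEFAULTS: dict[str, dict] = {
    "NN": {
        "hidden_layer_sizes": (64, 32),
        "activation": "relu",
        "learning_rate_init": 1e-3,
        "alpha": 1e-4,
        "max_iter": 200,
        "batch_size": "auto",
    },
    "XGB": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1, "subsample": 1.0},
    "RF": {"n_estimators": 200, "max_depth": None, "max_features": "sqrt"},
    "LR": {"C": 1.0, "max_iter": 2000},
    "SVM": {"kernel": "linear", "C": 1.0, "gamma": "scale"},
    # feature tables here typically have p ~ n or larger; Ledoit-Wolf
    # shrinkage keeps the within-class covariance well conditioned
    "LDA": {"solver": "lsqr", "shrinkage": "auto"},
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus concrete hyperparameters and a seed."""

    family: str
    hyperparameters: tuple = ()  # sorted (name, value) pairs; dict-like access below
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        hp = dict(self.hyperparameters) if not isinstance(self.hyperparameters, dict) else dict(self.hyperparameters)
        unknown = set(hp) - _SPACES[self.family]
        if unknown:
            raise ValueError(f"hyperparameters {sorted(unknown)} not in {self.family} space")
        frozen = tuple(sorted((k, _freeze(v)) for k, v in hp.items()))
        object.__setattr__(self, "hyperparameters", frozen)

    @property
    def params(self) -> dict:
        merged = dict(_DEFAULTS[self.family])
        merged.update(dict(self.hyperparameters))
        return merged

    def to_json(self) -> str:
        return json.dumps(
            {"family": self.family, "hyperparameters": dict(self.hyperparameters),
             "seed": self.seed},
            default=list,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        doc = json.loads(text)
        return cls(doc["family"], tuple(doc.get("hyperparameters", {}).items()),
                   doc.get("seed", 0))


def _freeze(value):
    if isinstance(value, list):
        return tuple(_freeze(v) for v in value)
    return value


@dataclass
class HyperparameterGrid:
    """Finite candidate lists per hyperparameter; searched exhaustively."""

    family: str
    axes: dict[str, list]

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        unknown = set(self.axes) - _SPACES[self.family]
        if unknown:
            raise ValueError(f"grid axes {sorted(unknown)} not in {self.family} space")
        for name, values in self.axes.items():
            if not values:
                raise ValueError(f"grid axis {name!r} is empty")

    @property
    def size(self) -> int:
        out = 1
        for values in self.axes.values():
            out *= len(values)
        return out

    def to_json(self) -> str:
        return json.dumps({"family": self.family, "axes": self.axes}, default=list)

    @classmethod
    def from_json(cls, text: str) -> "HyperparameterGrid":
        doc = json.loads(text)
        return cls(doc["family"], doc["axes"])


def enumerate_grid(grid: HyperparameterGrid, seed: int = 0) -> list[ModelSpec]:
    """Full Cartesian product, axes sorted by name, values in listed order."""
    names = sorted(grid.axes)
    combos = itertools.product(*(grid.axes[n] for n in names))
    return [ModelSpec(grid.family, tuple(zip(names, c)), seed) for c in combos]


def default_spec(family: str, seed: int = 0) -> ModelSpec:
    return ModelSpec(family, (), seed)


def default_grid(family: str) -> HyperparameterGrid:
    """Packaged default search grid for a family."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    text = resources.files("crankms.grids").joinpath(f"{family.lower()}.json").read_text()
    return HyperparameterGrid.from_json(text)


class Preprocessor:
    """Train-fold preprocessing: median imputation, inverse-hyperbolic-sine
    variance stabilization, then per-feature standardization.

    MS abundances are roughly log-normal and span decades; z-scoring them
    raw leaves extreme right tails that dominate every learner and corrupt
    attribution magnitudes. ``asinh`` behaves like ``log(2x)`` for large
    values while staying defined at zero (and for negative inputs from
    already-transformed tables), so the standardized features are
    approximately the log-scale signal. All-missing features impute to 0;
    zero-variance features get their scale clamped to 1.
    """

    def __init__(self):
        self.median_ = None
        self.mean_ = None
        self.scale_ = None

    def fit(self, X: np.ndarray) -> "Preprocessor":
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            self.median_ = np.nanmedian(X, axis=0)
        self.median_ = np.where(np.isnan(self.median_), 0.0, self.median_)
        stabilized = np.arcsinh(self._impute(X))
        self.mean_ = stabilized.mean(axis=0)
        sd = stabilized.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float).copy()
        mask = np.isnan(X)
        if mask.any():
            X[mask] = np.broadcast_to(self.median_, X.shape)[mask]
        return X

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.median_ is None:
            raise RuntimeError("Preprocessor not fitted")
        return (np.arcsinh(self._impute(X)) - self.mean_) / self.scale_


@dataclass
class TrainedModel:
    """Opaque fitted classifier plus its fitted preprocessing state."""

    spec: ModelSpec
    preprocessor: Preprocessor
    estimator: object
    n_features: int

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return predict_scores(self, X)


def _build_estimator(spec: ModelSpec):
    p = spec.params
    seed = spec.seed
    if spec.family == "NN":
        return MLPClassifier(
            hidden_layer_sizes=tuple(p["hidden_layer_sizes"]),
            activation=p["activation"],
            solver="adam",
            learning_rate_init=p["learning_rate_init"],
            alpha=p["alpha"],
            max_iter=int(p["max_iter"]),
            batch_size=p["batch_size"],
            random_state=seed,
        )
    if spec.family == "XGB":
        return XGBClassifier(
            n_estimators=int(p["n_estimators"]),
            max_depth=int(p["max_depth"]),
            learning_rate=p["learning_rate"],
            subsample=p.get("subsample", 1.0),
            colsample_bytree=p.get("colsample_bytree", 1.0),
            reg_lambda=p.get("reg_lambda", 1.0),
            min_child_weight=p.get("min_child_weight", 1),
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            tree_method="hist",
            verbosity=0,
        )
    if spec.family == "RF":
        return RandomForestClassifier(
            n_estimators=int(p["n_estimators"]),
            max_depth=p["max_depth"],
            max_features=p["max_features"],
            min_samples_split=p.get("min_samples_split", 2),
            min_samples_leaf=p.get("min_samples_leaf", 1),
            n_jobs=1,
            random_state=seed,
        )
    if spec.family == "LR":
        return LogisticRegression(
            C=p["C"],
            class_weight=p.get("class_weight"),
            fit_intercept=p.get("fit_intercept", True),
            max_iter=int(p["max_iter"]),
            solver="lbfgs",
        )
    if spec.family == "SVM":
        return SVC(kernel=p["kernel"], C=p["C"], gamma=p["gamma"], random_state=seed)
    if spec.family == "LDA":
        solver = p["solver"]
        shrinkage = p.get("shrinkage")
        if solver == "svd":
            shrinkage = None
        return LinearDiscriminantAnalysis(solver=solver, shrinkage=shrinkage)
    raise AssertionError(spec.family)  # pragma: no cover


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Fit preprocessing and the family's learner on (X, y).

    ``X`` may contain missing entries; ``y`` must contain both classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X row count must equal label count")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    prep = Preprocessor().fit(X)
    Z = prep.transform(X)
    estimator = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        estimator.fit(Z, y)
    return TrainedModel(spec, prep, estimator, X.shape[1])


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Class-1 score in [0, 1] per row of ``X`` (raw feature space)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, got {X.shape[1] if X.ndim == 2 else 'non-matrix'}"
        )
    Z = model.preprocessor.transform(X)
    est = model.estimator
    if isinstance(est, SVC):
        margin = est.decision_function(Z)
        return 1.0 / (1.0 + np.exp(-margin))
    proba = est.predict_proba(Z)
    positive = list(est.classes_).index(1)
    return proba[:, positive]
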