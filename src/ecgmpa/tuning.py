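"""MPA-driven hyperparameter tuning of the four classifiers.

The optimizer searches a box per classifier (search ranges below),
scoring each candidate by holdout error: the feature matrix is split
80/20 stratified by class, the classifier is fitted on the training
part with the decoded hyperparameters, and the fitness is
``1 - accuracy`` on the validation part (minimization convention).

Search boxes:

========== ============================= =========== =======
classifier parameter                     range       scale
========== ============================= =========== =======
SVM        C                             [1e-4, 1e3] log10
SVM        gamma (RBF width)             [1e-4, 1]   log10
GBDT       max_depth                     [1, 13]     integer
GBDT       gamma (min split loss)        [1e-4, 1]   log10
GBDT       learning rate                 [0, 1]      linear
RF         max_depth                     [1, 13]     integer
RF         max_features fraction         [1e-4, 1]   linear
RF         tree-count fraction -> 50..500 [0, 1]     linear
kNN        K (neighbors)                 [1, 13]     integer
========== ============================= =========== =======

Classifier internals are delegated to scikit-learn (SVM with RBF
kernel, random forest, kNN) and xgboost (gradient-boosted trees, whose
native ``gamma`` is the minimum split loss).  Parameters spanning
several decades (C, the two gammas) are searched in log10 space;
integer parameters are decoded by round-half-up; every decoded value is
clipped into its range, so the optimizer can never evaluate an
out-of-range configuration.  The boosting learning rate has an
effective floor of 1e-3 (a rate of exactly 0 cannot learn).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import LabelEncoder, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import mpa
from .preprocess import round_half_up

CLASSIFIERS = ("svm", "gbdt", "rf", "knn")

#: Effective lower bound for the boosting learning rate (a rate of 0 is
#: a degenerate model).
MIN_LEARNING_RATE = 1e-3

#: Tree-count fraction in [0, 1] maps affinely onto this range.
RF_TREES_RANGE = (50, 200)

#: Boosting rounds used by the GBDT wrapper (both at default and tuned
#: hyperparameters, so comparisons stay like-for-like).
GBDT_ROUNDS = 50


@dataclass(frozen=True)
class ParamDescriptor:
    name: str
    lower: float
    upper: float
    scale: str = "linear"  # or "log10"
    kind: str = "real"  # or "integer"

    def search_bounds(self) -> tuple[float, float]:
        if self.scale == "log10":
            return np.log10(self.lower), np.log10(self.upper)
        return self.lower, self.upper

    def decode(self, raw: float) -> float | int:
        lo, hi = self.search_bounds()
        raw = min(max(raw, lo), hi)
        value = 10.0**raw if self.scale == "log10" else raw
        if self.kind == "integer":
            return int(min(max(round_half_up(value), self.lower), self.upper))
        return float(min(max(value, self.lower), self.upper))


@dataclass(frozen=True)
class HyperparamSpec:
    classifier: str
    params: tuple[ParamDescriptor, ...]

    @property
    def dim(self) -> int:
        return len(self.params)

    def search_space(self) -> mpa.SearchSpace:
        bounds = np.array([p.search_bounds() for p in self.params])
        return mpa.SearchSpace(lower=bounds[:, 0], upper=bounds[:, 1])

    def decode(self, position: np.ndarray) -> dict[str, float | int]:
        position = np.atleast_1d(np.asarray(position, dtype=float))
        if position.size != self.dim:
            raise ValueError(
                f"position has {position.size} dims, spec needs {self.dim}"
            )
        return {p.name: p.decode(x) for p, x in zip(self.params, position)}


_SPECS: dict[str, HyperparamSpec] = {
    "svm": HyperparamSpec(
        "svm",
        (
            ParamDescriptor("C", 1e-4, 1e3, scale="log10"),
            ParamDescriptor("gamma", 1e-4, 1.0, scale="log10"),
        ),
    ),
    "gbdt": HyperparamSpec(
        "gbdt",
        (
            ParamDescriptor("max_depth", 1, 13, kind="integer"),
            ParamDescriptor("gamma", 1e-4, 1.0, scale="log10"),
            ParamDescriptor("learning_rate", 0.0, 1.0),
        ),
    ),
    "rf": HyperparamSpec(
        "rf",
        (
            ParamDescriptor("max_depth", 1, 13, kind="integer"),
            ParamDescriptor("max_features", 1e-4, 1.0),
            ParamDescriptor("n_estimators_frac", 0.0, 1.0),
        ),
    ),
    "knn": HyperparamSpec(
        "knn", (ParamDescriptor("n_neighbors", 1, 13, kind="integer"),)
    ),
}


def spec_for(classifier: str) -> HyperparamSpec:
    try:
        return _SPECS[classifier.lower()]
    except KeyError:
        raise ValueError(
            f"unknown classifier {classifier!r}; expected one of {CLASSIFIERS}"
        ) from None


def decode_position(position: np.ndarray, spec: HyperparamSpec) -> dict:
    """Decode a raw optimizer position into classifier hyperparameters."""
    return spec.decode(position)


def build_classifier(
    classifier: str, params: dict | None = None, model_seed: int = 0
):
    """Instantiate a classifier; ``params=None`` gives library defaults."""
    classifier = classifier.lower()
    params = dict(params or {})
    if classifier == "svm":
        return SVC(**params)
    if classifier == "gbdt":
        if "learning_rate" in params:
            params["learning_rate"] = max(params["learning_rate"], MIN_LEARNING_RATE)
        return XGBClassifier(
            n_estimators=GBDT_ROUNDS,
            tree_method="hist",
            random_state=model_seed,
            n_jobs=1,
            verbosity=0,
            **params,
        )
    if classifier == "rf":
        if "n_estimators_frac" in params:
            frac = params.pop("n_estimators_frac")
            lo, hi = RF_TREES_RANGE
            params["n_estimators"] = int(round(lo + frac * (hi - lo)))
        if "max_features" in params:
            params["max_features"] = max(params["max_features"], 1e-4)
        return RandomForestClassifier(random_state=model_seed, n_jobs=1, **params)
    if classifier == "knn":
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown classifier {classifier!r}")


@dataclass
class SplitData:
    X_train: np.ndarray
    X_val: np.ndarray
    y_train: np.ndarray
    y_val: np.ndarray


def split_holdout(
    features: np.ndarray | pd.DataFrame,
    labels,
    fraction: float = 0.8,
    seed: int = 0,
) -> SplitData:
    """Stratified holdout split (default 80% train / 20% validation)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("holdout split requires at least 2 classes")
    if counts.min() < 2:
        small = classes[counts < 2]
        raise ValueError(f"classes with < 2 members cannot be stratified: {small}")
    X_train, X_val, y_train, y_val = train_test_split(
        X, y, train_size=fraction, stratify=y, random_state=seed
    )
    return SplitData(X_train, X_val, y_train, y_val)


def fitness(
    classifier: str, params: dict, split: SplitData, model_seed: int = 0
) -> float:
    """Holdout error ``1 - accuracy`` of the classifier at ``params``."""
    model = build_classifier(classifier, params, model_seed=model_seed)
    enc = LabelEncoder().fit(np.concatenate([split.y_train, split.y_val]))
    model.fit(split.X_train, enc.transform(split.y_train))
    pred = model.predict(split.X_val)
    return float(np.mean(pred != enc.transform(split.y_val)))


@dataclass
class TunedModel:
    classifier: str
    params: dict
    model: Any
    label_encoder: LabelEncoder
    scaler: StandardScaler | None
    holdout_fitness: float  # 1 - validation accuracy at the best position
    result: mpa.OptimizationResult
    split_seed: int
    evaluation_log: list[dict] = field(default_factory=list)

    @property
    def holdout_accuracy(self) -> float:
        return 1.0 - self.holdout_fitness

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.label_encoder.inverse_transform(self.model.predict(X))


def tune(
    classifier: str,
    features: np.ndarray | pd.DataFrame,
    labels,
    mpa_params: mpa.MPAParams | None = None,
    split_seed: int = 0,
    model_seed: int = 0,
    standardize: bool = True,
) -> TunedModel:
    """Search the classifier's hyperparameter box with the MPA.

    Features are standardized on the training split (important for the
    SVM and kNN distance geometry).  Decoded-parameter evaluations are
    memoized — the fitness is deterministic given parameters, data and
    model seed — and every evaluation is appended to an audit log.
    The returned model is refitted at the best decoded parameters on the
    training split.
    """
    spec = spec_for(classifier)
    split = split_holdout(features, labels, seed=split_seed)
    scaler = None
    if standardize:
        scaler = StandardScaler().fit(split.X_train)
        split = SplitData(
            scaler.transform(split.X_train),
            scaler.transform(split.X_val),
            split.y_train,
            split.y_val,
        )
    mpa_params = mpa_params or mpa.MPAParams()

    cache: dict[tuple, float] = {}
    log: list[dict] = []

    def objective(position: np.ndarray) -> float:
        params = spec.decode(position)
        key = tuple(sorted(params.items()))
        if key not in cache:
            cache[key] = fitness(spec.classifier, params, split, model_seed)
            log.append({"params": params, "fitness": cache[key]})
        return cache[key]

    result = mpa.optimize(objective, spec.search_space(), mpa_params)
    best_params = spec.decode(result.best_position)
    model = build_classifier(spec.classifier, best_params, model_seed=model_seed)
    enc = LabelEncoder().fit(np.concatenate([split.y_train, split.y_val]))
    model.fit(split.X_train, enc.transform(split.y_train))
    return TunedModel(
        classifier=spec.classifier,
        params=best_params,
        model=model,
        label_encoder=enc,
        scaler=scaler,
        holdout_fitness=result.best_fitness,
        result=result,
        split_seed=split_seed,
        evaluation_log=log,
    )


def default_holdout_accuracy(
    classifier: str,
    features: np.ndarray | pd.DataFrame,
    labels,
    split_seed: int = 0,
    model_seed: int = 0,
    standardize: bool = True,
) -> float:
    """Validation accuracy at library-default hyperparameters, same split."""
    split = split_holdout(features, labels, seed=split_seed)
    if standardize:
        scaler = StandardScaler().fit(split.X_train)
        split = SplitData(
            scaler.transform(split.X_train),
            scaler.transform(split.X_val),
            split.y_train,
            split.y_val,
        )
    return 1.0 - fitness(classifier, {}, split, model_seed)
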