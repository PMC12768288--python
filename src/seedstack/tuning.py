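"""KOA-driven hyperparameter tuning of the six base-classifier families.

Families and default search ranges (integer/continuous kinds shown):

====== ==========================================================
DT     max_depth ∈ {1..100}, max_features ∈ [0.1, 1]
SVM    C ∈ [1, 1000], gamma ∈ [0.1, 1]          (RBF kernel)
KNN    n_neighbors ∈ {1..100}, p ∈ {1..5}       (Minkowski power)
MLP    k1, k2 ∈ {10..100}                       (two hidden layers)
RF     n_estimators ∈ {1..100}, max_depth ∈ {1..100},
       max_features ∈ [0.1, 1]
GBDT   n_estimators ∈ {1..100}, max_depth ∈ {1..100},
       max_features ∈ [0.1, 1]
====== ==========================================================

The tuning objective is the misclassification rate of the decoded model
on a fixed stratified validation split of the tuning data (k-fold CV
error is available via ``TuningConfig(fitness="cv")``). The split, the
model random states and the optimizer seed are all derived from one
seed, so tuning is a deterministic function of (family, data, seed).
Fitness values are cached by decoded parameters — integer rounding makes
many optimizer positions equivalent — with continuous dimensions bucketed
at 0.01 resolution.

GBDT is backed by scikit-learn's histogram-based gradient boosting
classifier, whose fit cost on these sample sizes is an order of
magnitude below the exact-split implementation with identical tuning
knobs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .koa import KOAConfig, Parameter, SearchSpace, decode_hyperparameters, optimize

__all__ = [
    "FAMILIES",
    "TuningConfig",
    "TunedModel",
    "default_search_space",
    "build_model",
    "tuning_objective",
    "tune_model",
]

FAMILIES = ("DT", "SVM", "KNN", "MLP", "RF", "GBDT")

_SPACES: dict[str, tuple[Parameter, ...]] = {
    "DT": (
        Parameter("max_depth", 1, 100, "integer"),
        Parameter("max_features", 0.1, 1.0, "continuous"),
    ),
    "SVM": (
        Parameter("C", 1, 1000, "continuous"),
        Parameter("gamma", 0.1, 1.0, "continuous"),
    ),
    "KNN": (
        Parameter("n_neighbors", 1, 100, "integer"),
        Parameter("p", 1, 5, "integer"),
    ),
    "MLP": (
        Parameter("k1", 10, 100, "integer"),
        Parameter("k2", 10, 100, "integer"),
    ),
    "RF": (
        Parameter("n_estimators", 1, 100, "integer"),
        Parameter("max_depth", 1, 100, "integer"),
        Parameter("max_features", 0.1, 1.0, "continuous"),
    ),
    "GBDT": (
        Parameter("n_estimators", 1, 100, "integer"),
        Parameter("max_depth", 1, 100, "integer"),
        Parameter("max_features", 0.1, 1.0, "continuous"),
    ),
}


class BoundedKNeighborsClassifier(KNeighborsClassifier):
    """KNN whose neighbour count is clamped to the fitted sample count.

    The search range for ``n_neighbors`` extends to 100, which can exceed
    a small training fold; the clamp makes every point of the search space
    feasible on any fold size.
    """

    def fit(self, X, y):
        self.n_neighbors = min(self.n_neighbors, len(X))
        return super().fit(X, y)


def default_search_space(family: str) -> SearchSpace:
    _check_family(family)
    return SearchSpace(_SPACES[family])


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}; supported: {', '.join(FAMILIES)}")


def build_model(family: str, params: dict, seed: int = 0):
    """Instantiate a classifier of the given family at the given parameters."""
    _check_family(family)
    if family == "DT":
        return DecisionTreeClassifier(
            max_depth=params["max_depth"], max_features=params["max_features"],
            random_state=seed,
        )
    if family == "SVM":
        return SVC(C=params["C"], gamma=params["gamma"], kernel="rbf", random_state=seed)
    if family == "KNN":
        return BoundedKNeighborsClassifier(n_neighbors=params["n_neighbors"], p=params["p"])
    if family == "MLP":
        return MLPClassifier(
            hidden_layer_sizes=(params["k1"], params["k2"]),
            max_iter=150, early_stopping=True, n_iter_no_change=10,
            random_state=seed,
        )
    if family == "RF":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"], max_depth=params["max_depth"],
            max_features=params["max_features"], random_state=seed, n_jobs=1,
        )
    return HistGradientBoostingClassifier(
        max_iter=params["n_estimators"], max_depth=params["max_depth"],
        max_features=params["max_features"], random_state=seed,
        early_stopping=True, validation_fraction=0.15, n_iter_no_change=5,
    )


@dataclass(frozen=True)
class TuningConfig:
    fitness: str = "holdout"     # "holdout" | "cv"
    holdout_fraction: float = 0.25
    cv_folds: int = 5
    koa: KOAConfig = field(default_factory=KOAConfig)

    def __post_init__(self) -> None:
        if self.fitness not in ("holdout", "cv"):
            raise ValueError("fitness must be 'holdout' or 'cv'")


@dataclass
class TunedModel:
    family: str
    model: object            # refit on the full tuning data at best params
    best_params: dict
    best_fitness: float      # validation misclassification rate
    history: np.ndarray      # best fitness per KOA generation


def _fit_quiet(model, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def tuning_objective(family: str, X, y, config: TuningConfig, seed: int):
    """The deterministic fitness function tuning minimizes.

    Returns ``f(position) -> error rate`` over decoded parameters, with
    the validation split (or CV folds) frozen at construction.
    """
    _check_family(family)
    X = np.asarray(X, float)
    y = np.asarray(y)
    space = default_search_space(family)

    if config.fitness == "holdout":
        X_fit, X_val, y_fit, y_val = train_test_split(
            X, y, test_size=config.holdout_fraction, stratify=y, random_state=seed
        )

        def error_at(params: dict) -> float:
            model = _fit_quiet(build_model(family, params, seed), X_fit, y_fit)
            return float(np.mean(model.predict(X_val) != y_val))

    else:
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))

        def error_at(params: dict) -> float:
            errs = []
            for tr, va in folds:
                model = _fit_quiet(build_model(family, params, seed), X[tr], y[tr])
                errs.append(np.mean(model.predict(X[va]) != y[va]))
            return float(np.mean(errs))

    cache: dict[tuple, float] = {}

    def objective(position: np.ndarray) -> float:
        params = decode_hyperparameters(position, space)
        key = []
        for name, v in params.items():
            if name == "max_features":
                # fitness is flat below ~5% feature-fraction changes; coarse
                # bucketing turns converged-population evaluations into hits
                key.append(round(round(v / 0.05) * 0.05, 2))
            elif isinstance(v, float):
                key.append(round(v, 2))
            else:
                key.append(v)
        key = tuple(key)
        if key not in cache:
            cache[key] = error_at(params)
        return cache[key]

    objective.error_at = error_at  # exposed for independent probing
    objective.space = space
    return objective


def tune_model(
    family: str,
    X_train,
    y_train,
    space: SearchSpace | None = None,
    config: KOAConfig | TuningConfig | None = None,
    seed: int = 0,
) -> TunedModel:
    """KOA-tune one family on training data and refit at the best params."""
    _check_family(family)
    if isinstance(config, KOAConfig):
        tuning = TuningConfig(koa=config)
    else:
        tuning = config or TuningConfig()
    space = space or default_search_space(family)
    objective = tuning_objective(family, X_train, y_train, tuning, seed)
    if space != objective.space:
        objective_space = space

        def wrapped(position):  # custom space: decode against it
            params = decode_hyperparameters(position, objective_space)
            return objective.error_at(params)

        obj = wrapped
    else:
        obj = objective
    koa_cfg = tuning.koa
    if koa_cfg.seed is None:
        koa_cfg = KOAConfig(**{**koa_cfg.__dict__, "seed": seed})
    best_pos, best_fit, history = optimize(obj, space, koa_cfg)
    best_params = decode_hyperparameters(best_pos, space)
    model = _fit_quiet(
        build_model(family, best_params, seed), np.asarray(X_train, float), np.asarray(y_train)
    )
    return TunedModel(family, model, best_params, best_fit, history)
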