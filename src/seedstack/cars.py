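"""Competitive Adaptive Reweighted Sampling (CARS) variable selection.

CARS shrinks a feature set over N sampling runs in two phases per run:

1. *enforced elimination* — an exponentially decaying retention ratio
   r_i = a·e^(−k·i), with a = (m/2)^(1/(N−1)) and k = ln(m/2)/(N−1) so
   that r_1 = 1 (all m features survive run 1) and m·r_N = 2 (two
   survive run N); the round(r_i·m) features with the largest absolute
   PLS regression coefficients are kept;
2. *adaptive reweighted sampling* (ARS) — round(r_i·m) draws with
   replacement, probability proportional to coefficient magnitude; the
   unique drawn features form the run's subset.

Each run's subset is scored by the root-mean-square error of K-fold
cross-validated PLS regression (RMSECV) on the full data; the subset
with the lowest RMSECV (earliest run on ties) is the selected one.

Class labels are encoded for PLS as integer codes 1…C by default
(one-hot is available), matching the error magnitudes this wrapper is
normally run with on multiclass data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "EDFSchedule",
    "PLSConfig",
    "CARSIteration",
    "CARSResult",
    "edf_schedule",
    "encode_labels",
    "pls_feature_weights",
    "ars_sample",
    "rmsecv",
    "run_cars",
]


# --------------------------------------------------------------------------- #
# EDF schedule
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class EDFSchedule:
    m: int
    N: int
    a: float
    k: float
    ratios: np.ndarray

    def n_retained(self, i: int) -> int:
        """Retention target of run i (1-based): round(r_i · m)."""
        return int(round(self.ratios[i - 1] * self.m))


def edf_schedule(m: int, N: int) -> EDFSchedule:
    """Exponential degradation schedule with r_1 = 1 and m·r_N = 2."""
    if m < 3:
        raise ValueError(f"need at least 3 features for an EDF schedule, got m={m}")
    if N < 2:
        raise ValueError(f"need at least 2 sampling runs, got N={N}")
    a = (m / 2.0) ** (1.0 / (N - 1))
    k = np.log(m / 2.0) / (N - 1)
    i = np.arange(1, N + 1)
    ratios = a * np.exp(-k * i)
    return EDFSchedule(m=m, N=N, a=a, k=k, ratios=ratios)


# --------------------------------------------------------------------------- #
# PLS weights and RMSECV
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class PLSConfig:
    n_components: int = 10
    cv_folds: int = 5
    mc_sample_ratio: float = 0.8
    label_encoding: str = "integer"  # "integer" | "one-hot"

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.mc_sample_ratio <= 1:
            raise ValueError("mc_sample_ratio must be in (0, 1]")
        if self.label_encoding not in ("integer", "one-hot"):
            raise ValueError("label_encoding must be 'integer' or 'one-hot'")


def encode_labels(labels: np.ndarray, encoding: str = "integer") -> np.ndarray:
    """Integer codes 1…C (column vector) or one-hot matrix, class-sorted."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    codes = np.searchsorted(classes, labels)
    if encoding == "integer":
        return (codes + 1.0).reshape(-1, 1)
    return np.eye(len(classes))[codes]


def _capped_components(requested: int, n_samples: int, n_features: int) -> int:
    cap = max(1, min(n_samples - 1, n_features))
    if requested > cap:
        warnings.warn(
            f"PLS components reduced from {requested} to {cap} "
            f"(n_samples={n_samples}, n_features={n_features})",
            stacklevel=2,
        )
    return min(requested, cap)


def _fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSRegression:
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-null residual deflation chatter
        pls.fit(X, Y)
    return pls


def pls_feature_weights(
    X: np.ndarray,
    y_encoded: np.ndarray,
    config: PLSConfig = PLSConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """|PLS coefficient| per feature, from a Monte-Carlo row subsample.

    With one-hot targets the absolute coefficients are summed over target
    columns. ``mc_sample_ratio = 1`` fits on all rows.
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(y_encoded, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] > 1:
        Y = Y.T
    n = X.shape[0]
    n_sub = max(2, int(round(config.mc_sample_ratio * n)))
    rows = rng.choice(n, size=min(n_sub, n), replace=False) if n_sub < n else np.arange(n)
    ncomp = _capped_components(config.n_components, len(rows), X.shape[1])
    pls = _fit_pls(X[rows], Y[rows], ncomp)
    coef = np.atleast_2d(pls.coef_)
    if coef.shape == (X.shape[1], Y.shape[1]):
        coef = coef.T
    return np.abs(coef).sum(axis=0)


def ars_sample(
    weights: np.ndarray, n_keep: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Adaptive reweighted sampling: unique ids of n_keep weighted draws.

    Draws are with replacement with probability ∝ weight, so the returned
    sorted id set has at most n_keep members. Zero-weight features are
    never drawn unless every weight is zero, in which case sampling falls
    back to uniform (with a warning).
    """
    rng = rng or np.random.default_rng()
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("feature weights must be nonnegative")
    if n_keep < 1 or n_keep > len(weights):
        raise ValueError(f"n_keep={n_keep} outside 1..{len(weights)}")
    total = weights.sum()
    if total == 0:
        warnings.warn("all feature weights are zero; ARS falls back to uniform sampling")
        p = np.full(len(weights), 1.0 / len(weights))
    else:
        p = weights / total
    drawn = rng.choice(len(weights), size=n_keep, replace=True, p=p)
    return np.unique(drawn)


def rmsecv(
    X: np.ndarray,
    y_encoded: np.ndarray,
    config: PLSConfig = PLSConfig(),
    rng: np.random.Generator | int | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Pooled K-fold cross-validation RMSE of a PLS regression.

    ``folds`` may carry explicit (train, test) index pairs; otherwise
    shuffled K-fold assignments are derived from ``rng``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(y_encoded, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] > 1:
        Y = Y.T
    if folds is None:
        seed = (
            int(rng.integers(2**31)) if isinstance(rng, np.random.Generator)
            else (rng if rng is not None else 0)
        )
        kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
        folds = list(kf.split(X))
    sq_sum, count = 0.0, 0
    for train_idx, test_idx in folds:
        ncomp = _capped_components(config.n_components, len(train_idx), X.shape[1])
        pls = _fit_pls(X[train_idx], Y[train_idx], ncomp)
        resid = Y[test_idx] - pls.predict(X[test_idx]).reshape(Y[test_idx].shape)
        sq_sum += float(np.sum(resid**2))
        count += resid.size
    return float(np.sqrt(sq_sum / count))


# --------------------------------------------------------------------------- #
# the CARS loop
# --------------------------------------------------------------------------- #

@dataclass
class CARSIteration:
    index: int
    edf_feature_ids: np.ndarray
    ars_feature_ids: np.ndarray
    rmsecv: float


@dataclass
class CARSResult:
    iterations: list[CARSIteration]
    best_iteration: int  # 1-based index into iterations
    selected_features: np.ndarray
    rmsecv_curve: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    @property
    def selected_names(self) -> list[str]:
        if not self.feature_names:
            return [str(j) for j in self.selected_features]
        return [self.feature_names[j] for j in self.selected_features]

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [it.index for it in self.iterations],
                "n_after_edf": [len(it.edf_feature_ids) for it in self.iterations],
                "n_after_ars": [len(it.ars_feature_ids) for it in self.iterations],
                "rmsecv": [it.rmsecv for it in self.iterations],
            }
        )

    def write_report(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.report_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            import json

            Path(json_path).write_text(json.dumps(self.selected_names))


def best_iteration_index(rmsecv_curve: np.ndarray) -> int:
    """1-based argmin; earliest on ties."""
    curve = np.asarray(rmsecv_curve, dtype=float)
    return int(np.argmin(curve)) + 1


def run_cars(
    X: np.ndarray,
    labels: np.ndarray,
    N: int = 20,
    config: PLSConfig = PLSConfig(),
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> CARSResult:
    """Full CARS run over N sampling iterations.

    Each iteration fits PLS feature weights on a Monte-Carlo row subsample
    of the currently retained features, applies the EDF retention target
    (top-weighted features), then ARS within the survivors, and scores the
    resulting subset by RMSECV on all rows. Feature ids in the result are
    column indices into ``X``.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("CARS needs at least 2 classes")
    m = X.shape[1]
    schedule = edf_schedule(m, N)
    Y = encode_labels(labels, config.label_encoding)
    rng = np.random.default_rng(seed)

    retained = np.arange(m)
    iterations: list[CARSIteration] = []
    for i in range(1, N + 1):
        if len(retained) < 2:
            logger.info("CARS stopped early at run %d: %d features left", i, len(retained))
            break
        with warnings.catch_warnings():
            # component capping is the expected behaviour as the set shrinks
            warnings.filterwarnings("ignore", message="PLS components reduced")
            weights = pls_feature_weights(X[:, retained], Y, config, rng)
        n_target = min(schedule.n_retained(i), len(retained))
        # enforced elimination: keep the top-weighted features
        top = np.argsort(weights)[::-1][:n_target]
        edf_ids = np.sort(retained[top])
        # ARS among the EDF survivors, weight order matching edf_ids
        w_map = dict(zip(retained, weights))
        w_edf = np.array([w_map[j] for j in edf_ids])
        ars_local = ars_sample(w_edf, n_target, rng)
        ars_ids = edf_ids[ars_local]
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="PLS components reduced")
            score = rmsecv(X[:, ars_ids], Y, config, rng=int(rng.integers(2**31)))
        iterations.append(CARSIteration(i, edf_ids, ars_ids, score))
        retained = ars_ids

    curve = np.array([it.rmsecv for it in iterations])
    best = best_iteration_index(curve)
    return CARSResult(
        iterations=iterations,
        best_iteration=best,
        selected_features=iterations[best - 1].ars_feature_ids.copy(),
        rmsecv_curve=curve,
        feature_names=list(feature_names or []),
    )
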