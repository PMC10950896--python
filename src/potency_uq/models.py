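"""Uncertainty-aware regressors on fingerprint/potency data.

Ensembles of decision trees (i.e. random-forest-style models) and of
Tanimoto-distance kNN regressors provide the ensemble-variance route to
uncertainty quantification: each member is fit on a random compound
subsample and a random fingerprint-bit subset, the prediction is the member
mean and the uncertainty the population variance across members. Single DT
and kNN models serve as controls without an uncertainty estimate.

Neural-network variants (MC-dropout feed-forward nets and mean-variance
estimation nets) live in :mod:`potency_uq.nets`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from ._rng import child_seed, stream
from .types import ActivityClass, PredictionSet


class NoUncertaintyError(RuntimeError):
    """Raised when a single-model control is queried for a variance."""


# ---------------------------------------------------------------------------
# data splitting


@dataclass(frozen=True)
class SplitSpec:
    """A random train/test partition of one activity class."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def split_data(cls: ActivityClass, seed: int, train_fraction: float = 0.7) -> SplitSpec:
    """Uniform random 70/30-style compound split, deterministic given seed."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(cls)
    if n == 0:
        raise ValueError("cannot split an empty activity class")
    perm = stream(seed, "split").permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    ids = np.asarray(cls.compound_ids, dtype=object)
    return SplitSpec(
        train_ids=tuple(ids[perm[:n_train]]),
        test_ids=tuple(ids[perm[n_train:]]),
        seed=seed,
        train_fraction=train_fraction,
    )


# ---------------------------------------------------------------------------
# Tanimoto distance


def tanimoto_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - |a AND b| / |a OR b| for equal-width bit vectors.

    Two all-zero vectors are identical by convention (distance 0).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint width mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum((a != 0) | (b != 0)))
    return 0.0 if union == 0 else 1.0 - inter / union


def tanimoto_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto distances between rows of two bit matrices."""
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint width mismatch")
    Af = A.astype(np.float64)
    Bf = B.astype(np.float64)
    inter = Af @ Bf.T
    union = Af.sum(axis=1)[:, None] + Bf.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - inter / union
    dist[union == 0] = 0.0  # pair of empty fingerprints: identical
    return dist


# ---------------------------------------------------------------------------
# ensembles


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters of a kNN or DT ensemble.

    ``max_samples`` / ``max_features`` are fractions of compounds /
    fingerprint bits given to each member; subsampling is without
    replacement by default (``bootstrap=True`` switches compound subsampling
    to with-replacement).
    """

    base_learner: str = "dt"  # {"dt", "knn"}
    n_estimators: int = 100
    max_samples: float = 1.0
    max_features: float = 1.0
    k_neighbors: int = 3  # knn only
    bootstrap: bool = False

    def validate(self) -> None:
        if self.base_learner not in ("dt", "knn"):
            raise ValueError(f"unknown base_learner {self.base_learner!r}")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be positive")
        for name in ("max_samples", "max_features"):
            v = getattr(self, name)
            if not 0.05 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0.05, 1.00]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be positive")


@dataclass
class _KnnMember:
    X: np.ndarray
    y: np.ndarray
    features: np.ndarray
    k: int

    def predict(self, X_test: np.ndarray) -> np.ndarray:
        dist = tanimoto_distance_matrix(X_test[:, self.features], self.X)
        k = min(self.k, self.X.shape[0])
        nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
        return self.y[nearest].mean(axis=1)


@dataclass
class _TreeMember:
    tree: DecisionTreeRegressor
    features: np.ndarray

    def predict(self, X_test: np.ndarray) -> np.ndarray:
        return self.tree.predict(X_test[:, self.features])


@dataclass
class EnsembleModel:
    """A fitted ensemble: one member per compound/bit subsample."""

    config: EnsembleConfig
    members: list
    seed: int
    n_bits: int

    def member_predictions(self, X_test: np.ndarray) -> np.ndarray:
        """(n_members, n_test) matrix of raw member outputs."""
        if X_test.shape[1] != self.n_bits:
            raise ValueError("fingerprint width mismatch")
        return np.stack([m.predict(X_test) for m in self.members])


def fit_ensemble(config: EnsembleConfig, train: ActivityClass, seed: int) -> EnsembleModel:
    """Fit ``n_estimators`` members on random compound/bit subsamples."""
    config.validate()
    if len(train) == 0:
        raise ValueError("empty training set")
    X, y = train.fingerprints, train.pic50
    n, n_bits = X.shape
    n_sub = max(1, math.ceil(config.max_samples * n))
    n_feat = max(1, math.ceil(config.max_features * n_bits))
    if config.base_learner == "knn" and n_sub < config.k_neighbors:
        raise ValueError(
            f"member subsample of {n_sub} compounds is smaller than k={config.k_neighbors}"
        )
    rng = stream(seed, "ensemble")
    # one shared tree seed: members fit on identical data yield identical
    # trees, so a degenerate ensemble has exactly zero variance
    tree_seed = child_seed(seed, "tree")
    members: list = []
    for _ in range(config.n_estimators):
        rows = (
            rng.choice(n, size=n_sub, replace=True)
            if config.bootstrap
            else rng.choice(n, size=n_sub, replace=False)
        )
        cols = np.sort(rng.choice(n_bits, size=n_feat, replace=False))
        if config.base_learner == "dt":
            tree = DecisionTreeRegressor(random_state=tree_seed)
            tree.fit(X[rows][:, cols], y[rows])
            members.append(_TreeMember(tree=tree, features=cols))
        else:
            members.append(
                _KnnMember(X=X[rows][:, cols], y=y[rows], features=cols, k=config.k_neighbors)
            )
    return EnsembleModel(config=config, members=members, seed=seed, n_bits=n_bits)


def predict_with_uncertainty(model, test: ActivityClass) -> PredictionSet:
    """Member-mean prediction with population variance across members.

    For single-model controls the variance is absent; downstream UQ metrics
    must treat it as unavailable.
    """
    if isinstance(model, EnsembleModel):
        preds = model.member_predictions(test.fingerprints)
        variance = preds.var(axis=0)  # population (1/n) convention
        variance[np.ptp(preds, axis=0) == 0.0] = 0.0  # identical members: exactly 0
        return PredictionSet(
            y_true=test.pic50,
            y_pred=preds.mean(axis=0),
            variance=variance,
            compound_ids=list(test.compound_ids),
            model=f"{model.config.base_learner}-ensemble",
        )
    if isinstance(model, SingleModel):
        return model.predict(test)
    raise TypeError(f"unknown model handle {type(model).__name__}")


# ---------------------------------------------------------------------------
# single-model controls


@dataclass
class SingleModel:
    """A single DT or Tanimoto-kNN regressor; no uncertainty estimate."""

    kind: str  # {"dt", "knn"}
    tree: Optional[DecisionTreeRegressor] = None
    X: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    k: int = 3

    def predict(self, test: ActivityClass) -> PredictionSet:
        if self.kind == "dt":
            y_pred = self.tree.predict(test.fingerprints)
        else:
            dist = tanimoto_distance_matrix(test.fingerprints, self.X)
            k = min(self.k, self.X.shape[0])
            nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
            y_pred = self.y[nearest].mean(axis=1)
        return PredictionSet(
            y_true=test.pic50,
            y_pred=y_pred,
            variance=None,
            compound_ids=list(test.compound_ids),
            model=f"single-{self.kind}",
        )

    def variance_for(self, test: ActivityClass):
        raise NoUncertaintyError(f"single {self.kind} model provides no uncertainty")


def fit_single(kind: str, train: ActivityClass, seed: int, k_neighbors: int = 3) -> SingleModel:
    if kind == "dt":
        tree = DecisionTreeRegressor(random_state=child_seed(seed, "single-dt"))
        tree.fit(train.fingerprints, train.pic50)
        return SingleModel(kind="dt", tree=tree)
    if kind == "knn":
        return SingleModel(kind="knn", X=train.fingerprints, y=train.pic50, k=k_neighbors)
    raise ValueError(f"unknown single model kind {kind!r}")


# ---------------------------------------------------------------------------
# hyperparameter optimization

#: search grid for the continuous subsampling fractions
SUBSAMPLE_GRID = (0.05, 0.25, 0.50, 0.75, 1.00)
N_ESTIMATORS_GRID = (100, 150, 200)
K_NEIGHBORS_GRID = (1, 3, 5)


def default_grid(family: str, light: bool = False) -> list[dict]:
    """Canonical, ordered hyperparameter grid for a model family.

    ``light`` restricts the grid for desk-scale runs.
    """
    if family in ("dt-ensemble", "knn-ensemble"):
        samples = (0.5, 1.0) if light else SUBSAMPLE_GRID
        features = (0.5, 1.0) if light else SUBSAMPLE_GRID
        estimators = (100,) if light else N_ESTIMATORS_GRID
        grid = []
        for n_est, ms, mf in itertools.product(estimators, samples, features):
            if family == "knn-ensemble":
                for k in K_NEIGHBORS_GRID:
                    grid.append(
                        dict(n_estimators=n_est, max_samples=ms, max_features=mf, k_neighbors=k)
                    )
            else:
                grid.append(dict(n_estimators=n_est, max_samples=ms, max_features=mf))
        return grid
    if family == "single-knn":
        return [dict(k_neighbors=k) for k in K_NEIGHBORS_GRID]
    if family == "single-dt":
        return [dict()]
    raise ValueError(f"no hyperparameter grid for family {family!r}")


def _fit_predict(family: str, params: dict, train: ActivityClass, test: ActivityClass, seed: int):
    if family == "dt-ensemble":
        model = fit_ensemble(EnsembleConfig(base_learner="dt", **params), train, seed)
    elif family == "knn-ensemble":
        model = fit_ensemble(EnsembleConfig(base_learner="knn", **params), train, seed)
    elif family == "single-dt":
        model = fit_single("dt", train, seed)
    elif family == "single-knn":
        model = fit_single("knn", train, seed, **params)
    else:
        raise ValueError(f"unknown model family {family!r}")
    return predict_with_uncertainty(model, test)


def optimize_hyperparameters(
    family: str,
    train: ActivityClass,
    grid: Sequence[dict] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Grid search minimizing mean k-fold cross-validated MSE.

    Ties break toward the earliest grid point in canonical order;
    deterministic given seed.
    """
    grid = list(grid) if grid is not None else default_grid(family)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return grid[0]
    n = len(train)
    if n < 2 * folds:
        raise ValueError(f"{n} compounds cannot form {folds} folds of >= 2")
    kf = KFold(n_splits=folds, shuffle=True, random_state=child_seed(seed, "cv"))
    fold_indices = list(kf.split(np.arange(n)))
    best_params, best_mse = None, np.inf
    for params in grid:
        fold_mse = []
        for tr_idx, va_idx in fold_indices:
            ps = _fit_predict(
                family, params, train.subset(tr_idx), train.subset(va_idx), seed
            )
            fold_mse.append(float(np.mean(ps.errors**2)))
        mean_mse = float(np.mean(fold_mse))
        if mean_mse < best_mse:
            best_params, best_mse = params, mean_mse
    return best_params
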