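"""Per-size regressors: grid search with k-fold CV over five model families.

Consortia of different sizes have different feature-vector lengths, so one
regressor is trained per consortium size.  Five families are supported —
elastic net, k-nearest neighbours, random forest, epsilon-insensitive support
vector regression and gradient-boosted trees — each tuned by exhaustive grid
search minimising mean validation MSE under k-fold cross-validation (k = 5
by default), after a seeded 75/25 train/test split.  Scale-sensitive
families (elastic net, SVR) are wrapped in a training-fold-only
standardisation pipeline; tree and neighbour families see the raw binary +
probability features.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

__all__ = [
    "ALGORITHMS",
    "DEFAULT_GRIDS",
    "GridSpec",
    "TrainedModel",
    "split_dataset",
    "grid_search",
    "predict",
    "train_all_families",
]

ALGORITHMS = ("elasticnet", "knn", "random_forest", "svm", "gboost")

#: Hyperparameter candidates per family (scikit-learn / xgboost names).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "elasticnet": {
        "alpha": [0.1, 1, 10, 100],
        "l1_ratio": [0.1, 0.5, 0.7, 1.0],
    },
    "knn": {
        "n_neighbors": list(range(1, 22)),
        "weights": ["uniform", "distance"],
        "metric": ["euclidean", "manhattan"],
    },
    "random_forest": {
        "n_estimators": [50, 100, 150, 200],
        "max_features": ["sqrt", "log2"],
        "max_depth": [None, 10, 20, 30],
    },
    "svm": {
        "C": [0.1, 1, 10],
        "kernel": ["rbf", "linear"],
        "gamma": ["scale", "auto"],
    },
    "gboost": {
        "n_estimators": [50, 100, 200],
        "learning_rate": [0.01, 0.1, 0.2],
        "max_depth": [3, 5, 7],
    },
}

#: Families whose features are centred/scaled on the training fold only.
_SCALED = frozenset({"elasticnet", "svm"})


@dataclass(frozen=True)
class GridSpec:
    """One family's search specification."""

    algorithm: str
    grid: Mapping[str, list] | None = None
    cv_folds: int = 5
    split_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")

    def resolved_grid(self) -> dict[str, list]:
        return dict(self.grid) if self.grid is not None else dict(
            DEFAULT_GRIDS[self.algorithm]
        )


@dataclass
class TrainedModel:
    """A fitted per-size regressor plus the metadata needed to apply it."""

    algorithm: str
    best_params: dict
    consortium_size: int
    estimator: object
    seed: int
    feature_names: tuple[str, ...]
    cv_mse: float
    train_mse: float = float("nan")

    @property
    def layout_hash(self) -> str:
        joined = "\n".join(self.feature_names)
        return hashlib.sha256(joined.encode()).hexdigest()[:16]


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "elasticnet":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("est", ElasticNet(max_iter=50_000, random_state=seed)),
            ]
        )
    if algorithm == "knn":
        return KNeighborsRegressor()
    if algorithm == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1)
    if algorithm == "svm":
        return Pipeline([("scale", StandardScaler()), ("est", SVR(epsilon=0.1))])
    if algorithm == "gboost":
        return XGBRegressor(
            random_state=seed, n_jobs=1, tree_method="hist", verbosity=0
        )
    raise ValueError(algorithm)


def split_dataset(
    X: pd.DataFrame,
    y: pd.Series,
    fraction: float = 0.75,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Seeded disjoint, exhaustive row partition (floor rule on train size)."""
    n = len(X)
    if n < 2:
        raise ValueError(f"need at least 2 rows to split, got {n}")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(np.floor(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx, test_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
    return (
        X.iloc[train_idx],
        X.iloc[test_idx],
        y.iloc[train_idx],
        y.iloc[test_idx],
    )


def grid_search(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    spec: GridSpec,
    consortium_size: int = 0,
) -> TrainedModel:
    """Exhaustive CV grid search minimising mean validation MSE.

    Ties are broken by grid order (first winning configuration kept); the
    winner is refitted on the full training set.
    """
    grid = spec.resolved_grid()
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    n = len(X_train)
    if n // spec.cv_folds < 1 or n < 2 * spec.cv_folds:
        raise ValueError(
            f"{n} training rows cannot support {spec.cv_folds}-fold CV"
        )
    if spec.algorithm == "knn" and "n_neighbors" in grid:
        # candidates above the training-fold size cannot be fit
        fold_size = n * (spec.cv_folds - 1) // spec.cv_folds
        feasible = [k for k in grid["n_neighbors"] if k <= fold_size]
        if not feasible:
            raise ValueError(
                f"no n_neighbors candidate fits folds of {fold_size} rows"
            )
        grid = {**grid, "n_neighbors": feasible}
    estimator = _make_estimator(spec.algorithm, spec.seed)
    prefix = "est__" if spec.algorithm in _SCALED else ""
    param_grid = {prefix + k: v for k, v in grid.items()}
    search = GridSearchCV(
        estimator,
        param_grid,
        scoring="neg_mean_squared_error",
        cv=KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed),
        n_jobs=1,
        refit=True,
    )
    search.fit(X_train.to_numpy(), y_train.to_numpy())
    best_params = {
        k.removeprefix("est__"): v for k, v in search.best_params_.items()
    }
    fitted = search.best_estimator_
    train_pred = fitted.predict(X_train.to_numpy())
    return TrainedModel(
        algorithm=spec.algorithm,
        best_params=best_params,
        consortium_size=consortium_size,
        estimator=fitted,
        seed=spec.seed,
        feature_names=tuple(X_train.columns),
        cv_mse=float(-search.best_score_),
        train_mse=float(np.mean((train_pred - y_train.to_numpy()) ** 2)),
    )


def predict(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Apply a trained model after checking the feature layout."""
    if tuple(X.columns) != model.feature_names:
        expected = hashlib.sha256(
            "\n".join(model.feature_names).encode()
        ).hexdigest()[:16]
        actual = hashlib.sha256("\n".join(X.columns).encode()).hexdigest()[:16]
        raise ValueError(
            f"feature layout mismatch: expected {len(model.feature_names)} "
            f"columns (hash {expected}), got {len(X.columns)} (hash {actual})"
        )
    values = np.asarray(model.estimator.predict(X.to_numpy()), dtype=np.float64)
    if not np.isfinite(values).all():  # pragma: no cover - defensive
        raise ArithmeticError("non-finite prediction")
    return values


def train_all_families(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    consortium_size: int,
    seed: int = 0,
    algorithms: Sequence[str] = ALGORITHMS,
    cv_folds: int = 5,
    grids: Mapping[str, Mapping[str, list]] | None = None,
) -> dict[str, TrainedModel]:
    """Grid-search every requested family on one per-size training set."""
    models: dict[str, TrainedModel] = {}
    for algorithm in algorithms:
        spec = GridSpec(
            algorithm=algorithm,
            grid=(grids or {}).get(algorithm),
            cv_folds=cv_folds,
            seed=seed,
        )
        models[algorithm] = grid_search(
            X_train, y_train, spec, consortium_size=consortium_size
        )
    return models
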