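"""Gradient-boosted decision-tree classifier on embedded coordinates.

Defaults follow the tuned configuration: 500 trees, learning rate 0.1,
maximum depth 30.  Backed by scikit-learn's gradient boosting, which is
deterministic for a fixed random seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold


@dataclass
class BoostParams:
    n_trees: int = 500
    learning_rate: float = 0.1
    max_depth: int = 30
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_depth < 1:
            raise ValueError("max_depth must be positive")


@dataclass
class FittedClassifier:
    params: BoostParams
    model: GradientBoostingClassifier
    feature_dim: int


def _validate_training_input(coords: np.ndarray, y: np.ndarray) -> tuple:
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(y).astype(int)
    if coords.ndim != 2:
        raise ValueError("coords must be 2-D")
    if coords.shape[0] != y.shape[0]:
        raise ValueError("coords rows must match label count")
    if not np.isfinite(coords).all():
        raise ValueError("coords contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return coords, y


def fit_classifier(
    coords: np.ndarray,
    y: np.ndarray,
    params: Optional[BoostParams] = None,
    positive_weight: Optional[float] = None,
) -> FittedClassifier:
    """Fit the boosted ensemble; deterministic given ``params.random_seed``.

    ``positive_weight`` optionally upweights the positive class; by default
    samples are unweighted.
    """
    params = params or BoostParams()
    coords, y = _validate_training_input(coords, y)
    model = GradientBoostingClassifier(
        n_estimators=params.n_trees,
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        random_state=params.random_seed,
    )
    sample_weight = None
    if positive_weight is not None:
        sample_weight = np.where(y == 1, positive_weight, 1.0)
    model.fit(coords, y, sample_weight=sample_weight)
    return FittedClassifier(params=params, model=model, feature_dim=coords.shape[1])


def predict_proba(model: FittedClassifier, coords: np.ndarray) -> np.ndarray:
    """P(positive class) for each row; empty input yields an empty vector."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[None, :] if coords.size else coords.reshape(0, model.feature_dim)
    if coords.shape[0] == 0:
        return np.empty(0)
    if coords.shape[1] != model.feature_dim:
        raise ValueError(
            f"coords have {coords.shape[1]} columns, model expects "
            f"{model.feature_dim}"
        )
    return model.model.predict_proba(coords)[:, 1]


def predict_labels(
    model: FittedClassifier, coords: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    return (predict_proba(model, coords) >= threshold).astype(int)


def tune_hyperparameters(
    coords: np.ndarray,
    y: np.ndarray,
    grid: Mapping[str, Sequence],
    folds: int = 10,
    seed: int = 0,
) -> BoostParams:
    """Exhaustive grid search by stratified-CV mean AUC.

    Ties are broken by fewer trees, then shallower depth.  Grid keys are
    ``BoostParams`` field names (``n_trees``, ``learning_rate``,
    ``max_depth``).
    """
    from .evaluation import roc_auc  # local import avoids a cycle

    if not grid:
        raise ValueError("grid must be non-empty")
    coords, y = _validate_training_input(coords, y)
    if folds < 2:
        raise ValueError("folds must be >= 2")

    keys = sorted(grid)
    candidates = [
        replace(BoostParams(random_seed=seed), **dict(zip(keys, values)))
        for values in itertools.product(*(grid[k] for k in keys))
    ]
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(coords, y))

    best = None
    for cand in candidates:
        aucs = []
        for train_idx, test_idx in splits:
            fitted = fit_classifier(coords[train_idx], y[train_idx], cand)
            scores = predict_proba(fitted, coords[test_idx])
            aucs.append(roc_auc(y[test_idx], scores))
        key = (-float(np.mean(aucs)), cand.n_trees, cand.max_depth)
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1]
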