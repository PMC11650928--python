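"""Gradient-boosted fusion of the four patch similarity indices.

The four per-patch similarity indices are concatenated in the fixed order
(head, pec, FDF, FDB) into a 4-vector X. A gradient-boosted regression-tree
ensemble maps X to the final similarity index:

    final = base + sum_i a_i * T_i(X)

where each tree T_i is fitted to the residual left by the previous trees
(r_0 = 0 relative to the base score) and a_i is the per-tree shrinkage. The
ensemble size M is detected automatically by early stopping on a held-out
fraction of the training pairs. Raw predictions are clipped into [0, 1]; a
final index strictly greater than 0.5 means "same individual".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .annotations_io import PATCH_TYPES
from .exceptions import ConfigError, NotFittedError
from .patch_pipeline import Patch
from .similarity_net import EmbeddingCache, PatchModel, similarity

__all__ = [
    "INDEX_ORDER",
    "FusionParams",
    "EnsembleModel",
    "collect_indices",
    "fit_ensemble",
    "final_similarity",
    "decide",
]

#: Fixed coordinate order of the fused index vector.
INDEX_ORDER = PATCH_TYPES  # ("head", "pec", "FDF", "FDB")


def collect_indices(
    patch_models: Mapping[str, PatchModel] | Sequence[PatchModel],
    patches_a: Mapping[str, Patch],
    patches_b: Mapping[str, Patch],
    cache: EmbeddingCache | None = None,
) -> np.ndarray:
    """Compute X = (s_head, s_pec, s_FDF, s_FDB) for one ordered image pair.

    ``patches_a`` / ``patches_b`` map patch type to that image's patch;
    ``patch_models`` covers the four patch types in any order.
    """
    if not isinstance(patch_models, Mapping):
        patch_models = {m.patch_type: m for m in patch_models}
    missing_models = [t for t in INDEX_ORDER if t not in patch_models]
    if missing_models:
        raise ConfigError(f"no model for patch types {missing_models}")
    out = np.empty(len(INDEX_ORDER))
    for k, ptype in enumerate(INDEX_ORDER):
        for side, patches in (("first", patches_a), ("second", patches_b)):
            if ptype not in patches:
                img = next(iter(patches.values())).source_image_id if patches else "?"
                raise ConfigError(
                    f"{side} image ({img!r}) is missing its {ptype!r} patch"
                )
        out[k] = similarity(
            patch_models[ptype], patches_a[ptype], patches_b[ptype], cache=cache
        )
    return out


@dataclass(frozen=True)
class FusionParams:
    """Boosting hyperparameters (tree depth, shrinkage, early stopping)."""

    max_trees: int = 200
    max_depth: int = 3
    learning_rate: float = 0.1
    validation_fraction: float = 0.2
    early_stopping_rounds: int = 10
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if self.max_trees < 1:
            raise ConfigError("max_trees must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ConfigError("validation_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")


@dataclass
class EnsembleModel:
    """Boosted regression-tree fusion model.

    ``trees`` may hold any objects exposing ``predict(X) -> (n,) array``
    (fitted sklearn regression trees, or hand-built stubs in tests);
    ``tree_weights`` are the per-tree coefficients a_i.
    """

    base_score: float = 0.5
    trees: list = field(default_factory=list)
    tree_weights: list[float] = field(default_factory=list)
    fitted: bool = False
    best_iteration: int | None = None

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        X = _as_index_matrix(X)
        pred = np.full(X.shape[0], self.base_score, dtype=np.float64)
        for a_i, tree in zip(self.tree_weights, self.trees):
            pred += a_i * tree.predict(X)
        return pred


def _as_index_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != len(INDEX_ORDER):
        raise ConfigError(f"index vectors must have exactly {len(INDEX_ORDER)} entries")
    return X


def fit_ensemble(
    X_train: np.ndarray,
    labels: np.ndarray,
    params: FusionParams = FusionParams(),
    rng: np.random.Generator | None = None,
) -> EnsembleModel:
    """Fit the boosted ensemble on (index vector, label) pairs.

    Squared-error boosting on the 0/1 labels: each tree fits the residual of
    the running prediction, added with shrinkage ``learning_rate``. M is the
    iteration with the best held-out loss, detected by early stopping with
    ``early_stopping_rounds`` patience on ``validation_fraction`` of the
    training pairs; at least one tree is always kept.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = _as_index_matrix(X_train)
    y = np.asarray(labels, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ConfigError("X_train and labels lengths differ")
    if len(np.unique(y)) < 2:
        raise ConfigError("labels must contain both classes")

    n = X.shape[0]
    order = rng.permutation(n)
    n_val = max(1, int(round(params.validation_fraction * n)))
    if n_val >= n:
        raise ConfigError("validation fraction leaves no training rows")
    val_idx, fit_idx = order[:n_val], order[n_val:]
    Xf, yf = X[fit_idx], y[fit_idx]
    Xv, yv = X[val_idx], y[val_idx]

    model = EnsembleModel(base_score=0.5)
    pred_f = np.full(len(yf), model.base_score)
    pred_v = np.full(len(yv), model.base_score)
    best_loss = np.inf
    best_m = 0
    tree_seed = int(rng.integers(0, 2**31 - 1))
    for m in range(1, params.max_trees + 1):
        residual = yf - pred_f
        tree = DecisionTreeRegressor(
            max_depth=params.max_depth,
            min_samples_leaf=params.min_samples_leaf,
            random_state=tree_seed + m,
        )
        tree.fit(Xf, residual)
        model.trees.append(tree)
        model.tree_weights.append(params.learning_rate)
        pred_f += params.learning_rate * tree.predict(Xf)
        pred_v += params.learning_rate * tree.predict(Xv)
        val_loss = float(np.mean((yv - pred_v) ** 2))
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_m = m
        elif m - best_m >= params.early_stopping_rounds:
            break
    best_m = max(best_m, 1)
    model.trees = model.trees[:best_m]
    model.tree_weights = model.tree_weights[:best_m]
    model.best_iteration = best_m
    model.fitted = True
    return model


def final_similarity(ensemble: EnsembleModel, X) -> float | np.ndarray:
    """Raw boosted prediction clipped into [0, 1]."""
    if not ensemble.fitted:
        raise NotFittedError("ensemble is not fitted")
    single = np.asarray(X).ndim == 1
    out = np.clip(ensemble.predict_raw(X), 0.0, 1.0)
    return float(out[0]) if single else out


def decide(final_index: float) -> str:
    """Apply the strict 0.5 decision rule: same iff index > 0.5."""
    if not 0.0 <= final_index <= 1.0:
        raise ConfigError(f"final index must be in [0, 1], got {final_index}")
    return "same" if final_index > 0.5 else "different"
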