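"""Two-feature Gaussian-kernel SVR scoring function.

Predicts DockQ from just two physical interface features: the cross-chain
heavy-atom contact count Nc (at 4.5 A) and the interface separability S.
Features are standardized on the training data only; the regressor is an
RBF-kernel support vector regression whose kernel width follows the usual
variance heuristic.  Higher predicted values mean more native-like, so this
score is evaluated with ``lower_is_better=False`` (opposite to energies).
Generalization is assessed leave-one-target-out: for each target, the model
is fit on all other targets and Spearman's rho between prediction and DockQ
is measured on the held-out target's models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .evaluation import spearman_rho
from .interface_features import (
    FeatureVector,
    count_interface_contacts,
    interface_separability,
)
from .structio import DimerStructure

__all__ = [
    "SVRHyperparams",
    "SVRScoreModel",
    "featurize",
    "fit",
    "predict",
    "leave_target_out",
]

FEATURE_NAMES = ("n_contacts", "separability")


@dataclass(frozen=True)
class SVRHyperparams:
    """RBF-SVR settings; conventional defaults, declared for reproducibility."""

    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "scale"  # 1 / (n_features * var) width heuristic


@dataclass
class SVRScoreModel:
    pipeline: Pipeline
    hyperparams: SVRHyperparams
    feature_names: tuple[str, str] = FEATURE_NAMES


def featurize(
    model: DimerStructure,
    contact_cutoff: float = 4.5,
    regularization: float = 1.0,
    seed: int = 0,
) -> FeatureVector:
    """(Nc, S) of a dimer, delegating to the interface-feature operations."""
    nc = count_interface_contacts(model, cutoff=contact_cutoff)
    s = interface_separability(model, regularization=regularization, seed=seed)
    return FeatureVector(n_contacts=nc, separability=s, contact_cutoff=contact_cutoff)


def _as_matrix(features: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
    else:
        X = np.array([f.as_array() for f in features], dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected exactly two features per sample")
    return X


def fit(
    features: Sequence[FeatureVector] | np.ndarray,
    dockq: Sequence[float],
    hyperparams: SVRHyperparams | None = None,
    seed: int = 0,
) -> SVRScoreModel:
    """Train the (Nc, S) -> DockQ regressor.

    Deterministic for fixed inputs and hyperparameters; *seed* is accepted
    for interface uniformity.
    """
    hp = hyperparams or SVRHyperparams()
    X = _as_matrix(features)
    y = np.asarray(dockq, dtype=float)
    if len(X) != len(y):
        raise ValueError("features and dockq must have equal length")
    if len(X) < 10:
        raise ValueError("at least 10 training samples are required")
    if np.ptp(X[:, 0]) == 0 or np.ptp(X[:, 1]) == 0:
        raise ValueError("each feature must be non-constant in training data")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svr", SVR(kernel="rbf", C=hp.C, epsilon=hp.epsilon, gamma=hp.gamma)),
        ]
    )
    pipe.fit(X, y)
    return SVRScoreModel(pipeline=pipe, hyperparams=hp)


def predict(
    model: SVRScoreModel, features: Sequence[FeatureVector] | np.ndarray
) -> np.ndarray:
    """Predicted DockQ per input; higher means more native-like."""
    return model.pipeline.predict(_as_matrix(features))


def leave_target_out(
    targets: Mapping[str, tuple[Sequence[FeatureVector] | np.ndarray, Sequence[float]]],
    hyperparams: SVRHyperparams | None = None,
    seed: int = 0,
) -> tuple[dict[str, float], float]:
    """Held-out Spearman rho per target and the per-target mean <rho>_t."""
    names = sorted(targets)
    if len(names) < 2:
        raise ValueError("leave-target-out requires at least two targets")
    prepared = {n: (_as_matrix(f), np.asarray(q, dtype=float)) for n, (f, q) in targets.items()}
    per_target: dict[str, float] = {}
    for held in names:
        X_train = np.vstack([prepared[n][0] for n in names if n != held])
        y_train = np.concatenate([prepared[n][1] for n in names if n != held])
        m = fit(X_train, y_train, hyperparams=hyperparams, seed=seed)
        X_test, y_test = prepared[held]
        per_target[held] = spearman_rho(predict(m, X_test), y_test)
    mean_rho = float(np.mean(list(per_target.values())))
    return per_target, mean_rho
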