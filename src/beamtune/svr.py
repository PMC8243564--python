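"""Support-vector regression of beam parameters from PCA shape features.

Four independent rbf-kernel SVRs map the concatenated (z-scored) feature
vector of the selected profiles to E, sigma_E, s and alpha.  Hyperparameters
(C, epsilon, kernel width) are selected per target by fivefold
cross-validation on the training grid, then the model is refitted on all
nodes.  Targets are standardized for fitting and de-standardized at
prediction; predictions are clipped into the training hypercube H so they
are always usable as optimizer start points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR as _SKSVR

from .params import PARAM_NAMES, BeamParameters, ParameterGrid
from .pca import PCAProfileModel
from .profiles import ProfileSet

__all__ = [
    "SearchGrid",
    "Prediction",
    "RegressorBundle",
    "assemble_features",
    "node_feature_matrix",
    "train_svr",
    "predict_params",
    "save_bundle",
    "load_bundle",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SearchGrid:
    """Hyperparameter candidates for the fivefold CV selection.

    ``epsilon`` values are in standardized-target units; ``gamma_factors``
    multiply the scale heuristic 1 / (n_features * Var(X)).
    """

    C: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    epsilon: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1)
    gamma_factors: tuple[float, ...] = (0.1, 1.0, 10.0)


@dataclass
class Prediction:
    """A predicted beam-parameter tuple plus per-parameter clipping flags."""

    params: BeamParameters
    clipped: dict[str, bool] = field(default_factory=dict)

    @property
    def was_clipped(self) -> bool:
        return any(self.clipped.values())


@dataclass
class RegressorBundle:
    """Four fitted SVRs plus the scalers and provenance metadata."""

    regressors: dict  # param name -> fitted sklearn SVR
    hyperparameters: dict  # param name -> {"C", "epsilon", "gamma"}
    cv_scores: dict  # param name -> best mean CV MSE (standardized units)
    target_mean: np.ndarray  # (4,)
    target_scale: np.ndarray  # (4,)
    hypercube: np.ndarray  # (4, 2)
    grid_hash: str
    profile_labels: tuple  # ordered profile selection the bundle was trained for
    n_features: int


def assemble_features(
    models: list[PCAProfileModel], profile_set: ProfileSet
) -> np.ndarray:
    """Concatenated standardized features (length 3n) of one profile set.

    Profiles must match the models' specs in the same order.
    """
    if len(models) != len(profile_set):
        raise ValueError(
            f"{len(models)} PCA models but {len(profile_set)} profiles"
        )
    parts = []
    for model, profile in zip(models, profile_set):
        if model.spec.label() != profile.spec.label():
            raise ValueError(
                f"profile selection mismatch: model {model.spec.label()} vs "
                f"profile {profile.spec.label()}"
            )
        parts.append(model.standardize(model.transform(profile)))
    return np.concatenate(parts)


def node_feature_matrix(models: list[PCAProfileModel]) -> np.ndarray:
    """Standardized node-feature table, shape (n_nodes, 3n)."""
    return np.hstack([m.standardize(m.node_features) for m in models])


def train_svr(
    models: list[PCAProfileModel],
    grid: ParameterGrid,
    folds: int = 5,
    seed: int = 0,
    search: SearchGrid = SearchGrid(),
) -> RegressorBundle:
    """Fit the four per-parameter SVRs with CV hyperparameter selection.

    For each target the (C, epsilon, gamma) combination minimizing the mean
    CV squared error is selected and refitted on the full training set.
    Fold assignment is seeded, so the selection is deterministic.
    """
    for m in models:
        if m.grid_hash and m.grid_hash != grid.content_hash():
            raise ValueError(
                f"PCA model {m.spec.label()} was fitted on a different grid "
                f"({m.grid_hash} != {grid.content_hash()})"
            )
    X = node_feature_matrix(models)
    Y = grid.nodes
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows vs {Y.shape[0]} grid nodes")
    if X.shape[0] < folds:
        raise ValueError(f"need at least {folds} training rows, got {X.shape[0]}")
    col_sd = X.std(axis=0)
    if np.any(col_sd == 0):
        bad = int(np.nonzero(col_sd == 0)[0][0])
        raise ValueError(
            f"degenerate constant feature at column {bad} "
            f"(profile index {bad // models[0].k}): cannot train SVR"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")

    t_mean = Y.mean(axis=0)
    t_scale = Y.std(axis=0, ddof=1)
    t_scale[t_scale == 0] = 1.0
    Yz = (Y - t_mean) / t_scale
    gamma_scale = 1.0 / (X.shape[1] * X.var())
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))

    regressors, hypers, scores = {}, {}, {}
    for j, name in enumerate(PARAM_NAMES):
        best = None
        for C in search.C:
            for eps in search.epsilon:
                for gf in search.gamma_factors:
                    gamma = gamma_scale * gf
                    mse = 0.0
                    for tr_idx, va_idx in splits:
                        svr = _SKSVR(kernel="rbf", C=C, epsilon=eps, gamma=gamma)
                        svr.fit(X[tr_idx], Yz[tr_idx, j])
                        resid = svr.predict(X[va_idx]) - Yz[va_idx, j]
                        mse += float(np.mean(resid**2))
                    mse /= len(splits)
                    if best is None or mse < best[0]:
                        best = (mse, C, eps, gamma)
        mse, C, eps, gamma = best
        final = _SKSVR(kernel="rbf", C=C, epsilon=eps, gamma=gamma)
        final.fit(X, Yz[:, j])
        regressors[name] = final
        hypers[name] = {"C": C, "epsilon": eps, "gamma": gamma}
        scores[name] = mse
    return RegressorBundle(
        regressors=regressors,
        hyperparameters=hypers,
        cv_scores=scores,
        target_mean=t_mean,
        target_scale=t_scale,
        hypercube=grid.hypercube,
        grid_hash=grid.content_hash(),
        profile_labels=tuple(m.spec.label() for m in models),
        n_features=X.shape[1],
    )


def predict_params(bundle: RegressorBundle, features: np.ndarray) -> Prediction:
    """Predict (E, sigma_E, s, alpha) from a standardized feature vector.

    Each prediction is clipped into the training hypercube; clipping is
    flagged per parameter.
    """
    features = np.asarray(features, dtype=float)
    if features.shape != (bundle.n_features,):
        raise ValueError(
            f"expected {bundle.n_features} features, got shape {features.shape}"
        )
    raw = np.array(
        [
            bundle.regressors[name].predict(features[None, :])[0]
            for name in PARAM_NAMES
        ]
    )
    vals = raw * bundle.target_scale + bundle.target_mean
    lo, hi = bundle.hypercube[:, 0], bundle.hypercube[:, 1]
    clipped_vals = np.clip(vals, lo, hi)
    flags = {
        name: bool(abs(clipped_vals[j] - vals[j]) > 0)
        for j, name in enumerate(PARAM_NAMES)
    }
    return Prediction(
        params=BeamParameters.from_array(clipped_vals), clipped=flags
    )


def predict_from_profiles(
    bundle: RegressorBundle, models: list[PCAProfileModel], profile_set: ProfileSet
) -> Prediction:
    """Convenience: features + guard that the selection matches the bundle."""
    labels = tuple(m.spec.label() for m in models)
    if labels != bundle.profile_labels:
        raise ValueError(
            f"profile selection {labels} does not match the bundle's "
            f"training selection {bundle.profile_labels}"
        )
    return predict_params(bundle, assemble_features(models, profile_set))


def save_bundle(bundle: RegressorBundle, path) -> None:
    joblib.dump({"format": "beamtune-svr", "version": _FORMAT_VERSION, "bundle": bundle}, path)


def load_bundle(path) -> RegressorBundle:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "beamtune-svr":
        raise ValueError(f"{path}: not a beamtune SVR bundle file")
    if payload.get("version") != _FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported bundle version {payload.get('version')}")
    return payload["bundle"]
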