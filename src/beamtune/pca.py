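"""Per-profile-index PCA shape models.

Each profile index i (one field x profile-type pair) gets its own PCA model
fitted on the training profiles over all parameter-grid nodes.  The model
holds the mean shape, the leading k (default 3) orthonormal component
shapes, the full explained-variance spectrum, the k features of every grid
node (row order bound to the grid's node order) and a per-feature z-score
scaler used before regression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .profiles import DoseProfile, ProfileSpec

__all__ = [
    "PCAProfileModel",
    "fit_pca",
    "explained_variance_curve",
    "save_pca",
    "load_pca",
]

_FORMAT_VERSION = 1


@dataclass
class PCAProfileModel:
    """Mean shape + principal components for one profile index."""

    spec: ProfileSpec
    mean_shape: np.ndarray  # (n_points,)
    components: np.ndarray  # (k, n_points), orthonormal rows
    explained_fractions: np.ndarray  # all available components, non-increasing
    node_features: np.ndarray  # (n_nodes, k), grid node order
    feature_mean: np.ndarray  # (k,) z-score scaler over training nodes
    feature_scale: np.ndarray  # (k,)
    grid_hash: str = ""

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def _check_lattice(self, profile: DoseProfile) -> None:
        if profile.doses.shape != self.mean_shape.shape:
            raise ValueError(
                f"profile lattice ({profile.doses.shape[0]} points) does not match "
                f"model lattice ({self.mean_shape.shape[0]} points)"
            )

    def transform(self, profile: DoseProfile) -> np.ndarray:
        """Project a profile onto the k components (after mean subtraction)."""
        self._check_lattice(profile)
        return self.components @ (profile.doses - self.mean_shape)

    def inverse_transform(self, features: np.ndarray) -> np.ndarray:
        """Reconstruct a profile shape from k features: mean + sum f_j c_j."""
        features = np.asarray(features, dtype=float)
        if features.shape != (self.k,):
            raise ValueError(f"expected {self.k} features, got shape {features.shape}")
        return self.mean_shape + features @ self.components

    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features) - self.feature_mean) / self.feature_scale


def fit_pca(
    profiles: list[DoseProfile], k: int = 3, grid_hash: str = ""
) -> PCAProfileModel:
    """Fit a mean-centred PCA on training profiles of one profile index.

    The profiles must share one lattice and be in grid-node order; their
    projections populate ``node_features``.  Components are ordered by
    decreasing variance and sign-fixed so each component's
    largest-magnitude coordinate is positive (PCA signs are otherwise
    arbitrary, which would make persistence unstable).
    """
    if len(profiles) < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} training profiles, got {len(profiles)}")
    spec = profiles[0].spec
    n = spec.n_points
    for p in profiles:
        if p.spec.n_points != n or abs(p.spec.step - spec.step) > 1e-12:
            raise ValueError(
                f"profile {p.spec.label()} lattice does not match {spec.label()}"
            )
    X = np.stack([p.doses for p in profiles])
    sk = _SKPCA(n_components=None, svd_solver="full")
    all_features = sk.fit_transform(X)
    components = sk.components_[:k].copy()
    features = all_features[:, :k].copy()
    # stable sign convention
    for j in range(k):
        imax = int(np.argmax(np.abs(components[j])))
        if components[j, imax] < 0:
            components[j] *= -1.0
            features[:, j] *= -1.0
    scale = features.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    return PCAProfileModel(
        spec=spec,
        mean_shape=sk.mean_.copy(),
        components=components,
        explained_fractions=sk.explained_variance_ratio_.copy(),
        node_features=features,
        feature_mean=features.mean(axis=0),
        feature_scale=scale,
        grid_hash=grid_hash,
    )


def explained_variance_curve(model: PCAProfileModel) -> np.ndarray:
    """Cumulative explained-variance fraction vs number of components."""
    return np.cumsum(model.explained_fractions)


def save_pca(model: PCAProfileModel, path) -> None:
    """Persist one PCA model as self-describing JSON (one file per index)."""
    spec = model.spec
    payload = {
        "format": "beamtune-pca",
        "version": _FORMAT_VERSION,
        "spec": {
            "field_size": spec.field_size,
            "kind": spec.kind,
            "depth": spec.depth,
            "range_cm": list(spec.range_cm),
            "step": spec.step,
        },
        "grid_hash": model.grid_hash,
        "mean_shape": model.mean_shape.tolist(),
        "components": model.components.tolist(),
        "explained_fractions": model.explained_fractions.tolist(),
        "node_features": model.node_features.tolist(),
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_pca(path) -> PCAProfileModel:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: truncated or corrupt PCA model file") from exc
    if payload.get("format") != "beamtune-pca":
        raise ValueError(f"{path}: not a beamtune PCA model file")
    if payload.get("version") != _FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported PCA model version {payload.get('version')}"
        )
    s = payload["spec"]
    spec = ProfileSpec(
        field_size=s["field_size"],
        kind=s["kind"],
        depth=s["depth"],
        range_cm=tuple(s["range_cm"]),
        step=s["step"],
    )
    return PCAProfileModel(
        spec=spec,
        mean_shape=np.array(payload["mean_shape"]),
        components=np.array(payload["components"]),
        explained_fractions=np.array(payload["explained_fractions"]),
        node_features=np.array(payload["node_features"]),
        feature_mean=np.array(payload["feature_mean"]),
        feature_scale=np.array(payload["feature_scale"]),
        grid_hash=payload.get("grid_hash", ""),
    )
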