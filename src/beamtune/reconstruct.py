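"""Reconstruction-based refinement of beam-parameter estimates.

The PCA features of each profile index form a scalar field over the 4D
training grid.  Multilinear interpolation of those fields gives the
features — and, through the inverse PCA transform, full reconstructed
profiles — at any parameter point P inside the hypercube H.  Refinement
minimizes the weighted squared mismatch

    sum_i  w_i * || Prof_i - RecProf_i(P) ||^2

over P in H with SLSQP, starting from the regression prediction.  Because
the multilinear objective is only piecewise-smooth, a seeded multi-start
(start point plus perturbations of one grid step per axis) is used by
default to escape cell-boundary kinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import minimize

from .params import PARAM_NAMES, BeamParameters, ParameterGrid
from .pca import PCAProfileModel
from .profiles import DoseProfile, ProfileSet

__all__ = ["FeatureField", "TuneResult", "objective", "refine"]


class FeatureField:
    """Per-profile-index PCA feature tables arranged on the 4D grid."""

    def __init__(self, grid: ParameterGrid, models: list[PCAProfileModel]):
        for m in models:
            if m.node_features.shape[0] != grid.n_nodes:
                raise ValueError(
                    f"model {m.spec.label()}: {m.node_features.shape[0]} feature rows "
                    f"for a grid of {grid.n_nodes} nodes"
                )
            if m.grid_hash and m.grid_hash != grid.content_hash():
                raise ValueError(
                    f"model {m.spec.label()} was fitted on a different grid"
                )
        self.grid = grid
        self.models = list(models)
        shape = grid.shape
        self._interps = []
        self._active = [i for i, n in enumerate(shape) if n > 1]
        active_axes = tuple(grid.axes[i] for i in self._active)
        for m in models:
            table = m.node_features.reshape(*shape, m.k)
            table = table.reshape(
                tuple(shape[i] for i in self._active) + (m.k,)
            )  # drop singleton axes (their coordinate is fixed)
            self._interps.append(
                RegularGridInterpolator(
                    active_axes, table, method="linear", bounds_error=True
                )
            )

    def interpolate(self, p: BeamParameters | np.ndarray) -> np.ndarray:
        """Concatenated raw features (length 3n) at P; exact at grid nodes."""
        arr = p.as_array() if isinstance(p, BeamParameters) else np.asarray(p, float)
        if not self.grid.contains(arr):
            raise ValueError(f"point {arr} outside the training hypercube; clip first")
        for i, n in enumerate(self.grid.shape):
            if n == 1 and abs(arr[i] - self.grid.axes[i][0]) > 1e-9:
                raise ValueError(
                    f"{PARAM_NAMES[i]} axis is a singleton at {self.grid.axes[i][0]}; "
                    f"cannot interpolate at {arr[i]}"
                )
        query = np.clip(
            arr[self._active],
            [self.grid.axes[i][0] for i in self._active],
            [self.grid.axes[i][-1] for i in self._active],
        )
        return np.concatenate([itp(query[None, :])[0] for itp in self._interps])

    def reconstruct(self, p: BeamParameters | np.ndarray) -> ProfileSet:
        """RecProf(P): inverse PCA transform of the interpolated features."""
        feats = self.interpolate(p)
        out, pos = [], 0
        for m in self.models:
            shape = m.inverse_transform(feats[pos : pos + m.k])
            out.append(DoseProfile(spec=m.spec, doses=np.maximum(shape, 0.0)))
            pos += m.k
        return ProfileSet(out)


def objective(
    field_: FeatureField,
    p: BeamParameters | np.ndarray,
    observed: ProfileSet,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted sum of squared L2 profile mismatches at parameter point P."""
    if weights is None:
        weights = np.ones(len(observed))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(observed),):
        raise ValueError(f"need {len(observed)} weights, got {weights.shape}")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    rec = field_.reconstruct(p)
    total = 0.0
    for w, obs, r in zip(weights, observed, rec):
        if obs.spec.n_points != r.spec.n_points:
            raise ValueError(
                f"observed profile {obs.spec.label()} lattice does not match model"
            )
        total += w * float(np.sum((obs.doses - r.doses) ** 2))
    return total


@dataclass
class TuneResult:
    """Outcome of one reconstruction-based refinement."""

    start: BeamParameters
    optimum: BeamParameters
    objective_start: float
    objective_optimum: float
    weights: np.ndarray
    reconstructed: ProfileSet
    success: bool
    message: str = ""
    per_profile: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "start": dict(zip(PARAM_NAMES, self.start.as_array().tolist())),
            "optimum": dict(zip(PARAM_NAMES, self.optimum.as_array().tolist())),
            "objective_start": self.objective_start,
            "objective_optimum": self.objective_optimum,
            "weights": np.asarray(self.weights).tolist(),
            "success": self.success,
            "message": self.message,
            "per_profile": self.per_profile,
        }


def refine(
    field_: FeatureField,
    start: BeamParameters,
    observed: ProfileSet,
    weights: np.ndarray | None = None,
    fix_sigma_e: float | None = None,
    multi_start: int = 5,
    seed: int = 0,
    maxiter: int = 200,
    ftol: float = 1e-12,
    max_restarts: int = 5,
) -> TuneResult:
    """Bound-constrained SLSQP minimization of the profile mismatch over H.

    The search runs in per-axis normalized coordinates (forward-difference
    step 1e-6 of each axis span).  Each start point is polished by
    restarting SLSQP at its own result until the objective stops improving:
    the objective is only piecewise-smooth (multilinear interpolation has
    gradient kinks at cell boundaries), and a restart resets the
    quasi-Newton state once the iterate has settled inside one smooth cell.
    With ``fix_sigma_e`` set, sigma_E is frozen at that value and only the
    remaining coordinates move.  The returned optimum never scores worse
    than the start point; if the optimizer fails outright the start point
    is returned with ``success=False``.
    """
    grid = field_.grid
    box = grid.hypercube
    if weights is None:
        weights = np.ones(len(observed))
    weights = np.asarray(weights, dtype=float)

    x0 = np.clip(start.as_array(), box[:, 0], box[:, 1])
    sigma_idx = PARAM_NAMES.index("sigma_E")
    if fix_sigma_e is not None:
        x0[sigma_idx] = np.clip(fix_sigma_e, box[sigma_idx, 0], box[sigma_idx, 1])
    free = [
        i
        for i in range(4)
        if box[i, 1] > box[i, 0] and not (fix_sigma_e is not None and i == sigma_idx)
    ]
    span = box[:, 1] - box[:, 0]

    def expand(u: np.ndarray) -> np.ndarray:
        x = x0.copy()
        for j, i in enumerate(free):
            x[i] = box[i, 0] + u[j] * span[i]
        return x

    def fun(u: np.ndarray) -> float:
        return objective(field_, expand(u), observed, weights)

    f_start = fun(np.array([(x0[i] - box[i, 0]) / span[i] for i in free]))
    if not free:
        rec = field_.reconstruct(x0)
        return TuneResult(
            start=BeamParameters.from_array(x0),
            optimum=BeamParameters.from_array(x0),
            objective_start=f_start,
            objective_optimum=f_start,
            weights=weights,
            reconstructed=rec,
            success=True,
            message="no free coordinates",
        )

    rng = np.random.default_rng(seed)
    step = grid.spacing()
    starts = [x0]
    for _ in range(max(0, multi_start - 1)):
        pert = x0.copy()
        for i in free:
            pert[i] += rng.choice([-1.0, 1.0]) * step[i]
        starts.append(np.clip(pert, box[:, 0], box[:, 1]))

    best_x, best_f, any_success, messages = x0, f_start, False, []
    for s in starts:
        u = np.array([(s[i] - box[i, 0]) / span[i] for i in free])
        f_prev = np.inf
        for _ in range(max_restarts):
            res = minimize(
                fun,
                u,
                method="SLSQP",
                bounds=[(0.0, 1.0)] * len(free),
                options={"maxiter": maxiter, "ftol": ftol, "eps": 1e-6},
            )
            u = np.clip(res.x, 0.0, 1.0)
            if not np.isfinite(res.fun) or f_prev - res.fun <= ftol * max(
                1.0, abs(f_prev)
            ):
                break
            f_prev = float(res.fun)
        messages.append(res.message)
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = expand(u), float(res.fun)
        any_success = any_success or bool(res.success)

    if best_f < f_start:  # final polish of the winner with a finer step
        u = np.array([(best_x[i] - box[i, 0]) / span[i] for i in free])
        res = minimize(
            fun,
            u,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * len(free),
            options={"maxiter": maxiter, "ftol": 1e-16, "eps": 1e-7},
        )
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = expand(np.clip(res.x, 0.0, 1.0)), float(res.fun)

    rec = field_.reconstruct(best_x)
    return TuneResult(
        start=BeamParameters.from_array(x0),
        optimum=BeamParameters.from_array(best_x),
        objective_start=f_start,
        objective_optimum=best_f,
        weights=weights,
        reconstructed=rec,
        success=any_success or best_f <= f_start,
        message="; ".join(dict.fromkeys(messages)),
    )
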