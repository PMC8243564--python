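"""Workflow orchestration.

Workflow A (model building): generate the virtual-linac dose grids over the
training grid, extract and normalize the selected profiles, fit the
per-index PCA models, train the SVR bundle and/or the deep model, and
evaluate parameter recovery on freshly sampled test tuples.

Workflow B (beam tuning): read measured profiles, place them on the
100%-at-D_max scale, predict a start point with either regressor, refine
it against reconstructed profiles, and report per-profile fit metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .deep import TrainedDeepModel, predict_deep
from .metrics import RegressionReport, gamma_1d, mean_abs_error, regression_report
from .params import BeamParameters, ParameterGrid, TestPool, sample_test_tuples
from .pca import PCAProfileModel, fit_pca
from .profiles import ProfileSet, extract_profiles, normalize_dose3d
from .reconstruct import FeatureField, TuneResult, refine
from .surrogate import generate_dose3d, write_dose3d
from .svr import RegressorBundle, assemble_features, predict_params

__all__ = [
    "TrainingData",
    "plan_manifest",
    "build_training_data",
    "profile_sets_for_tuples",
    "fit_pca_models",
    "evaluate_regressor",
    "tune_beam",
]


@dataclass
class TrainingData:
    """Per-node profile sets plus the dose-file manifest."""

    grid: ParameterGrid
    profile_sets: list  # ProfileSet per grid node, node order
    manifest: pd.DataFrame  # one row per (node, field) dose grid

    def targets(self) -> np.ndarray:
        return self.grid.nodes


def _profile_sets_for(
    config: RunConfig,
    tuples: list[BeamParameters],
    seed_offset: int,
    write_dose_dir=None,
    manifest_rows: list | None = None,
) -> list[ProfileSet]:
    """Generate dose grids for each tuple x field and extract the selection.

    Each (tuple, field) pair gets its own child seed spawned from the
    master seed, so reruns are bit-identical and tuples are independent.
    """
    model = config.surrogate()
    fields = sorted({p.field_size for p in config.profiles})
    specs_by_field = {
        f: [p for p in config.profiles if p.field_size == f] for f in fields
    }
    ss = np.random.SeedSequence(entropy=(config.seed, seed_offset))
    children = ss.spawn(len(tuples) * len(fields))
    out = []
    for ti, p in enumerate(tuples):
        by_label = {}
        for fi, f in enumerate(fields):
            rng = np.random.default_rng(children[ti * len(fields) + fi])
            dose = generate_dose3d(p, f, noise=config.noise, seed=rng, model=model)
            dose = normalize_dose3d(dose)
            for prof in extract_profiles(dose, specs_by_field[f]):
                by_label[prof.spec.label()] = prof
            if manifest_rows is not None:
                fname = f"dose_t{ti:04d}_f{f:g}.txt"
                manifest_rows.append(
                    {
                        "tuple_index": ti,
                        "E": p.E,
                        "sigma_E": p.sigma_E,
                        "s": p.s,
                        "alpha": p.alpha,
                        "field_cm": f,
                        "file": fname,
                        "written": write_dose_dir is not None,
                    }
                )
                if write_dose_dir is not None:
                    write_dose3d(dose, f"{write_dose_dir}/{fname}")
        out.append(ProfileSet([by_label[s.label()] for s in config.profiles]))
    return out


def plan_manifest(config: RunConfig, fields=None) -> pd.DataFrame:
    """Enumerate the (node, field) dose grids a training build will produce,
    without generating them: one row per 3D dose file."""
    grid = config.grid()
    fields = sorted(fields if fields is not None else {p.field_size for p in config.profiles})
    rows = []
    for ti, node in enumerate(grid.nodes):
        for f in fields:
            rows.append(
                {
                    "tuple_index": ti,
                    "E": node[0],
                    "sigma_E": node[1],
                    "s": node[2],
                    "alpha": node[3],
                    "field_cm": f,
                    "file": f"dose_t{ti:04d}_f{f:g}.txt",
                    "written": False,
                }
            )
    return pd.DataFrame(rows)


def build_training_data(config: RunConfig, write_dose_dir=None) -> TrainingData:
    """Workflow A, stage 1: dose grids + normalized profiles for every node.

    The manifest lists one dose-grid entry per (node, field); the grids are
    written as text files only when ``write_dose_dir`` is given (they are
    large), otherwise only the extracted profiles are kept.
    """
    grid = config.grid()
    rows: list = []
    sets = _profile_sets_for(
        config,
        grid.node_tuples(),
        seed_offset=0,
        write_dose_dir=write_dose_dir,
        manifest_rows=rows,
    )
    return TrainingData(grid=grid, profile_sets=sets, manifest=pd.DataFrame(rows))


def profile_sets_for_tuples(
    config: RunConfig, tuples: list[BeamParameters], seed_offset: int = 1
) -> list[ProfileSet]:
    """Profiles for arbitrary parameter tuples (e.g. the sampled test set)."""
    return _profile_sets_for(config, tuples, seed_offset=seed_offset)


def fit_pca_models(
    training: TrainingData, k: int = 3
) -> list[PCAProfileModel]:
    """One PCA shape model per selected profile index, node order preserved."""
    n_profiles = len(training.profile_sets[0])
    grid_hash = training.grid.content_hash()
    return [
        fit_pca([ps[i] for ps in training.profile_sets], k=k, grid_hash=grid_hash)
        for i in range(n_profiles)
    ]


@dataclass
class RecoveryResult:
    """Parameter-recovery evaluation of one regressor on test tuples."""

    true_params: list
    predicted: list  # regression-only predictions
    refined: list | None  # after reconstruction-based refinement (or None)
    report_predicted: RegressionReport
    report_refined: RegressionReport | None = None
    extras: dict = field(default_factory=dict)


def evaluate_regressor(
    config: RunConfig,
    models: list[PCAProfileModel],
    regressor,
    test_sets: list[ProfileSet],
    test_tuples: list[BeamParameters],
    grid: ParameterGrid,
    refine_estimates: bool = True,
) -> RecoveryResult:
    """Predict each test tuple (SVR bundle or deep model), optionally refine,
    and summarize predicted-vs-true regression statistics."""
    field_ = FeatureField(grid, models) if refine_estimates else None
    predicted, refined = [], [] if refine_estimates else None
    for ps in test_sets:
        if isinstance(regressor, RegressorBundle):
            pred = predict_params(regressor, assemble_features(models, ps))
        elif isinstance(regressor, TrainedDeepModel):
            pred = predict_deep(regressor, ps)
        else:
            raise TypeError(f"unknown regressor type {type(regressor)!r}")
        predicted.append(pred.params)
        if refine_estimates:
            result = refine(
                field_,
                pred.params,
                ps,
                weights=np.asarray(config.weights, dtype=float),
                fix_sigma_e=config.fixed_sigma_e,
                seed=config.seed,
            )
            refined.append(result.optimum)
    rep_pred = regression_report(test_tuples, predicted)
    rep_ref = regression_report(test_tuples, refined) if refine_estimates else None
    return RecoveryResult(
        true_params=test_tuples,
        predicted=predicted,
        refined=refined,
        report_predicted=rep_pred,
        report_refined=rep_ref,
    )


def sample_default_test_set(
    config: RunConfig, pool: TestPool
) -> tuple[list[BeamParameters], list[ProfileSet]]:
    tuples = sample_test_tuples(pool)
    return tuples, profile_sets_for_tuples(config, tuples)


def tune_beam(
    config: RunConfig,
    models: list[PCAProfileModel],
    regressor,
    observed: ProfileSet,
    grid: ParameterGrid | None = None,
) -> TuneResult:
    """Workflow B: predict a start point from the observed (measured)
    profiles, refine it against reconstructed profiles, and attach
    per-profile MAE and 1D-gamma (3%/3 mm) fit metrics."""
    grid = grid or config.grid()
    if isinstance(regressor, RegressorBundle):
        pred = predict_params(regressor, assemble_features(models, observed))
    elif isinstance(regressor, TrainedDeepModel):
        pred = predict_deep(regressor, observed)
    else:
        raise TypeError(f"unknown regressor type {type(regressor)!r}")
    field_ = FeatureField(grid, models)
    result = refine(
        field_,
        pred.params,
        observed,
        weights=np.asarray(config.weights, dtype=float),
        fix_sigma_e=config.fixed_sigma_e,
        seed=config.seed,
    )
    for obs, rec in zip(observed, result.reconstructed):
        g = gamma_1d(obs, rec, dose_tol_pct=3.0, dta_mm=3.0)
        result.per_profile.append(
            {
                "profile": obs.spec.label(),
                "mae_pct": mean_abs_error(obs, rec),
                "gamma_pass_rate_pct": g.pass_rate,
            }
        )
    return result
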