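"""Evaluation metrics: predicted-vs-true regression reports, mean absolute
profile error and the 1D gamma index.

The gamma index is the standard composite dosimetry QA metric: a reference
point passes if some point of the evaluated curve lies within the combined
dose-difference / distance-to-agreement ellipse (here 3% of the D_max dose
and 3 mm by default, global normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import PARAM_NAMES
from .profiles import DoseProfile

__all__ = [
    "RegressionReport",
    "GammaResult",
    "regression_report",
    "mean_abs_error",
    "gamma_1d",
]


@dataclass
class ParamRegression:
    slope: float
    intercept: float
    pearson_r: float
    r2: float
    error_sd: float
    degenerate: bool = False  # constant true values: slope undefined


@dataclass
class RegressionReport:
    """Per-parameter OLS of predicted on true + prediction-error SD."""

    per_param: dict  # name -> ParamRegression

    def __getitem__(self, name: str) -> ParamRegression:
        return self.per_param[name]

    def to_dict(self) -> dict:
        return {
            name: {
                "slope": pr.slope,
                "intercept": pr.intercept,
                "pearson_r": pr.pearson_r,
                "r2": pr.r2,
                "error_sd": pr.error_sd,
                "degenerate": pr.degenerate,
            }
            for name, pr in self.per_param.items()
        }


def regression_report(true_params, predicted_params) -> RegressionReport:
    """OLS of predicted on true, per parameter, plus the SD (ddof=1) of the
    true-minus-predicted differences.

    ``true_params`` / ``predicted_params``: sequences of BeamParameters or
    arrays of shape (n, 4) in (E, sigma_E, s, alpha) order; n >= 3.
    """
    T = np.array(
        [p.as_array() if hasattr(p, "as_array") else np.asarray(p) for p in true_params]
    )
    P = np.array(
        [
            p.as_array() if hasattr(p, "as_array") else np.asarray(p)
            for p in predicted_params
        ]
    )
    if T.shape != P.shape or T.ndim != 2 or T.shape[1] != 4:
        raise ValueError(f"shape mismatch: true {T.shape} vs predicted {P.shape}")
    if T.shape[0] < 3:
        raise ValueError("need at least 3 pairs per parameter")
    out = {}
    for j, name in enumerate(PARAM_NAMES):
        t, q = T[:, j], P[:, j]
        sd = float(np.std(t - q, ddof=1))
        if np.ptp(t) == 0:
            out[name] = ParamRegression(
                slope=np.nan, intercept=np.nan, pearson_r=np.nan, r2=np.nan,
                error_sd=sd, degenerate=True,
            )
            continue
        res = stats.linregress(t, q)
        out[name] = ParamRegression(
            slope=float(res.slope),
            intercept=float(res.intercept),
            pearson_r=float(res.rvalue),
            r2=float(res.rvalue**2),
            error_sd=sd,
        )
    return RegressionReport(per_param=out)


def _check_same_lattice(a: DoseProfile, b: DoseProfile) -> None:
    if a.spec.n_points != b.spec.n_points or not np.allclose(
        a.positions, b.positions, atol=1e-9
    ):
        raise ValueError(
            f"profiles {a.spec.label()} and {b.spec.label()} are on different lattices"
        )


def mean_abs_error(a: DoseProfile, b: DoseProfile) -> float:
    """Mean |a - b| over samples, in percentage points of the D_max dose."""
    _check_same_lattice(a, b)
    return float(np.mean(np.abs(a.doses - b.doses)))


@dataclass
class GammaResult:
    gamma: np.ndarray  # per reference point
    pass_rate: float  # % of points with gamma <= 1
    dose_tol_pct: float
    dta_mm: float


def gamma_1d(
    reference: DoseProfile,
    evaluated: DoseProfile,
    dose_tol_pct: float = 3.0,
    dta_mm: float = 3.0,
    local: bool = False,
    resample_mm: float = 0.1,
) -> GammaResult:
    """1D gamma index of ``evaluated`` against ``reference``.

    Doses must be on the normalized scale where the D_max dose is 100, so a
    global ``dose_tol_pct`` of 3 means 3 percentage points.  For each
    reference point the evaluated curve is resampled at ``resample_mm``
    within +-3 DTA (beyond which the distance term alone exceeds 1) and

        gamma(r) = min_e sqrt(((D_e - D_r)/dD)^2 + ((x_e - x_r)/DTA)^2)

    is minimized over those samples.  With ``local=True`` the dose
    tolerance is ``dose_tol_pct`` % of the local reference dose instead.
    """
    ref_pos, ref_dose = reference.positions, reference.doses
    ev_pos, ev_dose = evaluated.positions, evaluated.doses
    lo = max(ref_pos[0], ev_pos[0])
    hi = min(ref_pos[-1], ev_pos[-1])
    if lo > hi:
        raise ValueError("reference and evaluated profiles do not overlap")
    dta_cm = dta_mm / 10.0
    window = 3.0 * dta_cm
    step_cm = resample_mm / 10.0
    n_off = int(round(window / step_cm))
    offsets = step_cm * np.arange(-n_off, n_off + 1)  # exact zero at the centre
    gammas = np.empty(ref_pos.size)
    for i, (xr, dr) in enumerate(zip(ref_pos, ref_dose)):
        xs = xr + offsets
        inside = (xs >= ev_pos[0] - 1e-9) & (xs <= ev_pos[-1] + 1e-9)
        if not np.any(inside):
            # no evaluated data within the search window: dose term at the
            # nearest evaluated point, full distance penalty
            xs = np.array([np.clip(xr, ev_pos[0], ev_pos[-1])])
            inside = np.array([True])
        xs = xs[inside]
        ds = np.interp(xs, ev_pos, ev_dose)
        tol = dose_tol_pct * (dr / 100.0) if local else dose_tol_pct
        if tol <= 0:
            tol = np.finfo(float).tiny
        g2 = ((ds - dr) / tol) ** 2 + ((xs - xr) / dta_cm) ** 2
        gammas[i] = np.sqrt(np.min(g2))
    pass_rate = 100.0 * float(np.mean(gammas <= 1.0))
    return GammaResult(
        gamma=gammas, pass_rate=pass_rate, dose_tol_pct=dose_tol_pct, dta_mm=dta_mm
    )
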