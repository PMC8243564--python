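"""Parametric virtual linac: analytic water-phantom dose as a function of
the primary-beam parameters, plus the 3D dose-grid text format.

This module stands in for a full Monte Carlo treatment head + phantom
simulation.  It is *not* transport physics: it is a smooth, physically
plausible parametric model designed so that

* the depth dose builds up to a maximum at ``D_max`` (1.4 cm by default)
  and then falls off exponentially, penetrating deeper for higher mean
  energy ``E``;
* lateral profiles are double-error-function field shapes whose penumbra
  widens with focal-spot size ``s``, divergence ``alpha`` and depth, with a
  small in-field "horn" that softens as ``E`` grows and low-amplitude
  scatter wings outside the field edge that grow with ``alpha``;
* the energy-spectrum width ``sigma_E`` perturbs the dose only very weakly
  (by design about two orders of magnitude less than ``E`` over the
  training ranges), so that ``sigma_E`` is essentially unrecoverable from
  profile shapes — mirroring the behaviour of real 6 MV beams;
* optional multiplicative Gaussian noise emulates Monte Carlo tally
  uncertainty, with 1 SD = 0.75% of local dose (2 SD = 1.5%).

Doses are tallied on a fixed 100^3 voxel lattice covering a 50 cm water
cube: voxel centres x, y in {-24.75 + 0.5 i} cm and depth z in
{0.25 + 0.5 k} cm, i, k = 0..99, with the beam axis along z and the source
at SSD = 100 cm above the phantom surface (z = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .params import BeamParameters

__all__ = [
    "GRID_AXES",
    "SurrogateModel",
    "Dose3D",
    "depth_dose",
    "lateral_dose",
    "generate_dose3d",
    "write_dose3d",
    "read_dose3d",
]

_N = 100
_LATERAL_AXIS = -24.75 + 0.5 * np.arange(_N)  # cm, voxel centres
_DEPTH_AXIS = 0.25 + 0.5 * np.arange(_N)  # cm

#: Canonical tally lattice: (x, y, z) voxel-centre coordinates.
GRID_AXES = (_LATERAL_AXIS.copy(), _LATERAL_AXIS.copy(), _DEPTH_AXIS.copy())


@dataclass(frozen=True)
class SurrogateModel:
    """Constants of the analytic dose model.

    The defaults put the depth-dose maximum at 1.4 cm and give roughly 65%
    depth dose at 10 cm for a 10 x 10 cm^2 field at E = 6.0 MeV.  The
    ``sigma_coupling`` is deliberately tiny: over the full training ranges
    the profile change due to sigma_E is far smaller than that due to E
    (the documented weak-sigma_E property).
    """

    ssd: float = 100.0  # source-to-surface distance, cm
    d_max: float = 1.4  # depth of dose maximum on axis, cm
    mu0: float = 0.30  # attenuation scale, cm^-1 MeV (mu = mu0 / E at 10x10)
    field_mu_coeff: float = 0.04  # phantom-scatter softening of mu with field size
    sigma_coupling: float = 1e-4  # cm^-1 MeV^-1, weak sigma_E attenuation term
    p_base: float = 0.22  # cm, intrinsic penumbra (source occlusion, 0.5 cm tally
    # pitch and chamber volume averaging; a 6 MV 80-20 penumbra is several mm)
    p_spot: float = 0.50  # penumbra per cm of focal-spot FWHM (geometric
    # projection of the spot through the collimator aperture)
    spot_proj: float = 50.0  # cm, effective collimator distance for spot projection
    p_div: float = 0.02  # cm penumbra per degree of divergence (divergence acts
    # mostly on in-field flatness and scatter wings, not the edge gradient)
    p_scatter: float = 0.003  # cm penumbra per cm depth (in-phantom scatter)
    horn_coeff: float = 0.10  # horn amplitude per MeV below horn_e0
    horn_e0: float = 7.0  # MeV, energy at which horns vanish
    flat_div: float = 0.04  # extra in-field horn amplitude per degree of divergence
    horn_depth_decay: float = 30.0  # cm, horns wash out with depth (off-axis hardening)
    wing_base: float = 0.003  # scatter-wing amplitude (fraction of axis dose)
    wing_div: float = 0.012  # extra wing amplitude per degree of divergence
    wing_decay: float = 3.0  # cm, wing exponential decay length
    noise_sd: float = 0.0075  # 1 SD of multiplicative tally noise (2 SD = 1.5%)
    fields: tuple[float, ...] = (3.0, 10.0, 30.0)  # nominal square field sides, cm

    def mu(self, E: float, field: float) -> float:
        """Effective linear attenuation (cm^-1); decreasing in E and field size."""
        return (self.mu0 / E) * (1.0 - self.field_mu_coeff * np.log(field / 10.0))


DEFAULT_MODEL = SurrogateModel()


@lru_cache(maxsize=4096)
def _buildup_rate(mu: float, d_max: float) -> float:
    """Solve for beta so that (1 - e^(-beta z)) e^(-mu z) peaks at z = d_max."""

    def f(beta: float) -> float:
        e = np.exp(-beta * d_max)
        return beta * e - mu * (1.0 - e)

    return float(brentq(f, 1e-6, 200.0, xtol=1e-12))


def depth_dose(
    z: np.ndarray | float,
    p: BeamParameters,
    field: float,
    model: SurrogateModel = DEFAULT_MODEL,
) -> np.ndarray | float:
    """Relative on-axis dose at depth ``z`` (cm).

    Build-up-then-falloff curve ``(1 - e^(-beta z)) e^(-mu_tot z)`` with the
    build-up rate solved so the maximum sits at ``model.d_max``.  ``mu_tot``
    decreases with E (harder beams penetrate deeper) and carries the weak
    multiplicative sigma_E perturbation.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise ValueError("depth z must be >= 0")
    mu_tot = model.mu(p.E, field) + model.sigma_coupling * p.sigma_E
    beta = _buildup_rate(round(mu_tot, 12), model.d_max)
    out = (1.0 - np.exp(-beta * z_arr)) * np.exp(-mu_tot * z_arr)
    return out if isinstance(z, np.ndarray) else float(out)


def _penumbra_sigma(z, p: BeamParameters, model: SurrogateModel):
    """Gaussian penumbra width (cm) at depth z: affine in s, alpha and z."""
    return (
        model.p_base
        + model.p_spot * p.s * (1.0 + z / model.spot_proj)
        + model.p_div * p.alpha * (1.0 + z / model.ssd)
        + model.p_scatter * z
    )


def _lateral_unnormalized(x, z, p: BeamParameters, field: float, model: SurrogateModel):
    w = 0.5 * field * (1.0 + z / model.ssd)  # geometric half-width at depth z
    sig = _penumbra_sigma(z, p, model)
    shape = 0.5 * (erf((w - x) / (np.sqrt(2.0) * sig)) + erf((w + x) / (np.sqrt(2.0) * sig)))
    u = x / w
    horn_amp = (
        (model.horn_coeff * max(model.horn_e0 - p.E, 0.0) + model.flat_div * p.alpha)
        * np.sqrt(field / 10.0)
        * np.exp(-z / model.horn_depth_decay)
    )
    horn = 1.0 + horn_amp * u**2 * np.exp(-(u**4))
    wing_amp = (model.wing_base + model.wing_div * p.alpha) * np.sqrt(field / 10.0)
    wing = wing_amp * np.exp(-np.maximum(np.abs(x) - w, 0.0) / model.wing_decay)
    return shape * horn + wing


def lateral_dose(
    x: np.ndarray | float,
    z: float,
    p: BeamParameters,
    field: float,
    model: SurrogateModel = DEFAULT_MODEL,
) -> np.ndarray | float:
    """Relative off-axis dose at position ``x`` and depth ``z``, centre = 1.

    Symmetric double-error-function field edge (half-width scaled by the
    geometric divergence (SSD+z)/SSD) with horn and scatter-wing terms; the
    curve is normalized to exactly 1 on the beam axis.
    """
    if z < 0:
        raise ValueError("depth z must be >= 0")
    x_arr = np.asarray(x, dtype=float)
    val = _lateral_unnormalized(x_arr, z, p, field, model)
    centre = _lateral_unnormalized(np.array(0.0), z, p, field, model)
    out = val / centre
    return out if isinstance(x, np.ndarray) else float(out)


@dataclass
class Dose3D:
    """Dose on the canonical 100^3 tally lattice for one field size.

    ``values`` is indexed ``[z, y, x]``; axes hold the voxel-centre
    coordinates in cm.  Doses are non-negative, in arbitrary units before
    normalization and in % of the D_max axis dose after.
    """

    field_size: float
    values: np.ndarray
    x: np.ndarray = dc_field(default_factory=lambda: GRID_AXES[0].copy())
    y: np.ndarray = dc_field(default_factory=lambda: GRID_AXES[1].copy())
    z: np.ndarray = dc_field(default_factory=lambda: GRID_AXES[2].copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.z), len(self.y), len(self.x))
        if self.values.shape != expected:
            raise ValueError(
                f"dose array shape {self.values.shape} does not match grid {expected}"
            )
        if np.any(self.values < 0):
            raise ValueError("doses must be non-negative")

    @property
    def n_values(self) -> int:
        return int(self.values.size)


def generate_dose3d(
    p: BeamParameters,
    field: float,
    noise: bool = True,
    seed: int | np.random.Generator | None = 0,
    model: SurrogateModel = DEFAULT_MODEL,
) -> Dose3D:
    """Evaluate the separable surrogate on every voxel of the tally lattice.

    ``dose[z,y,x] = depth_dose(z) * lateral_dose(x,z) * lateral_dose(y,z)``;
    with ``noise`` on, every voxel is multiplied by ``1 + eps`` with
    ``eps ~ N(0, noise_sd^2)`` drawn from the seeded generator.
    """
    if not any(abs(field - f) < 1e-9 for f in model.fields):
        raise ValueError(f"unknown field size {field}; configured: {model.fields}")
    x_ax, y_ax, z_ax = GRID_AXES
    dd = depth_dose(z_ax, p, field, model)  # (nz,)
    lat = np.empty((len(z_ax), len(x_ax)))
    for k, z in enumerate(z_ax):
        lat[k] = lateral_dose(x_ax, float(z), p, field, model)
    vals = dd[:, None, None] * lat[:, :, None] * lat[:, None, :]
    # lat[:, :, None] varies along y (axis 1), lat[:, None, :] along x (axis 2);
    # the two factors are identical because the lattice is x/y symmetric.
    if noise:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        vals = vals * (1.0 + model.noise_sd * rng.standard_normal(vals.shape))
        np.maximum(vals, 0.0, out=vals)
    return Dose3D(field_size=field, values=vals)


_HEADER_MAGIC = "beamtune-dose3d v1"


def write_dose3d(d: Dose3D, path) -> None:
    """Write a dose grid as plain text: '#' header then values in
    z-outer, y-middle, x-inner order, >= 9 significant digits."""
    with open(path, "w") as fh:
        fh.write(f"# {_HEADER_MAGIC}\n")
        fh.write(f"# field_cm: {d.field_size:g}\n")
        for name, ax in (("x", d.x), ("y", d.y), ("z", d.z)):
            step = ax[1] - ax[0] if len(ax) > 1 else 0.0
            fh.write(f"# {name}: {ax[0]:.9g} {step:.9g} {len(ax)}\n")
        flat = d.values.reshape(-1)  # [z, y, x] C-order = z-outer, x-inner
        for start in range(0, flat.size, 5):
            fh.write(" ".join(f"{v:.9g}" for v in flat[start : start + 5]) + "\n")


def read_dose3d(path) -> Dose3D:
    """Read a dose grid written by :func:`write_dose3d`; strict validation."""
    header: dict[str, str] = {}
    values: list[float] = []
    with open(path) as fh:
        first = fh.readline().strip()
        if first != f"# {_HEADER_MAGIC}":
            raise ValueError(f"{path}: not a beamtune dose3d file (bad magic line)")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, rest = line[1:].partition(":")
                header[key.strip()] = rest.strip()
                continue
            for tok in line.split():
                try:
                    v = float(tok)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad dose value {tok!r}") from exc
                if v < 0:
                    raise ValueError(f"{path}:{lineno}: negative dose {v}")
                values.append(v)
    for key in ("field_cm", "x", "y", "z"):
        if key not in header:
            raise ValueError(f"{path}: missing header key {key!r}")
    field = float(header["field_cm"].lower().split("x")[0])
    axes = {}
    for name in ("x", "y", "z"):
        origin_s, step_s, count_s = header[name].split()
        origin, step, count = float(origin_s), float(step_s), int(count_s)
        axes[name] = origin + step * np.arange(count)
    expected = len(axes["x"]) * len(axes["y"]) * len(axes["z"])
    if len(values) != expected:
        raise ValueError(
            f"{path}: expected {expected} dose values, found {len(values)}"
        )
    vals = np.array(values).reshape(len(axes["z"]), len(axes["y"]), len(axes["x"]))
    return Dose3D(field_size=field, values=vals, x=axes["x"], y=axes["y"], z=axes["z"])
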