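"""Profile extraction and normalization.

Converts 3D water-phantom dose grids into the 1D curves that clinical
dosimetry works with: one percentage-depth-dose curve along the beam axis
and lateral profiles at named depths, on a uniform (default 1 mm) lattice,
normalized so the on-axis dose at D_max is 100%.  Also reads measured
position/dose text files and places them on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .surrogate import Dose3D

__all__ = [
    "ProfileSpec",
    "DoseProfile",
    "ProfileSet",
    "D_MAX_DEPTH",
    "LATERAL_DEPTHS",
    "DEPTH_RANGE_MAX",
    "LATERAL_RANGE_MAX",
    "prof_max_specs",
    "default_profile_specs",
    "normalize_dose3d",
    "extract_profiles",
    "clip_profile",
    "read_measured_profile",
    "write_profile",
    "normalize_measured_set",
]

#: Depth of the on-axis dose maximum used as the 100% normalization point (cm).
D_MAX_DEPTH = 1.4

#: Standard lateral-profile depths (cm).
LATERAL_DEPTHS = (1.4, 5.0, 10.0, 20.0, 30.0)

#: Largest extractable ranges on the canonical tally lattice (cm).
DEPTH_RANGE_MAX = (0.3, 49.7)
LATERAL_RANGE_MAX = (-24.7, 24.7)

_POS_ATOL = 1e-6  # lattice alignment tolerance, cm


@dataclass(frozen=True)
class ProfileSpec:
    """Identity and sampling lattice of one profile.

    ``kind`` is 'depth' (dose vs depth on the beam axis) or 'lateral'
    (dose vs off-axis position at fixed ``depth``).  ``range_cm`` is the
    [min, max] position window and ``step`` the sampling step in cm.
    """

    field_size: float
    kind: str
    depth: float | None = None
    range_cm: tuple[float, float] = None  # type: ignore[assignment]
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("depth", "lateral"):
            raise ValueError(f"kind must be 'depth' or 'lateral', got {self.kind!r}")
        if self.kind == "lateral" and self.depth is None:
            raise ValueError("lateral profiles need a depth")
        if self.range_cm is None:
            default = DEPTH_RANGE_MAX if self.kind == "depth" else LATERAL_RANGE_MAX
            object.__setattr__(self, "range_cm", tuple(default))
        lo, hi = self.range_cm
        if not lo < hi:
            raise ValueError(f"range min must be < max, got {self.range_cm}")
        if self.kind == "depth" and lo < 0:
            raise ValueError("depth-profile positions must be >= 0")
        if not self.step > 0:
            raise ValueError("step must be > 0")

    @property
    def positions(self) -> np.ndarray:
        lo, hi = self.range_cm
        n = int(round((hi - lo) / self.step)) + 1
        return lo + self.step * np.arange(n)

    @property
    def n_points(self) -> int:
        lo, hi = self.range_cm
        return int(round((hi - lo) / self.step)) + 1

    def label(self) -> str:
        if self.kind == "depth":
            return f"f{self.field_size:g}_depth"
        return f"f{self.field_size:g}_lat{self.depth:g}"


@dataclass
class DoseProfile:
    """A 1D dose curve on the uniform lattice of its :class:`ProfileSpec`."""

    spec: ProfileSpec
    doses: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.shape != (self.spec.n_points,):
            raise ValueError(
                f"profile {self.spec.label()}: expected {self.spec.n_points} doses, "
                f"got {self.doses.shape}"
            )
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")

    @property
    def positions(self) -> np.ndarray:
        return self.spec.positions


class ProfileSet(list):
    """Ordered list of :class:`DoseProfile` with pairwise-distinct specs."""

    def __init__(self, profiles: Sequence[DoseProfile] = ()):
        super().__init__(profiles)
        labels = [p.spec.label() for p in self]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate profile specs in set: {labels}")

    @property
    def specs(self) -> list[ProfileSpec]:
        return [p.spec for p in self]


def prof_max_specs(
    fields: Sequence[float] = (3.0, 10.0, 30.0), step: float = 0.1
) -> list[ProfileSpec]:
    """The maximal profile design: per field, one depth profile plus lateral
    profiles at the five standard depths (18 profiles for three fields)."""
    specs = []
    for f in fields:
        specs.append(ProfileSpec(field_size=f, kind="depth", step=step))
        for d in LATERAL_DEPTHS:
            specs.append(ProfileSpec(field_size=f, kind="lateral", depth=d, step=step))
    return specs


def default_profile_specs(step: float = 0.1, ranges: dict | None = None) -> list[ProfileSpec]:
    """The default six-profile design: depth, lateral at D_max and lateral at
    10 cm depth, for the 10 x 10 and 30 x 30 cm^2 fields."""
    specs = []
    for f in (10.0, 30.0):
        for kind, depth in (("depth", None), ("lateral", D_MAX_DEPTH), ("lateral", 10.0)):
            rng = None if ranges is None else ranges.get((f, kind, depth))
            kwargs = {} if rng is None else {"range_cm": tuple(rng)}
            specs.append(ProfileSpec(field_size=f, kind=kind, depth=depth, step=step, **kwargs))
    return specs


def _axis_dose_interpolator(d: Dose3D) -> RegularGridInterpolator:
    return RegularGridInterpolator(
        (d.z, d.y, d.x), d.values, method="linear", bounds_error=True
    )


def normalize_dose3d(d: Dose3D) -> Dose3D:
    """Rescale so the on-axis dose at D_max (1.4 cm) is 100%.

    The lattice has no voxel centred on the axis or exactly at 1.4 cm, so
    the reference dose is obtained by trilinear interpolation to
    (x, y, z) = (0, 0, 1.4).
    """
    if not (d.z[0] <= D_MAX_DEPTH <= d.z[-1]):
        raise ValueError("dose grid does not cover the D_max depth of 1.4 cm")
    interp = _axis_dose_interpolator(d)
    ref = float(interp([[D_MAX_DEPTH, 0.0, 0.0]])[0])
    if ref <= 0:
        raise ValueError(f"reference dose at D_max is non-positive ({ref})")
    return Dose3D(
        field_size=d.field_size, values=d.values * (100.0 / ref), x=d.x, y=d.y, z=d.z
    )


def extract_profiles(d: Dose3D, specs: Sequence[ProfileSpec]) -> ProfileSet:
    """Extract the requested profiles from a (normalized) dose grid.

    Depth profiles are sampled along (0, 0, z); lateral profiles are the
    mean of the x- and y-direction cuts through the axis at the requested
    depth (the averaging assumes a circularly symmetric focal spot and can
    be bypassed by extracting a single cut via ``average_xy=False`` on
    :func:`_extract_one`).  All sampling uses trilinear interpolation of the
    tallied doses onto the spec lattice.
    """
    interp = _axis_dose_interpolator(d)
    out = []
    for spec in specs:
        if abs(spec.field_size - d.field_size) > 1e-9:
            raise ValueError(
                f"spec field {spec.field_size} does not match dose grid field {d.field_size}"
            )
        out.append(_extract_one(d, interp, spec))
    return ProfileSet(out)


def _extract_one(
    d: Dose3D,
    interp: RegularGridInterpolator,
    spec: ProfileSpec,
    average_xy: bool = True,
) -> DoseProfile:
    pos = spec.positions
    if spec.kind == "depth":
        lo, hi = d.z[0], d.z[-1]
        if pos[0] < lo - _POS_ATOL or pos[-1] > hi + _POS_ATOL:
            raise ValueError(
                f"depth range {spec.range_cm} exceeds grid span [{lo}, {hi}]"
            )
        pts = np.column_stack([pos, np.zeros_like(pos), np.zeros_like(pos)])
        doses = interp(pts)
    else:
        lo, hi = d.x[0], d.x[-1]
        if pos[0] < lo - _POS_ATOL or pos[-1] > hi + _POS_ATOL:
            raise ValueError(
                f"lateral range {spec.range_cm} exceeds grid span [{lo}, {hi}]"
            )
        if not (d.z[0] <= spec.depth <= d.z[-1]):
            raise ValueError(f"lateral depth {spec.depth} outside grid span")
        zcol = np.full_like(pos, spec.depth)
        zero = np.zeros_like(pos)
        x_cut = interp(np.column_stack([zcol, zero, pos]))
        if average_xy:
            y_cut = interp(np.column_stack([zcol, pos, zero]))
            doses = 0.5 * (x_cut + y_cut)
        else:
            doses = x_cut
    return DoseProfile(spec=spec, doses=np.maximum(doses, 0.0))


def clip_profile(p: DoseProfile, range_cm: tuple[float, float]) -> DoseProfile:
    """Restrict a profile to a sub-range on its existing lattice.

    The clipped profile keeps the lattice points of ``p`` that fall inside
    the requested range (no resampling, hence no interpolation drift); at
    least two points must survive.
    """
    lo, hi = range_cm
    pos = p.positions
    if lo < pos[0] - _POS_ATOL or hi > pos[-1] + _POS_ATOL:
        raise ValueError(
            f"requested range {range_cm} outside profile range "
            f"[{pos[0]:g}, {pos[-1]:g}]"
        )
    mask = (pos >= lo - _POS_ATOL) & (pos <= hi + _POS_ATOL)
    kept = np.nonzero(mask)[0]
    if kept.size < 2:
        raise ValueError(f"range {range_cm} keeps fewer than two lattice points")
    new_spec = replace(
        p.spec, range_cm=(float(pos[kept[0]]), float(pos[kept[-1]]))
    )
    return DoseProfile(spec=new_spec, doses=p.doses[kept])


def read_measured_profile(path, step: float = 0.1) -> DoseProfile:
    """Read a measured profile text file and resample it to the 1 mm lattice.

    Format: ``# key: value`` header lines (required: field_cm, kind;
    lateral profiles also need depth_cm; optional position_unit, cm or mm),
    then two whitespace-separated columns (position, dose).  Positions must
    be strictly monotonic; values are linearly interpolated onto the
    uniform lattice spanning the measured range.
    """
    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, rest = line[1:].partition(":")
                header[key.strip()] = rest.strip()
                continue
            toks = line.split()
            if len(toks) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {toks}")
            rows.append((float(toks[0]), float(toks[1])))
    for key in ("field_cm", "kind"):
        if key not in header:
            raise ValueError(f"{path}: missing header key {key!r}")
    kind = header["kind"]
    depth = float(header["depth_cm"]) if "depth_cm" in header else None
    if kind == "lateral" and depth is None:
        raise ValueError(f"{path}: lateral profile requires a depth_cm header")
    unit = header.get("position_unit", "cm")
    scale = {"cm": 1.0, "mm": 0.1}.get(unit)
    if scale is None:
        raise ValueError(f"{path}: unknown position_unit {unit!r}")
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least two data rows")
    pos = np.array([r[0] for r in rows]) * scale
    dose = np.array([r[1] for r in rows])
    diffs = np.diff(pos)
    if np.any(diffs == 0):
        dup = int(np.nonzero(diffs == 0)[0][0])
        raise ValueError(
            f"{path}: duplicated position {pos[dup]:g} at data rows {dup + 1} and {dup + 2}"
        )
    if np.all(diffs < 0):
        pos, dose = pos[::-1], dose[::-1]
    elif not np.all(diffs > 0):
        raise ValueError(f"{path}: positions are not monotonic")
    lo = np.ceil(pos[0] / step - _POS_ATOL) * step
    hi = np.floor(pos[-1] / step + _POS_ATOL) * step
    spec = ProfileSpec(
        field_size=float(header["field_cm"].lower().split("x")[0]),
        kind=kind,
        depth=depth,
        range_cm=(float(lo), float(hi)),
        step=step,
    )
    doses = np.interp(spec.positions, pos, dose)
    return DoseProfile(spec=spec, doses=np.maximum(doses, 0.0))


def write_profile(p: DoseProfile, path) -> None:
    """Write a profile in the measured-profile text format (round-trips
    through :func:`read_measured_profile`)."""
    with open(path, "w") as fh:
        fh.write(f"# field_cm: {p.spec.field_size:g}\n")
        fh.write(f"# kind: {p.spec.kind}\n")
        if p.spec.depth is not None:
            fh.write(f"# depth_cm: {p.spec.depth:g}\n")
        fh.write("# position_unit: cm\n")
        for x, d in zip(p.positions, p.doses):
            fh.write(f"{x:.4f} {d:.9g}\n")


def _refined_max(positions: np.ndarray, doses: np.ndarray) -> float:
    """Maximum dose with parabolic refinement around the sampled peak."""
    i = int(np.argmax(doses))
    if 0 < i < len(doses) - 1:
        y0, y1, y2 = doses[i - 1], doses[i], doses[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            return float(y1 - 0.25 * (y0 - y2) * delta)
    return float(doses[i])


def normalize_measured_set(
    profiles: Sequence[DoseProfile], fallback_reference: float | None = None
) -> ProfileSet:
    """Place measured profiles on the common 100%-at-D_max scale.

    Depth profiles are scaled so their (parabolically refined) maximum is
    100.  Each lateral profile is anchored so its centre (position 0) value
    equals the normalized depth dose at its depth — taken from the same
    field's depth profile when available, from any depth profile otherwise,
    or from ``fallback_reference`` (% value at the lateral's depth) if no
    depth profile exists at all.
    """
    depth_profiles: dict[float, DoseProfile] = {}
    out: list[DoseProfile] = []
    for p in profiles:
        if p.spec.kind == "depth":
            scale = 100.0 / _refined_max(p.positions, p.doses)
            q = DoseProfile(spec=p.spec, doses=p.doses * scale)
            depth_profiles[p.spec.field_size] = q
            out.append(q)
        else:
            out.append(p)
    for i, p in enumerate(out):
        if p.spec.kind != "lateral":
            continue
        ref_profile = depth_profiles.get(p.spec.field_size) or next(
            iter(depth_profiles.values()), None
        )
        if ref_profile is not None:
            target = float(
                np.interp(p.spec.depth, ref_profile.positions, ref_profile.doses)
            )
        elif fallback_reference is not None:
            target = float(fallback_reference)
        else:
            raise ValueError(
                f"lateral profile {p.spec.label()}: no depth profile available "
                "and no fallback reference configured"
            )
        centre = float(np.interp(0.0, p.positions, p.doses))
        if centre <= 0:
            raise ValueError(f"lateral profile {p.spec.label()}: non-positive centre dose")
        out[i] = DoseProfile(spec=p.spec, doses=p.doses * (target / centre))
    return ProfileSet(out)
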