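"""Run configuration: a single plain-text (YAML) file describing the grid,
the field sizes, the profile selection with ranges, weights, the sigma_E
policy and all seeds.  Every run can write back a resolved copy for exact
replay.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .params import DEFAULT_TRAINING_AXES, ParameterGrid, enumerate_training_grid
from .profiles import ProfileSpec, default_profile_specs
from .surrogate import SurrogateModel

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything one training/tuning run needs, in plain data."""

    grid_axes: tuple = DEFAULT_TRAINING_AXES
    fields: tuple = (10.0, 30.0)
    profiles: list = field(default_factory=list)  # list of ProfileSpec
    weights: list = field(default_factory=list)  # per profile, defaults to 1
    sigma_e_policy: str | float = "free"  # "free" or a fixed MeV value
    seed: int = 0
    noise: bool = True
    pca_components: int = 3
    step: float = 0.1
    surrogate_overrides: dict = field(default_factory=dict)
    output_dir: str = "beamtune_out"

    def __post_init__(self) -> None:
        if not self.profiles:
            self.profiles = default_profile_specs(step=self.step)
        if not self.weights:
            self.weights = [1.0] * len(self.profiles)
        if len(self.weights) != len(self.profiles):
            raise ValueError(
                f"{len(self.weights)} weights for {len(self.profiles)} profiles"
            )
        selection_fields = {p.field_size for p in self.profiles}
        missing = selection_fields - {float(f) for f in self.fields}
        if missing:
            raise ValueError(
                f"profile selection references fields {sorted(missing)} "
                f"not in the configured field list {self.fields}"
            )
        if isinstance(self.sigma_e_policy, str) and self.sigma_e_policy != "free":
            raise ValueError(
                f"sigma_e_policy must be 'free' or a number, got {self.sigma_e_policy!r}"
            )

    def grid(self) -> ParameterGrid:
        return enumerate_training_grid(self.grid_axes)

    def surrogate(self) -> SurrogateModel:
        base = dataclasses.asdict(SurrogateModel())
        base.update(self.surrogate_overrides)
        base["fields"] = tuple(base["fields"])
        return SurrogateModel(**base)

    @property
    def fixed_sigma_e(self) -> float | None:
        return None if self.sigma_e_policy == "free" else float(self.sigma_e_policy)

    # ---- persistence -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "grid": {
                name: list(map(float, ax))
                for name, ax in zip(("E", "sigma_E", "s", "alpha"), self.grid_axes)
            },
            "fields": list(map(float, self.fields)),
            "profiles": [
                {
                    "field": p.field_size,
                    "kind": p.kind,
                    "depth": p.depth,
                    "range": list(p.range_cm),
                    "step": p.step,
                }
                for p in self.profiles
            ],
            "weights": list(map(float, self.weights)),
            "sigma_e_policy": self.sigma_e_policy,
            "seed": self.seed,
            "noise": self.noise,
            "pca_components": self.pca_components,
            "step": self.step,
            "surrogate": dict(self.surrogate_overrides),
            "output_dir": self.output_dir,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        grid = d.get("grid", {})
        axes = (
            tuple(
                tuple(grid.get(name, default))
                for name, default in zip(
                    ("E", "sigma_E", "s", "alpha"), DEFAULT_TRAINING_AXES
                )
            )
            if grid
            else DEFAULT_TRAINING_AXES
        )
        step = float(d.get("step", 0.1))
        profiles = [
            ProfileSpec(
                field_size=float(p["field"]),
                kind=p["kind"],
                depth=None if p.get("depth") is None else float(p["depth"]),
                range_cm=None if p.get("range") is None else tuple(p["range"]),
                step=float(p.get("step", step)),
            )
            for p in d.get("profiles", [])
        ]
        return cls(
            grid_axes=axes,
            fields=tuple(d.get("fields", (10.0, 30.0))),
            profiles=profiles,
            weights=list(d.get("weights", [])),
            sigma_e_policy=d.get("sigma_e_policy", "free"),
            seed=int(d.get("seed", 0)),
            noise=bool(d.get("noise", True)),
            pca_components=int(d.get("pca_components", 3)),
            step=step,
            surrogate_overrides=dict(d.get("surrogate", {})),
            output_dir=str(d.get("output_dir", "beamtune_out")),
        )

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
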