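"""Beam-parameter space: tuples, the regular training grid and test sampling.

A virtual linac's primary electron beam is described by four numbers: the
mean energy ``E`` (MeV), the FWHM of the (Gaussian) energy spectrum
``sigma_E`` (MeV), the focal-spot FWHM ``s`` (cm) and the angular divergence
``alpha`` (degrees).  Training data for the regression models are generated
on a regular rectilinear grid of such tuples; the axis-aligned bounding box
of that grid (the hypercube ``H``) is the domain on which every downstream
estimate is constrained to live.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "BeamParameters",
    "ParameterGrid",
    "TestPool",
    "enumerate_training_grid",
    "sample_test_tuples",
    "DEFAULT_TRAINING_AXES",
    "DEFAULT_TEST_POOL",
]

#: Canonical parameter ordering used for every array representation.
PARAM_NAMES = ("E", "sigma_E", "s", "alpha")

#: Node-matching tolerance in native units; grid values are short decimals,
#: exact float equality is fragile after parsing.
NODE_ATOL = 1e-9


@dataclass(frozen=True)
class BeamParameters:
    """One primary-electron-beam parameter tuple ``(E, sigma_E, s, alpha)``.

    Units: E and sigma_E in MeV, s in cm, alpha in degrees.
    """

    E: float
    sigma_E: float
    s: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"mean energy E must be > 0, got {self.E}")
        for name in ("sigma_E", "s", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.sigma_E, self.s, self.alpha], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "BeamParameters":
        E, sigma_E, s, alpha = (float(v) for v in values)
        return cls(E=E, sigma_E=sigma_E, s=s, alpha=alpha)


class ParameterGrid:
    """Regular rectilinear grid of beam-parameter tuples.

    ``axes`` is a per-parameter strictly increasing list of node values, in
    the order of :data:`PARAM_NAMES`.  ``nodes`` is their Cartesian product
    in lexicographic order (E slowest, alpha fastest), so node -> row index
    is reproducible across runs and persistence.
    """

    def __init__(self, axes: Sequence[Sequence[float]]):
        if len(axes) != 4:
            raise ValueError(f"expected 4 axes (E, sigma_E, s, alpha), got {len(axes)}")
        clean = []
        for name, axis in zip(PARAM_NAMES, axes):
            arr = np.asarray(axis, dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"axis {name!r} must be a non-empty 1D sequence")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"axis {name!r} must be strictly increasing: {arr}")
            clean.append(arr)
        self.axes: tuple[np.ndarray, ...] = tuple(clean)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(len(a) for a in self.axes)  # type: ignore[return-value]

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def nodes(self) -> np.ndarray:
        """All grid tuples, shape (n_nodes, 4), lexicographic order."""
        prod = list(itertools.product(*self.axes))
        return np.array(prod, dtype=float)

    @property
    def hypercube(self) -> np.ndarray:
        """Per-parameter [min, max] bounds, shape (4, 2)."""
        return np.array([[a[0], a[-1]] for a in self.axes], dtype=float)

    def node_tuples(self) -> list[BeamParameters]:
        return [BeamParameters.from_array(row) for row in self.nodes]

    def contains(self, p: BeamParameters | Sequence[float]) -> bool:
        """True if ``p`` lies inside the hypercube H (bounds inclusive)."""
        arr = p.as_array() if isinstance(p, BeamParameters) else np.asarray(p, float)
        box = self.hypercube
        return bool(np.all(arr >= box[:, 0] - NODE_ATOL) and np.all(arr <= box[:, 1] + NODE_ATOL))

    def is_node(self, p: BeamParameters | Sequence[float]) -> bool:
        """True if ``p`` coincides with a grid node in all four coordinates."""
        arr = p.as_array() if isinstance(p, BeamParameters) else np.asarray(p, float)
        return all(np.any(np.abs(axis - v) <= NODE_ATOL) for axis, v in zip(self.axes, arr))

    def node_index(self, p: BeamParameters | Sequence[float]) -> int:
        """Row index of node ``p`` in :attr:`nodes`; raises if not a node."""
        arr = p.as_array() if isinstance(p, BeamParameters) else np.asarray(p, float)
        idx = []
        for name, axis, v in zip(PARAM_NAMES, self.axes, arr):
            hits = np.nonzero(np.abs(axis - v) <= NODE_ATOL)[0]
            if hits.size == 0:
                raise KeyError(f"value {v} not on axis {name!r}")
            idx.append(int(hits[0]))
        return int(np.ravel_multi_index(idx, self.shape))

    def spacing(self) -> np.ndarray:
        """Representative per-axis grid step (median spacing; 0 for singletons)."""
        return np.array(
            [float(np.median(np.diff(a))) if a.size > 1 else 0.0 for a in self.axes]
        )

    def content_hash(self) -> str:
        """Stable hash of the axis values, used to guard model consistency."""
        import hashlib

        h = hashlib.sha256()
        for a in self.axes:
            h.update(np.round(a, 12).tobytes())
        return h.hexdigest()[:16]


def enumerate_training_grid(axes: Sequence[Sequence[float]]) -> ParameterGrid:
    """Build the regular training grid S from four per-parameter value lists.

    Nodes are ordered lexicographically with E slowest-varying and alpha
    fastest; the hypercube H is spanned by the axis extremes.
    """
    return ParameterGrid(axes)


@dataclass
class TestPool:
    """Candidate values for sampling test tuples disjoint from the grid S.

    ``values`` are per-parameter candidate lists *after* exclusions; any
    tuple drawn from their product differs from every node of S in at least
    the coordinates whose candidate list avoids the grid's axis values.
    """

    values: Sequence[Sequence[float]]
    n_samples: int
    seed: int

    __test__ = False  # not a pytest class, despite the domain name

    def __post_init__(self) -> None:
        if len(self.values) != 4:
            raise ValueError("expected 4 candidate lists (E, sigma_E, s, alpha)")
        self.values = tuple(np.asarray(v, dtype=float) for v in self.values)
        if any(v.size == 0 for v in self.values):
            raise ValueError("candidate lists must be non-empty after exclusions")

    @property
    def pool_size(self) -> int:
        return int(np.prod([v.size for v in self.values]))


def sample_test_tuples(pool: TestPool) -> list[BeamParameters]:
    """Sample test tuples uniformly without replacement from the pool product.

    Reproducible for a fixed ``pool.seed``.  Raises if the requested sample
    size exceeds the product pool size.
    """
    if pool.n_samples > pool.pool_size:
        raise ValueError(
            f"sample size {pool.n_samples} exceeds pool size {pool.pool_size}"
        )
    rng = np.random.default_rng(pool.seed)
    flat = rng.choice(pool.pool_size, size=pool.n_samples, replace=False)
    shape = tuple(v.size for v in pool.values)
    out = []
    for f in flat:
        idx = np.unravel_index(int(f), shape)
        out.append(
            BeamParameters.from_array([pool.values[k][idx[k]] for k in range(4)])
        )
    return out


def _setdiff(values: Iterable[float], excluded: Iterable[float]) -> np.ndarray:
    vals = np.asarray(list(values), dtype=float)
    keep = np.ones(vals.size, dtype=bool)
    for e in excluded:
        keep &= np.abs(vals - e) > NODE_ATOL
    return vals[keep]


#: Training-grid axes of the study design: 5 energies x 3 spectrum widths
#: x 5 spot sizes x 4 divergences = 300 tuples.
DEFAULT_TRAINING_AXES: tuple[tuple[float, ...], ...] = (
    (5.6, 5.8, 6.0, 6.2, 6.4),
    (0.0, 0.5, 1.0),
    (0.0, 0.1, 0.2, 0.3, 0.4),
    (0.0, 1.0, 2.0, 3.0),
)


def DEFAULT_TEST_POOL(n_samples: int = 25, seed: int = 0) -> TestPool:
    """Candidate sets for test-tuple sampling, excluding training-axis values.

    E: 5.65 + 0.05 i (i = 0..14) minus {5.8, 6.0, 6.2}; sigma_E: 0.1 + 0.1 i
    (i = 0..8) minus {0.5}; s: 0.05 + 0.1 i (i = 0..3); alpha: 0.5 + 0.25 i
    (i = 0..9) minus {1, 2}.  Every draw therefore misses the grid in E,
    sigma_E, s and alpha simultaneously.
    """
    e_vals = _setdiff((5.65 + 0.05 * i for i in range(15)), (5.8, 6.0, 6.2))
    sig_vals = _setdiff((0.1 + 0.1 * i for i in range(9)), (0.5,))
    s_vals = np.array([0.05 + 0.1 * i for i in range(4)])
    a_vals = _setdiff((0.5 + 0.25 * i for i in range(10)), (1.0, 2.0))
    return TestPool(values=(e_vals, sig_vals, s_vals, a_vals), n_samples=n_samples, seed=seed)
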