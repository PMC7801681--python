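"""Distance-distribution descriptors of confined object patterns.

Six cumulative distance distribution functions characterize a pattern of N
object centroids ``p_1..p_N`` in a domain D:

* ``F`` — empty-space function: distance from an arbitrary position ``q ∈ D``
  to the nearest object centroid;
* ``G`` — nearest-neighbour function: per-object distance to its nearest
  neighbouring centroid;
* ``H`` — pair-distance function: all N(N−1)/2 inter-centroid distances;
* ``B`` — per-object distance to the closest point on the domain boundary;
* ``C`` — per-object distance to the domain centroid;
* ``Z`` — per-object distance to its farthest neighbour.

Each estimate is an empirical CDF built from the strict-inequality indicator
``1{d < x}``: the function is 0 at a jump abscissa and rises immediately to
the right of it.  F is estimated over a set of evaluation positions — voxel
centers for image-derived patterns, or a fixed-seed uniform sample for
analytic domains — shared between an observed pattern and all its model
simulations so that position sampling contributes no extra variance.

No edge-corrected estimators are used: edge effects are handled by
conditional simulation (same domain, object count and sizes in the null
models), not by correcting the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import Sdi3dError
from .geometry import Domain, VoxelMaskDomain
from .patterns import ObjectPattern

__all__ = [
    "EmpiricalCDF",
    "EvalPositions",
    "uniform_positions",
    "voxel_positions",
    "estimate_F",
    "estimate_pairwise",
    "estimate_boundary",
    "estimate_descriptor",
    "descriptor_distances",
    "evaluate_cdf",
    "summary_distances",
    "DESCRIPTORS",
]

DESCRIPTORS = ("F", "G", "H", "B", "C", "Z")


@dataclass
class EmpiricalCDF:
    """Empirical CDF with the strict-inequality convention ``P(d < x)``.

    ``values`` are the sorted jump abscissae with ``weights`` summing to 1;
    evaluation at a jump point returns the value *before* the jump.
    """

    descriptor: str
    values: np.ndarray
    weights: np.ndarray
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        order = np.argsort(self.values, kind="stable")
        self.values = self.values[order]
        self.weights = self.weights[order]
        if len(self.weights) and not np.isclose(self.weights.sum(), 1.0):
            raise Sdi3dError("ECDF weights must sum to 1")
        self._cum = np.concatenate([[0.0], np.cumsum(self.weights)])
        if len(self._cum):
            self._cum[-1] = 1.0 if len(self.weights) else 0.0

    @classmethod
    def from_distances(cls, descriptor: str, distances) -> "EmpiricalCDF":
        d = np.asarray(distances, dtype=float).ravel()
        if d.size == 0:
            raise Sdi3dError(f"no distances to build {descriptor} from")
        return cls(descriptor, d, np.full(d.size, 1.0 / d.size))

    def evaluate(self, x):
        """``P(d < x)`` — strict inequality, 0 at a jump abscissa."""
        idx = np.searchsorted(self.values, np.asarray(x, dtype=float), side="left")
        out = self._cum[idx]
        return float(out) if np.isscalar(x) else out

    def evaluate_right(self, x):
        """``P(d ≤ x)`` — the value immediately right of x; this is the
        constant value of the step function on the interval above x, which is
        what sup-deviation computations over a jump grid need."""
        idx = np.searchsorted(self.values, np.asarray(x, dtype=float), side="right")
        out = self._cum[idx]
        return float(out) if np.isscalar(x) else out

    def __call__(self, x):
        return self.evaluate(x)

    def mean(self) -> float:
        """Mean of the underlying distance sample."""
        return float(np.sum(self.values * self.weights))


@dataclass
class EvalPositions:
    """Positions at which the empty-space function F is evaluated."""

    points: np.ndarray  # (L, 3)
    provenance: str  # voxel_centers | uniform_grid | random_uniform
    seed: int | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise Sdi3dError("positions must be an (L, 3) array")
        if len(self.points) < 100:
            raise Sdi3dError("need at least 100 evaluation positions")

    @property
    def count(self) -> int:
        return len(self.points)


def uniform_positions(domain: Domain, L: int = 10_000,
                      rng: np.random.Generator | int | None = None) -> EvalPositions:
    """L uniform random positions inside the domain (fixed-seed reproducible)."""
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = 0 if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    return EvalPositions(domain.sample_uniform(rng, L), "random_uniform", seed)


def voxel_positions(domain: VoxelMaskDomain) -> EvalPositions:
    """All foreground voxel centers of a mask domain (the dense choice for
    image-derived patterns)."""
    return EvalPositions(domain.voxel_centers(), "voxel_centers")


# ---------------------------------------------------------------------------
# Distance sets underlying each descriptor
# ---------------------------------------------------------------------------

def _nn_far_pair(centroids: np.ndarray):
    d = squareform(pdist(centroids))
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    np.fill_diagonal(d, -np.inf)
    far = d.max(axis=1)
    return nn, pdist(centroids), far


def descriptor_distances(pattern: ObjectPattern, descriptor: str,
                         positions: EvalPositions | None = None) -> np.ndarray:
    """The raw distance sample behind one descriptor of one pattern."""
    n = pattern.n_objects
    if descriptor == "F":
        if n < 1:
            raise Sdi3dError("F is undefined for an empty pattern")
        if positions is None:
            raise Sdi3dError("F requires evaluation positions")
        return cdist(positions.points, pattern.centroids).min(axis=1)
    if descriptor in ("G", "H", "Z"):
        if n < 2:
            raise Sdi3dError(f"{descriptor} requires at least 2 objects")
        nn, pair, far = _nn_far_pair(pattern.centroids)
        return {"G": nn, "H": pair, "Z": far}[descriptor]
    if descriptor == "B":
        if n < 1:
            raise Sdi3dError("B is undefined for an empty pattern")
        return pattern.domain.boundary_distances(pattern.centroids)
    if descriptor == "C":
        if n < 1:
            raise Sdi3dError("C is undefined for an empty pattern")
        return np.linalg.norm(pattern.centroids - pattern.domain.centroid(), axis=1)
    raise Sdi3dError(f"unknown descriptor {descriptor!r}")


def estimate_F(pattern: ObjectPattern, positions: EvalPositions) -> EmpiricalCDF:
    """Empty-space function: ECDF of position-to-nearest-centroid distances."""
    return EmpiricalCDF.from_distances("F", descriptor_distances(pattern, "F", positions))


def estimate_pairwise(pattern: ObjectPattern):
    """Nearest-neighbour G, all-pairs H and farthest-neighbour Z estimates.

    G and Z weight each object 1/N; H weights each unordered pair
    2/(N(N−1)).
    """
    if pattern.n_objects < 2:
        raise Sdi3dError("pairwise descriptors require at least 2 objects")
    nn, pair, far = _nn_far_pair(pattern.centroids)
    return (EmpiricalCDF.from_distances("G", nn),
            EmpiricalCDF.from_distances("H", pair),
            EmpiricalCDF.from_distances("Z", far))


def estimate_boundary(pattern: ObjectPattern):
    """Boundary-distance B and domain-centroid-distance C estimates."""
    return (EmpiricalCDF.from_distances("B", descriptor_distances(pattern, "B")),
            EmpiricalCDF.from_distances("C", descriptor_distances(pattern, "C")))


def estimate_descriptor(pattern: ObjectPattern, descriptor: str,
                        positions: EvalPositions | None = None) -> EmpiricalCDF:
    """Any one of the six descriptors by id."""
    return EmpiricalCDF.from_distances(
        descriptor, descriptor_distances(pattern, descriptor, positions))


def evaluate_cdf(f: EmpiricalCDF, x) -> float:
    """Evaluate an empirical CDF at x under the strict-``<`` convention."""
    return f.evaluate(x)


@dataclass
class SummaryDistances:
    """Mean nearest-neighbour, pair and farthest-neighbour distances."""

    nearest: float
    pair: float
    farthest: float


def summary_distances(pattern: ObjectPattern) -> SummaryDistances:
    """Means of the distance sets behind G, H and Z."""
    if pattern.n_objects < 2:
        raise Sdi3dError("summary distances require at least 2 objects")
    nn, pair, far = _nn_far_pair(pattern.centroids)
    return SummaryDistances(float(nn.mean()), float(pair.mean()), float(far.mean()))
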