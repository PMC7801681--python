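"""Monte-Carlo goodness-of-fit machinery: model functions, SDI, population tests.

The workflow, per observed pattern and model:

1. condition the model on the pattern — same domain, object count, radii and
   (for orbital variants) per-object boundary distances;
2. simulate a first set of ``n_sim1`` patterns and average the descriptor of
   interest into a model function, with a pointwise 95% envelope;
3. measure ``S = mean(x*) − obs(x*)``, the maximal signed vertical deviation
   between the first-set mean and the observed descriptor (``x*`` is the
   abscissa of maximal absolute deviation; the sign is oriented so that
   ``S > 0`` when the observed curve sits below the model mean, i.e. when the
   observed distances are larger than the model predicts);
4. simulate a second, independent set of ``n_sim2`` patterns, give each its
   own ``S`` against the same first-set mean, and report the Spatial
   Distribution Index: the fraction of second-set ``S`` values strictly below
   the observed one.

With this orientation an SDI near 1 flags observed distances larger than the
model's (e.g. the nearest-neighbour function shifted right under repulsion)
and an SDI near 0 flags smaller ones (e.g. the boundary-distance function
shifted left under attraction to the border).

Under a model that fits, the observed pattern is exchangeable with the
second-set simulations, so the SDI is uniform over a population of patterns;
uniformity is assessed with the two-sided Kolmogorov-Smirnov test.  Because
descriptors are step functions, the sup deviation is attained immediately to
the right of a jump: all curves are compared on the union of their jump
abscissae using right-limits, which makes the sup exact (no discretization
grid).  SDI values are discrete (multiples of ``1/n_sim2``); ties between a
simulated and the observed ``S`` count as not-below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .descriptors import EvalPositions, descriptor_distances, uniform_positions
from .errors import Sdi3dError
from .models import ModelSpec, simulate
from .patterns import ObjectPattern

__all__ = [
    "ModelFunctionEstimate",
    "SDIResult",
    "PopulationTest",
    "estimate_model_function",
    "compute_sdi",
    "compute_sdi_multi",
    "test_uniformity",
    "compare_mean_distances",
]


@dataclass
class ModelFunctionEstimate:
    """Simulation-averaged descriptor with a pointwise 95% envelope.

    ``grid`` holds the union of jump abscissae; ``mean``, ``lower`` and
    ``upper`` are right-limits on the grid (the constant value of each step
    function immediately above the abscissa).  The envelope uses pointwise
    order statistics (3rd smallest / 3rd largest of 99 ≈ the 2.5th / 97.5th
    percentiles) and is diagnostic; inference goes through the SDI.
    """

    descriptor: str
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_sim: int
    spec: ModelSpec


@dataclass
class SDIResult:
    """Per-pattern SDI for one descriptor under one model."""

    descriptor: str
    S: float
    x_star: float
    sdi: float
    n_sim1: int
    n_sim2: int
    seed: int | None = None


@dataclass
class PopulationTest:
    """KS uniformity verdict over a population of per-pattern SDIs."""

    descriptor: str
    model: str
    sdis: np.ndarray
    statistic: float
    p_value: float

    @property
    def n(self) -> int:
        return len(self.sdis)


def _merged_grid(values: np.ndarray, rel: float = 1e-9) -> np.ndarray:
    """Sorted unique jump abscissae with float-jitter clusters collapsed.

    Distances that agree to a relative 1e-9 (e.g. orbit distances
    reconstructed through unit-vector round-trips) are represented by the
    cluster maximum, so identical-by-construction jump sets evaluate
    identically instead of producing spurious micro-deviations.
    """
    grid = np.unique(values)
    if len(grid) < 2:
        return grid
    scale = max(abs(grid[-1]), 1e-300)
    keep = np.concatenate([np.diff(grid) > rel * scale, [True]])
    return grid[keep]


def _right_curves(jump_sets: list[np.ndarray], grid: np.ndarray) -> np.ndarray:
    """Right-limit values of each jump-set ECDF on the grid: P(d <= x)."""
    out = np.empty((len(jump_sets), len(grid)))
    for k, jumps in enumerate(jump_sets):
        s = np.sort(jumps)
        out[k] = np.searchsorted(s, grid, side="right") / len(s)
    return out


def _signed_max_dev(curve: np.ndarray, mean: np.ndarray, grid: np.ndarray):
    """Maximal signed deviation, oriented model-mean minus observed curve.

    Both inputs are right-limits on the common jump grid, where the sup of a
    difference of step functions is attained; ties in |deviation| break
    toward the smallest abscissa (first occurrence).
    """
    diff = mean - curve
    k = int(np.argmax(np.abs(diff)))
    return float(diff[k]), float(grid[k])


def _conditioned_sims(pattern: ObjectPattern, spec: ModelSpec, n_sim: int,
                      rng: np.random.Generator) -> list[ObjectPattern]:
    cspec = spec.conditioned_on(pattern)
    return [simulate(pattern.domain, cspec, rng) for _ in range(n_sim)]


def _needs_positions(descriptors) -> bool:
    return "F" in descriptors


def _default_positions(pattern, positions, rng, L: int = 10_000):
    if positions is not None:
        return positions
    seed = int(rng.integers(2**31))
    return uniform_positions(pattern.domain, L, seed)


def estimate_model_function(pattern: ObjectPattern, spec: ModelSpec,
                            descriptor: str, n_sim: int = 99,
                            positions: EvalPositions | None = None,
                            rng: np.random.Generator | int | None = None
                            ) -> ModelFunctionEstimate:
    """Average a descriptor over ``n_sim`` conditioned simulations.

    The evaluation grid is the union of the jump abscissae of the observed
    pattern and of every simulation; the envelope is the pointwise
    2.5–97.5 percentile band (order statistics).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if _needs_positions([descriptor]):
        positions = _default_positions(pattern, positions, rng)
    sims = _conditioned_sims(pattern, spec, n_sim, rng)
    obs_jumps = descriptor_distances(pattern, descriptor, positions)
    sim_jumps = [descriptor_distances(s, descriptor, positions) for s in sims]
    grid = _merged_grid(np.concatenate([obs_jumps, *sim_jumps]))
    curves = _right_curves(sim_jumps, grid)
    k_lo = int(np.floor(0.025 * n_sim))
    srt = np.sort(curves, axis=0)
    mean = curves.mean(axis=0)
    # order statistics can cross the mean on near-degenerate 0/1 curves
    # (e.g. single-object descriptors); clip so lower <= mean <= upper holds
    return ModelFunctionEstimate(
        descriptor=descriptor, grid=grid, mean=mean,
        lower=np.minimum(srt[k_lo], mean),
        upper=np.maximum(srt[n_sim - 1 - k_lo], mean), n_sim=n_sim, spec=spec)


def compute_sdi_multi(pattern: ObjectPattern, spec: ModelSpec, descriptors,
                      n_sim1: int = 99, n_sim2: int = 99,
                      positions: EvalPositions | None = None,
                      rng: np.random.Generator | int | None = None
                      ) -> dict[str, SDIResult]:
    """SDI for several descriptors at once, sharing the two simulation sets.

    The two sets of conditioned simulations are by far the dominant cost;
    every descriptor is then measured on the same simulations, exactly as a
    single-descriptor run would do.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    descriptors = list(descriptors)
    if _needs_positions(descriptors):
        positions = _default_positions(pattern, positions, rng)
    sims1 = _conditioned_sims(pattern, spec, n_sim1, rng)
    sims2 = _conditioned_sims(pattern, spec, n_sim2, rng)
    out = {}
    for desc in descriptors:
        obs = descriptor_distances(pattern, desc, positions)
        j1 = [descriptor_distances(s, desc, positions) for s in sims1]
        j2 = [descriptor_distances(s, desc, positions) for s in sims2]
        grid = _merged_grid(np.concatenate([obs, *j1, *j2]))
        mean1 = _right_curves(j1, grid).mean(axis=0)
        obs_curve = _right_curves([obs], grid)[0]
        S_obs, x_star = _signed_max_dev(obs_curve, mean1, grid)
        curves2 = _right_curves(j2, grid)
        S_sims = mean1 - curves2
        # per-simulation x*: each second-set simulation treated like an observation
        S2 = S_sims[np.arange(n_sim2), np.argmax(np.abs(S_sims), axis=1)]
        sdi = float(np.count_nonzero(S2 < S_obs)) / n_sim2
        out[desc] = SDIResult(desc, S_obs, x_star, sdi, n_sim1, n_sim2)
    return out


def compute_sdi(pattern: ObjectPattern, spec: ModelSpec, descriptor: str,
                n_sim1: int = 99, n_sim2: int = 99,
                positions: EvalPositions | None = None,
                rng: np.random.Generator | int | None = None) -> SDIResult:
    """SDI of one pattern for one descriptor under one conditioned model."""
    return compute_sdi_multi(pattern, spec, [descriptor], n_sim1, n_sim2,
                             positions, rng)[descriptor]


def test_uniformity(sdis, descriptor: str = "", model: str = "") -> PopulationTest:
    """Two-sided Kolmogorov-Smirnov test of SDI uniformity on [0, 1].

    Applied to the discrete SDI values as they are (no continuity
    correction), with the asymptotic p-value.
    """
    sdis = np.asarray(sdis, dtype=float)
    if len(sdis) < 10:
        raise Sdi3dError(f"need at least 10 SDI values, got {len(sdis)}")
    if np.any((sdis < 0) | (sdis > 1)):
        raise Sdi3dError("SDI values must lie in [0, 1]")
    res = stats.kstest(sdis, stats.uniform.cdf, method="asymp")
    return PopulationTest(descriptor, model, sdis,
                          float(res.statistic), float(res.pvalue))


@dataclass
class MatchedDistanceTest:
    """Wilcoxon matched-pairs comparison of observed vs model-mean distances."""

    which: str
    observed: np.ndarray
    predicted: np.ndarray
    statistic: float
    p_value: float


def compare_mean_distances(observed_patterns, spec: ModelSpec, which: str,
                           n_sim_per_pattern: int = 19,
                           rng: np.random.Generator | int | None = None
                           ) -> MatchedDistanceTest:
    """Pair each pattern's mean distance with its conditioned-model prediction.

    ``which`` selects the distance set: ``nearest`` (per-object nearest
    neighbour), ``pair`` (all pairs) or ``farthest``.  The paired
    observed/predicted means are compared with the two-sided Wilcoxon
    signed-rank test.
    """
    from .descriptors import summary_distances

    if which not in ("nearest", "pair", "farthest"):
        raise Sdi3dError("which must be nearest|pair|farthest")
    patterns = list(observed_patterns)
    if len(patterns) < 6:
        raise Sdi3dError("need at least 6 patterns for a matched-pairs test")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    obs, pred = [], []
    for pat in patterns:
        obs.append(getattr(summary_distances(pat), which))
        sims = _conditioned_sims(pat, spec, n_sim_per_pattern, rng)
        pred.append(float(np.mean([getattr(summary_distances(s), which)
                                   for s in sims])))
    obs = np.asarray(obs)
    pred = np.asarray(pred)
    diffs = obs - pred
    if np.allclose(diffs, 0.0):
        return MatchedDistanceTest(which, obs, pred, 0.0, 1.0)
    res = stats.wilcoxon(obs, pred)
    return MatchedDistanceTest(which, obs, pred, float(res.statistic),
                               float(res.pvalue))
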