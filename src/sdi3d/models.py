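"""Simulators for spatial models of hard spheres in confined domains.

All models are conditioned on the domain shape, the number of objects and the
per-object radii; objects never overlap each other or the boundary:

* ``csr`` — completely random: sequential insertion of uniform candidate
  positions, each placement uniform conditional on no overlap;
* ``border_attraction`` / ``border_repulsion`` — as csr, with candidates
  additionally accepted by a Gaussian-tail rule on their distance ``d`` to
  the boundary: attraction accepts ``d ≤ μ`` outright and otherwise with
  probability ``exp(−((d−μ)/σ)²/2)``; repulsion is symmetric;
* ``orbital`` — each object is uniform on its orbit, the iso-surface of a
  fixed distance to the boundary, given per-object;
* ``max_repulsion`` / ``orbital_max_repulsion`` — Metropolis minimization of
  the energy ``E = −(1/N) Σ_i min_{j≠i} ‖p_i − p_j‖`` (mean nearest-neighbour
  distance, negated), started from a csr (resp. orbital) configuration; the
  orbital variant keeps every centroid-to-boundary distance fixed.

Sequential insertion can dead-end; two restart mechanisms deal with it:
after ``restart_threshold`` failed attempts for one object the configuration
is cleared and the insertion order re-randomized, and after ``max_restarts``
such restarts a :class:`~sdi3d.errors.PackingError` is raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyOrbitError, PackingError, Sdi3dError
from .geometry import Domain, SphereDomain
from .patterns import ObjectPattern

__all__ = [
    "MODELS",
    "ModelSpec",
    "EnergyTrace",
    "simulate",
    "simulate_csr",
    "simulate_border_biased",
    "simulate_orbital",
    "simulate_max_repulsion",
    "simulate_orbital_max_repulsion",
    "pattern_energy",
    "maximize_repulsion",
]

MODELS = ("csr", "orbital", "max_repulsion", "orbital_max_repulsion",
          "border_attraction", "border_repulsion")


@dataclass
class ModelSpec:
    """Full parameterization of one spatial model.

    ``radii`` and (for orbital variants) ``orbit_distances`` are per-object,
    in physical units.  Annealing parameters apply to the maximal-repulsion
    variants only; ``delta`` (proposal step) defaults to the mean object
    radius and ``beta0`` is auto-calibrated so that initial uphill acceptance
    is about one half.
    """

    model: str
    radii: np.ndarray = field(default_factory=lambda: np.array([]))
    orbit_distances: np.ndarray | None = None
    mu: float | None = None
    sigma: float | None = None
    beta_growth: float = 1.05
    delta: float | None = None
    conv_tol: float = 1e-4
    window_sweeps: int = 50
    max_sweeps: int = 2000
    orbit_tolerance: float | None = None
    restart_threshold: int = 1000
    max_restarts: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise Sdi3dError(f"unknown model {self.model!r}; expected one of {MODELS}")
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if np.any(self.radii <= 0):
            raise Sdi3dError("all radii must be positive")
        if self.orbit_distances is not None:
            self.orbit_distances = np.atleast_1d(
                np.asarray(self.orbit_distances, dtype=float))
            if len(self.orbit_distances) != len(self.radii):
                raise Sdi3dError("orbit_distances and radii lengths differ")
            if np.any(self.orbit_distances < self.radii - 1e-9):
                raise Sdi3dError("orbit distances must be >= object radii")
        if self.model.startswith("border"):
            if self.mu is None or self.sigma is None or self.mu <= 0 or self.sigma <= 0:
                raise Sdi3dError("border-biased models need positive mu and sigma")
        if self.model.startswith("orbital") and self.orbit_distances is None:
            raise Sdi3dError(f"{self.model} needs orbit_distances")

    def conditioned_on(self, pattern: ObjectPattern) -> "ModelSpec":
        """Copy of the spec with radii (and orbit distances, when relevant)
        measured from a pattern — the conditioning used by the SDI test."""
        orbits = self.orbit_distances
        if self.model.startswith("orbital"):
            orbits = pattern.domain.boundary_distances(pattern.centroids)
        return replace(self, radii=pattern.radii.copy(), orbit_distances=orbits)

    def effective_orbit_tolerance(self) -> float:
        if self.orbit_tolerance is not None:
            return self.orbit_tolerance
        return 0.01 * float(np.mean(self.radii)) if len(self.radii) else 0.0


@dataclass
class EnergyTrace:
    """Energy trajectory of one Metropolis run, recorded per adaptation window."""

    moves: np.ndarray          # cumulative proposed moves at each window end
    energies: np.ndarray       # current energy at each window end
    best_energies: np.ndarray  # best-visited energy at each window end
    accepted_fraction: float
    converged: bool
    n_moves: int
    beta0: float

    @property
    def best_energy(self) -> float:
        return float(self.best_energies[-1]) if len(self.best_energies) else np.nan


def _feasibility_check(domain: Domain, radii: np.ndarray):
    inr = domain.inradius()
    if np.any(radii >= inr):
        raise PackingError(
            f"object radius {radii.max():.6g} does not fit the domain "
            f"(inradius {inr:.6g})")


def _insert_sequential(domain: Domain, radii: np.ndarray,
                       rng: np.random.Generator, sampler, extra_accept,
                       restart_threshold: int, max_restarts: int,
                       skip_containment: bool = False) -> np.ndarray:
    """Shared sequential-insertion engine for csr/border/orbital models.

    ``sampler(i, m)`` draws m candidate positions for object index i;
    ``extra_accept(i, pts)`` returns a boolean keep-mask (or None for always).
    """
    n = len(radii)
    if n == 0:
        return np.empty((0, 3))
    batch = 64
    for _restart in range(max_restarts + 1):
        order = rng.permutation(n)
        placed = np.empty((n, 3))
        placed_r = np.empty(n)
        n_placed = 0
        dead_end = False
        for i in order:
            attempts = 0
            success = False
            while attempts < restart_threshold:
                cand = sampler(i, batch)
                keep = np.ones(len(cand), dtype=bool)
                if not skip_containment:
                    inside = domain.contains_points(cand)
                    keep &= inside
                    if inside.any():
                        bd = np.full(len(cand), -np.inf)
                        bd[inside] = domain.boundary_distances(cand[inside])
                        keep &= bd >= radii[i] - 1e-12
                if extra_accept is not None:
                    keep &= extra_accept(i, cand, rng)
                if n_placed and keep.any():
                    from scipy.spatial.distance import cdist

                    dmin_ok = np.all(
                        cdist(cand, placed[:n_placed])
                        >= (radii[i] + placed_r[:n_placed])[None, :] - 1e-12,
                        axis=1)
                    keep &= dmin_ok
                hits = np.flatnonzero(keep)
                if hits.size:
                    attempts += hits[0]  # candidates burned before the accepted one
                    placed[n_placed] = cand[hits[0]]
                    placed_r[n_placed] = radii[i]
                    n_placed += 1
                    success = True
                    break
                attempts += len(cand)
            if not success:
                dead_end = True
                break
        if not dead_end:
            return placed[np.argsort(order)]  # restore input object order
    raise PackingError(
        f"failed to place {n} objects after {max_restarts} restarts "
        f"({restart_threshold} attempts each); packing may be infeasible")


def _pattern(domain, positions, radii, metadata) -> ObjectPattern:
    return ObjectPattern.from_arrays(domain, positions, radii, metadata=metadata)


def simulate_csr(domain: Domain, radii, rng: np.random.Generator,
                 restart_threshold: int = 1000, max_restarts: int = 100) -> ObjectPattern:
    """Completely random hard-sphere pattern conditioned on domain and radii."""
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    _feasibility_check(domain, radii)
    pos = _insert_sequential(
        domain, radii, rng,
        sampler=lambda i, m: domain.sample_uniform(rng, m),
        extra_accept=None,
        restart_threshold=restart_threshold, max_restarts=max_restarts)
    return _pattern(domain, pos, radii, {"model": "csr"})


def simulate_border_biased(domain: Domain, radii, mode: str, mu: float,
                           sigma: float, rng: np.random.Generator,
                           restart_threshold: int = 1000,
                           max_restarts: int = 100) -> ObjectPattern:
    """Hard-sphere pattern with attraction to / repulsion from the boundary.

    Attraction accepts a candidate at boundary distance ``d`` with
    probability 1 when ``d ≤ μ`` and ``exp(−((d−μ)/σ)²/2)`` otherwise;
    repulsion is the mirror image.
    """
    if mode not in ("attraction", "repulsion"):
        raise Sdi3dError("mode must be 'attraction' or 'repulsion'")
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    _feasibility_check(domain, radii)

    def accept(i, cand, rng_):
        inside = domain.contains_points(cand)
        keep = np.zeros(len(cand), dtype=bool)
        if not inside.any():
            return keep
        d = domain.boundary_distances(cand[inside])
        p = np.exp(-0.5 * ((d - mu) / sigma) ** 2)
        if mode == "attraction":
            p = np.where(d <= mu, 1.0, p)
        else:
            p = np.where(d >= mu, 1.0, p)
        keep[inside] = rng_.random(len(d)) < p
        return keep

    pos = _insert_sequential(
        domain, radii, rng,
        sampler=lambda i, m: domain.sample_uniform(rng, m),
        extra_accept=accept,
        restart_threshold=restart_threshold, max_restarts=max_restarts)
    return _pattern(domain, pos, radii,
                    {"model": f"border_{mode}", "mu": mu, "sigma": sigma})


def simulate_orbital(domain: Domain, radii, orbit_distances,
                     rng: np.random.Generator, orbit_tolerance: float | None = None,
                     restart_threshold: int = 1000,
                     max_restarts: int = 100) -> ObjectPattern:
    """Each object uniform on its orbit — the iso-surface of a fixed distance
    to the boundary — without overlaps.

    Sphere domains use exact shell sampling; other domains use rejection
    sampling onto the iso-surface within ``orbit_tolerance`` (default 1% of
    the mean radius).
    """
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    orbits = np.atleast_1d(np.asarray(orbit_distances, dtype=float))
    if len(orbits) != len(radii):
        raise Sdi3dError("orbit_distances and radii lengths differ")
    if np.any(orbits < radii - 1e-9):
        raise Sdi3dError("orbit distances must be >= object radii (containment)")
    inr = domain.inradius()
    if np.any(orbits > inr + 1e-9):
        raise EmptyOrbitError(
            f"orbit distance {orbits.max():.6g} exceeds the domain inradius "
            f"{inr:.6g}: empty orbit")
    tol = orbit_tolerance if orbit_tolerance is not None else 0.01 * float(radii.mean())

    if isinstance(domain, SphereDomain):
        center, R = domain.center, domain.radius

        def sampler(i, m):
            u = rng.standard_normal((m, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            return center + (R - orbits[i]) * u

        skip_containment = True
    else:
        def sampler(i, m):
            target = orbits[i]
            for _ in range(200):
                cand = domain.sample_uniform(rng, 256)
                bd = domain.boundary_distances(cand)
                hit = cand[np.abs(bd - target) <= tol]
                if len(hit):
                    return hit[:m]
            raise EmptyOrbitError(
                f"rejection sampling found no point within {tol:.3g} of the "
                f"iso-surface at distance {target:.6g}; orbit may be empty "
                f"or the tolerance too tight")

        skip_containment = False

    pos = _insert_sequential(
        domain, radii, rng, sampler=sampler, extra_accept=None,
        restart_threshold=restart_threshold, max_restarts=max_restarts,
        skip_containment=skip_containment)
    return _pattern(domain, pos, radii,
                    {"model": "orbital", "orbit_distances": orbits.tolist()})


def pattern_energy(pattern: ObjectPattern) -> float:
    """Repulsion energy: minus the mean nearest-neighbour distance."""
    if pattern.n_objects < 2:
        raise Sdi3dError("energy requires at least 2 objects")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(pattern.centroids))
    np.fill_diagonal(d, np.inf)
    return float(-d.min(axis=1).mean())


def maximize_repulsion(initial: ObjectPattern, on_orbits: bool = False,
                       rng: np.random.Generator | None = None,
                       spec: ModelSpec | None = None) -> tuple[ObjectPattern, EnergyTrace]:
    """Metropolis minimization of the repulsion energy from an initial pattern.

    Returns the best-energy configuration visited (never worse than the
    initial one) and the energy trace.  With ``on_orbits=True`` every
    centroid keeps its initial distance to the boundary.  Non-convergence
    within the move budget is reported in the trace, not raised.
    """
    if initial.n_objects < 2:
        raise Sdi3dError("maximal repulsion requires at least 2 objects")
    rng = np.random.default_rng() if rng is None else rng
    spec = spec or ModelSpec("max_repulsion", radii=initial.radii)
    radii = initial.radii
    delta0 = spec.delta if spec.delta is not None else float(radii.mean())
    seed = int(rng.integers(2**31))

    if isinstance(initial.domain, SphereDomain):
        from ._anneal import anneal_in_ball

        dom = initial.domain
        rel = initial.centroids - dom.center
        rho = np.linalg.norm(rel, axis=1) if on_orbits else np.zeros(len(radii))
        best, w_m, w_E, w_b, acc, conv, n_moves, beta0 = anneal_in_ball(
            np.ascontiguousarray(rel), np.ascontiguousarray(radii),
            dom.radius, np.ascontiguousarray(rho), on_orbits,
            spec.beta_growth, delta0, spec.conv_tol,
            spec.window_sweeps, spec.max_sweeps, seed)
        pos = best + dom.center
    else:
        pos, w_m, w_E, w_b, acc, conv, n_moves, beta0 = _anneal_generic(
            initial.domain, initial.centroids.copy(), radii, on_orbits,
            spec, delta0, np.random.default_rng(seed))

    trace = EnergyTrace(np.asarray(w_m), np.asarray(w_E), np.asarray(w_b),
                        float(acc), bool(conv), int(n_moves), float(beta0))
    meta = dict(initial.metadata)
    meta["model"] = "orbital_max_repulsion" if on_orbits else "max_repulsion"
    out = _pattern(initial.domain, pos, radii, meta)
    if not conv:
        warnings.warn("annealing stopped at the move budget without meeting "
                      "the energy-stabilization tolerance")
    return out, trace


def _anneal_generic(domain, pos, radii, on_orbits, spec, delta0, rng):
    """Plain-Python annealer for mesh / voxel-mask / ellipsoid domains."""
    from scipy.spatial.distance import pdist, squareform

    n = len(radii)
    tol = spec.effective_orbit_tolerance()
    orbits = domain.boundary_distances(pos) if on_orbits else None
    D = squareform(pdist(pos))
    np.fill_diagonal(D, np.inf)

    def energy_of(Dm):
        return float(-Dm.min(axis=1).mean())

    E = energy_of(D)
    best_E, best_pos = E, pos.copy()
    delta = delta0

    def propose(i):
        while True:
            dx = rng.uniform(-delta, delta, 3)
            if np.dot(dx, dx) <= delta * delta:
                break
        cand = pos[i] + dx
        if on_orbits:
            # project back to the iso-distance surface along the boundary-
            # distance gradient (unit vector away from the closest boundary pt)
            for _ in range(8):
                if not domain.contains(cand):
                    return None
                d = float(domain.boundary_distances(cand[None, :])[0])
                if abs(d - orbits[i]) <= tol:
                    return cand
                bp = domain.closest_boundary_points(cand[None, :])[0]
                g = cand - bp
                gn = np.linalg.norm(g)
                if gn < 1e-12:
                    return None
                cand = cand + (orbits[i] - d) * g / gn
            return None
        if not domain.contains(cand):
            return None
        if float(domain.boundary_distances(cand[None, :])[0]) < radii[i] - 1e-12:
            return None
        return cand

    # beta0 calibration from 100 probe moves
    ups = []
    for _ in range(100):
        i = rng.integers(n)
        cand = propose(i)
        if cand is None:
            continue
        di = np.linalg.norm(pos - cand, axis=1)
        di[i] = np.inf
        if np.any(di < radii[i] + radii):
            continue
        D2 = D.copy()
        D2[i, :] = di
        D2[:, i] = di
        dE = energy_of(D2) - E
        if dE > 0:
            ups.append(dE)
    beta0 = np.log(2.0) / np.median(ups) if ups else 1.0
    beta = beta0

    window = spec.window_sweeps * n
    max_moves = spec.max_sweeps * n
    w_m, w_E, w_b = [], [], []
    moves = accepted = 0
    prev_best = best_E
    stable = 0
    converged = False
    while moves < max_moves and not converged:
        acc_w = 0
        for _ in range(window):
            moves += 1
            i = int(rng.integers(n))
            cand = propose(i)
            if cand is None:
                continue
            di = np.linalg.norm(pos - cand, axis=1)
            di[i] = np.inf
            if np.any(di < radii[i] + radii - 1e-12):
                continue
            D2 = D.copy()
            D2[i, :] = di
            D2[:, i] = di
            newE = energy_of(D2)
            dE = newE - E
            if dE < 0 or rng.random() < np.exp(-min(beta * dE, 50.0)):
                D = D2
                pos[i] = cand
                E = newE
                acc_w += 1
                if E < best_E:
                    best_E, best_pos = E, pos.copy()
        accepted += acc_w
        w_m.append(moves)
        w_E.append(E)
        w_b.append(best_E)
        beta *= spec.beta_growth ** spec.window_sweeps
        delta = delta / 0.9 if acc_w > 0.3 * window else delta * 0.9
        if abs(prev_best - best_E) / max(abs(best_E), 1e-300) < spec.conv_tol:
            stable += 1
            if stable >= 3:
                converged = True
        else:
            stable = 0
        prev_best = best_E
    return (best_pos, np.array(w_m), np.array(w_E), np.array(w_b),
            accepted / max(moves, 1), converged, moves, beta0)


def simulate_max_repulsion(domain, radii, rng, spec: ModelSpec | None = None):
    """Maximal-repulsion pattern: csr start, then annealing."""
    spec = spec or ModelSpec("max_repulsion", radii=radii)
    start = simulate_csr(domain, radii, rng, spec.restart_threshold, spec.max_restarts)
    return maximize_repulsion(start, on_orbits=False, rng=rng, spec=spec)


def simulate_orbital_max_repulsion(domain, radii, orbit_distances, rng,
                                   spec: ModelSpec | None = None):
    """Orbit-constrained maximal repulsion: orbital start, annealing on orbits."""
    spec = spec or ModelSpec("orbital_max_repulsion", radii=radii,
                             orbit_distances=orbit_distances)
    start = simulate_orbital(domain, radii, orbit_distances, rng,
                             spec.effective_orbit_tolerance(),
                             spec.restart_threshold, spec.max_restarts)
    return maximize_repulsion(start, on_orbits=True, rng=rng, spec=spec)


def simulate(domain: Domain, spec: ModelSpec, rng: np.random.Generator) -> ObjectPattern:
    """Dispatch a single simulation according to a :class:`ModelSpec`."""
    m = spec.model
    if m == "csr":
        return simulate_csr(domain, spec.radii, rng,
                            spec.restart_threshold, spec.max_restarts)
    if m in ("border_attraction", "border_repulsion"):
        return simulate_border_biased(domain, spec.radii, m.split("_")[1],
                                      spec.mu, spec.sigma, rng,
                                      spec.restart_threshold, spec.max_restarts)
    if m == "orbital":
        return simulate_orbital(domain, spec.radii, spec.orbit_distances, rng,
                                spec.orbit_tolerance,
                                spec.restart_threshold, spec.max_restarts)
    if m == "max_repulsion":
        return simulate_max_repulsion(domain, spec.radii, rng, spec)[0]
    if m == "orbital_max_repulsion":
        return simulate_orbital_max_repulsion(domain, spec.radii,
                                              spec.orbit_distances, rng, spec)[0]
    raise Sdi3dError(f"unknown model {m!r}")
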