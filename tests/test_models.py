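"""Spatial model simulators: csr, border-biased, orbital, maximal repulsion."""

import numpy as np
import pytest
from scipy import stats

from sdi3d import (
    EllipsoidDomain,
    EmptyOrbitError,
    ModelSpec,
    ObjectPattern,
    PackingError,
    Sdi3dError,
    SphereDomain,
    maximize_repulsion,
    pattern_energy,
    simulate,
    simulate_border_biased,
    simulate_csr,
    simulate_max_repulsion,
    simulate_orbital,
    simulate_orbital_max_repulsion,
    summary_distances,
    validate_pattern,
)


class TestCSR:
    def test_single_object_radial_law(self, rng):
        """One sphere of radius r in a ball R: center uniform in the eroded
        ball, so E||p|| = 3(R-r)/4."""
        R, r, n = 10.0, 2.0, 4000
        dom = SphereDomain(R)
        d = np.array([np.linalg.norm(simulate_csr(dom, [r], rng).centroids[0])
                      for _ in range(n)])
        a = R - r
        se = np.sqrt(3 * a**2 / 80 / n)
        assert abs(d.mean() - 3 * a / 4) < 3 * se
        assert d.max() <= a + 1e-9

    def test_infeasible_packing_raises(self, rng):
        # two unit spheres need centers >= 2 apart but both within 0.9 of center
        with pytest.raises(PackingError):
            simulate_csr(SphereDomain(1.9), [1.0, 1.0], rng,
                         restart_threshold=50, max_restarts=3)

    def test_radius_larger_than_domain_raises(self, rng):
        with pytest.raises(PackingError):
            simulate_csr(SphereDomain(3.0), [3.5], rng)

    def test_outputs_valid(self, sphere30, rng):
        for _ in range(20):
            pat = simulate_csr(sphere30, np.full(10, 5.0), rng)
            assert validate_pattern(pat).ok
            assert pat.n_objects == 10

    def test_radii_order_preserved(self, sphere30, rng):
        radii = np.array([1.0, 2.0, 3.0, 4.0])
        pat = simulate_csr(sphere30, radii, rng)
        np.testing.assert_array_equal(pat.radii, radii)


class TestBorderBiased:
    def test_attraction_moves_objects_outward(self, sphere30, rng):
        """Benchmark geometry: attraction (mu=5) reduces, repulsion
        (mu=15) increases mean boundary distance relative to csr."""
        radii = np.full(10, 5.0)
        n = 60

        def mean_bd(sim):
            return [sphere30.boundary_distances(sim().centroids).mean()
                    for _ in range(n)]

        csr = mean_bd(lambda: simulate_csr(sphere30, radii, rng))
        att = mean_bd(lambda: simulate_border_biased(
            sphere30, radii, "attraction", 5.0, 5.0, rng))
        rep = mean_bd(lambda: simulate_border_biased(
            sphere30, radii, "repulsion", 15.0, 5.0, rng))
        assert stats.mannwhitneyu(att, csr, alternative="less").pvalue < 1e-3
        assert stats.mannwhitneyu(rep, csr, alternative="greater").pvalue < 1e-3

    def test_mu_beyond_radius_reduces_to_csr(self, rng):
        """With mu >= R every candidate is on the favored side: the
        acceptance rule never fires and the distribution is csr."""
        dom = SphereDomain(10.0)
        radii = np.full(3, 1.0)
        att = np.concatenate([
            dom.boundary_distances(simulate_border_biased(
                dom, radii, "attraction", 10.0, 1.0, rng).centroids)
            for _ in range(150)])
        csr = np.concatenate([
            dom.boundary_distances(simulate_csr(dom, radii, rng).centroids)
            for _ in range(150)])
        assert stats.ks_2samp(att, csr).pvalue > 0.01

    def test_outputs_valid(self, sphere30, rng):
        pat = simulate_border_biased(sphere30, np.full(10, 5.0), "attraction",
                                     5.0, 5.0, rng)
        assert validate_pattern(pat).ok


class TestOrbital:
    def test_single_orbit_geometry(self, sphere10, rng):
        for _ in range(10):
            pat = simulate_orbital(sphere10, [1.0], [4.0], rng)
            assert np.linalg.norm(pat.centroids[0]) == pytest.approx(6.0)

    def test_direction_uniform(self, sphere10, rng):
        dirs = np.array([simulate_orbital(sphere10, [1.0], [4.0], rng).centroids[0]
                         for _ in range(4000)])
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        # mean unit direction ~ 0 by symmetry; se per axis = 1/sqrt(3n)
        assert np.all(np.abs(dirs.mean(axis=0)) < 3 / np.sqrt(3 * len(dirs)))

    def test_empty_orbit_raises(self, sphere10, rng):
        with pytest.raises(EmptyOrbitError):
            simulate_orbital(sphere10, [1.0], [10.5], rng)

    def test_orbit_below_radius_rejected(self, sphere10, rng):
        with pytest.raises(Sdi3dError):
            simulate_orbital(sphere10, [2.0], [1.0], rng)

    def test_conditioning_preserves_boundary_distances(self, sphere30, rng):
        base = simulate_csr(sphere30, np.full(8, 3.0), rng)
        orbits = sphere30.boundary_distances(base.centroids)
        sim = simulate_orbital(sphere30, base.radii, orbits, rng)
        got = np.sort(sphere30.boundary_distances(sim.centroids))
        np.testing.assert_allclose(got, np.sort(orbits), atol=1e-9)
        assert validate_pattern(sim).ok

    def test_rejection_sampling_on_mesh_like_domain(self, rng):
        """Non-sphere domains use iso-surface rejection sampling."""
        ell = EllipsoidDomain((8.0, 8.0, 8.0))  # sphere handled generically
        pat = simulate_orbital(ell, [1.0, 1.0], [3.0, 5.0], rng,
                               orbit_tolerance=0.05)
        bd = ell.boundary_distances(pat.centroids)
        np.testing.assert_allclose(np.sort(bd), [3.0, 5.0], atol=0.06)


class TestEnergy:
    def test_hand_examples(self):
        dom = SphereDomain(10.0)

        def pat(pts):
            return ObjectPattern.from_arrays(dom, pts, np.full(len(pts), 0.1))

        assert pattern_energy(pat([[0, 0, 0], [3, 0, 0]])) == pytest.approx(-3.0)
        assert pattern_energy(pat([[0, 0, 0], [1, 0, 0], [3, 0, 0]])) == \
            pytest.approx(-4 / 3)
        s = 2.0
        tri = [[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]]
        assert pattern_energy(pat(tri)) == pytest.approx(-s)
        with pytest.raises(Sdi3dError):
            pattern_energy(pat([[0, 0, 0]]))


class TestMaximalRepulsion:
    def test_two_sphere_optimum(self, sphere30, rng):
        """N=2 optimum is antipodal on the eroded ball: NN distance 2(R-r)."""
        for _ in range(10):
            _pat, trace = simulate_max_repulsion(sphere30, np.full(2, 5.0), rng)
            assert -trace.best_energy == pytest.approx(2 * 25.0, rel=0.02)

    def test_best_energy_monotone_and_below_initial(self, sphere30, rng):
        start = simulate_csr(sphere30, np.full(10, 5.0), rng)
        out, trace = maximize_repulsion(start, rng=rng)
        assert np.all(np.diff(trace.best_energies) <= 1e-12)
        assert trace.best_energy <= pattern_energy(start) + 1e-12
        assert pattern_energy(out) == pytest.approx(trace.best_energy)
        assert validate_pattern(out).ok

    def test_repulsion_beats_csr_nn_distance(self, sphere30, rng):
        radii = np.full(10, 5.0)
        nn_csr = [summary_distances(simulate_csr(sphere30, radii, rng)).nearest
                  for _ in range(30)]
        nn_max = [summary_distances(simulate_max_repulsion(
            sphere30, radii, rng)[0]).nearest for _ in range(30)]
        assert stats.mannwhitneyu(nn_max, nn_csr, alternative="greater").pvalue < 1e-3

    def test_orbit_constrained_keeps_orbits(self, sphere30, rng):
        radii = np.full(10, 5.0)
        base = simulate_csr(sphere30, radii, rng)
        orbits = sphere30.boundary_distances(base.centroids)
        spec = ModelSpec("orbital_max_repulsion", radii=radii,
                         orbit_distances=orbits)
        pat, trace = simulate_orbital_max_repulsion(sphere30, radii, orbits,
                                                    rng, spec)
        dev = np.abs(np.sort(sphere30.boundary_distances(pat.centroids))
                     - np.sort(orbits))
        assert dev.max() <= spec.effective_orbit_tolerance()
        assert validate_pattern(pat).ok

    def test_generic_annealer_matches_analytic_optimum(self, rng):
        """The plain-Python path (non-sphere domains) reaches the same N=2
        antipodal optimum, here on an ellipsoid with equal semi-axes."""
        ell = EllipsoidDomain((12.0, 12.0, 12.0))
        spec = ModelSpec("max_repulsion", radii=np.full(2, 2.0), max_sweeps=1500)
        start = simulate_csr(ell, spec.radii, rng)
        _pat, trace = maximize_repulsion(start, rng=rng, spec=spec)
        assert -trace.best_energy == pytest.approx(2 * 10.0, rel=0.05)


class TestDispatcherAndSpec:
    def test_all_models_dispatch_valid(self, sphere30, rng):
        radii = np.full(6, 4.0)
        orbits = np.full(6, 8.0)
        for model in ("csr", "border_attraction", "border_repulsion",
                      "orbital", "max_repulsion", "orbital_max_repulsion"):
            kw = {}
            if model.startswith("border"):
                kw = {"mu": 5.0, "sigma": 5.0}
            if model.startswith("orbital"):
                kw = {"orbit_distances": orbits}
            spec = ModelSpec(model, radii=radii, **kw)
            pat = simulate(sphere30, spec, rng)
            assert validate_pattern(pat).ok, model

    def test_spec_validation(self):
        with pytest.raises(Sdi3dError):
            ModelSpec("nope", radii=[1.0])
        with pytest.raises(Sdi3dError):
            ModelSpec("border_attraction", radii=[1.0])  # missing mu/sigma
        with pytest.raises(Sdi3dError):
            ModelSpec("orbital", radii=[1.0])  # missing orbits
        with pytest.raises(Sdi3dError):
            ModelSpec("orbital", radii=[2.0], orbit_distances=[1.0])

    def test_conditioning_copies_measurements(self, sphere30, rng):
        pat = simulate_csr(sphere30, np.array([3.0, 4.0, 5.0]), rng)
        spec = ModelSpec("orbital", radii=np.ones(1), orbit_distances=np.ones(1))
        cond = spec.conditioned_on(pat)
        np.testing.assert_array_equal(cond.radii, pat.radii)
        np.testing.assert_allclose(cond.orbit_distances,
                                   sphere30.boundary_distances(pat.centroids))
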