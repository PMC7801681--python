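"""Geometric queries: analytic domains, meshes, voxel masks, sampling."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sdi3d import (
    DomainError,
    EllipsoidDomain,
    MeshDomain,
    ObjectPattern,
    OutsideDomainError,
    SphereDomain,
    VoxelMaskDomain,
    mask_to_mesh,
    rasterize_pattern,
)
from sdi3d.geometry import domain_from_dict


def ball_mask(radius_vox, shape=None, center=None, spacing=(1, 1, 1)):
    shape = shape or (int(2 * radius_vox + 6),) * 3
    center = center if center is not None else np.array(shape) / 2.0
    idx = np.indices(shape)
    centers = np.stack(idx, axis=-1) + 0.5
    return np.sum(((centers - center) / np.asarray(spacing) * np.asarray(spacing)) ** 2,
                  axis=-1) <= radius_vox**2


class TestSphere:
    def test_boundary_distance(self, sphere10):
        assert sphere10.distance_to_boundary([0, 0, 4]) == pytest.approx(6.0)
        assert sphere10.distance_to_boundary([0, 0, 0]) == pytest.approx(10.0)
        with pytest.raises(OutsideDomainError):
            sphere10.distance_to_boundary([0, 0, 11])

    def test_closest_boundary_point(self, sphere10):
        np.testing.assert_allclose(sphere10.closest_boundary_point([0, 0, 4]),
                                   [0, 0, 10])
        # center: tie broken deterministically, at distance R
        q = sphere10.closest_boundary_point([0, 0, 0])
        assert np.linalg.norm(q) == pytest.approx(10.0)
        np.testing.assert_allclose(q, sphere10.closest_boundary_point([0.0, 0, 0]))

    def test_contains_sphere(self, sphere10):
        assert sphere10.contains_sphere([0, 0, 4], 6.0)  # touching allowed
        assert not sphere10.contains_sphere([0, 0, 4], 6.01)
        assert not sphere10.contains_sphere([0, 0, 20], 1.0)
        with pytest.raises(ValueError):
            sphere10.contains_sphere([0, 0, 0], -1.0)

    def test_centroid_offcenter(self):
        dom = SphereDomain(5.0, center=(1, 2, 3))
        np.testing.assert_allclose(dom.centroid(), [1, 2, 3])

    @given(st.lists(st.floats(-0.57, 0.57), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=50)
    def test_distance_identity(self, xyz):
        """distance_to_boundary + ||p - center|| == R exactly, any interior p."""
        dom = SphereDomain(1.0)
        p = np.array(xyz)
        assert dom.distance_to_boundary(p) + np.linalg.norm(p) == pytest.approx(
            1.0, abs=1e-12)

    def test_sampling_moments(self, rng):
        dom = SphereDomain(1.0)
        r = np.linalg.norm(dom.sample_uniform(rng, 100_000), axis=1)
        se_mean = np.sqrt(3 / 80 / len(r))  # Var(||p||) = 3R^2/80
        assert abs(r.mean() - 0.75) < 3 * se_mean
        frac = (r > 0.5).mean()
        se_frac = np.sqrt(7 / 8 * 1 / 8 / len(r))
        assert abs(frac - 7 / 8) < 3 * se_frac

    def test_sampling_radial_cdf(self, rng):
        """r^3 is uniform for a uniform point in the unit ball (chi-square)."""
        r = np.linalg.norm(SphereDomain(1.0).sample_uniform(rng, 10_000), axis=1)
        counts, _ = np.histogram(r**3, bins=20, range=(0, 1))
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_sampling_determinism(self):
        a = SphereDomain(2.0).sample_uniform(np.random.default_rng(5), 10)
        b = SphereDomain(2.0).sample_uniform(np.random.default_rng(5), 10)
        np.testing.assert_array_equal(a, b)


class TestEllipsoid:
    def test_reduces_to_sphere(self, rng):
        ell = EllipsoidDomain((7.0, 7.0, 7.0))
        pts = SphereDomain(6.5).sample_uniform(rng, 50)
        np.testing.assert_allclose(ell.boundary_distances(pts),
                                   7.0 - np.linalg.norm(pts, axis=1), atol=1e-8)

    def test_closest_point_consistency(self, rng):
        ell = EllipsoidDomain((10.0, 6.0, 4.0))
        pts = ell.sample_uniform(rng, 100)
        q = ell.closest_boundary_points(pts)
        d = ell.boundary_distances(pts)
        # returned point is on the surface and at the reported distance
        np.testing.assert_allclose(np.sum((q / ell.semi_axes) ** 2, axis=1),
                                   1.0, atol=1e-6)
        np.testing.assert_allclose(np.linalg.norm(pts - q, axis=1), d, atol=1e-8)

    def test_distance_is_minimal(self, rng):
        """Reported boundary distance <= distance to any surface point."""
        ell = EllipsoidDomain((8.0, 5.0, 3.0))
        pts = ell.sample_uniform(rng, 20)
        th = np.linspace(0, np.pi, 60)
        ph = np.linspace(0, 2 * np.pi, 120)
        T, P = np.meshgrid(th, ph)
        surf = np.stack([8.0 * np.sin(T) * np.cos(P), 5.0 * np.sin(T) * np.sin(P),
                         3.0 * np.cos(T)], axis=-1).reshape(-1, 3)
        d = ell.boundary_distances(pts)
        for k, p in enumerate(pts):
            dense = np.linalg.norm(surf - p, axis=1).min()
            assert d[k] <= dense + 1e-4


@pytest.fixture(scope="module")
def mesh_sphere():
    return MeshDomain(trimesh.creation.icosphere(subdivisions=4, radius=10.0))


class TestMesh:
    def test_matches_analytic(self, mesh_sphere, rng):
        pts = SphereDomain(9.0).sample_uniform(rng, 50)
        d = mesh_sphere.boundary_distances(pts)
        analytic = 10.0 - np.linalg.norm(pts, axis=1)
        assert np.max(np.abs(d - analytic)) < 0.005 * 10.0  # chord error <=0.5% R

    def test_contains(self, mesh_sphere, rng):
        inside = SphereDomain(9.5).sample_uniform(rng, 30)
        outside = inside / np.linalg.norm(inside, axis=1, keepdims=True) * 11.0
        assert mesh_sphere.contains_points(inside).all()
        assert not mesh_sphere.contains_points(outside).any()

    def test_closest_point_on_mesh(self, mesh_sphere, rng):
        pts = SphereDomain(9.0).sample_uniform(rng, 20)
        q = mesh_sphere.closest_boundary_points(pts)
        d = mesh_sphere.boundary_distances(pts)
        np.testing.assert_allclose(np.linalg.norm(pts - q, axis=1), d, rtol=1e-9)
        # the returned points lie on the mesh surface (re-projection is a fixpoint)
        d2 = np.abs(mesh_sphere.boundary_distances(q))
        assert np.max(d2) < 1e-8

    def test_box_centroid(self):
        box = MeshDomain(trimesh.creation.box(extents=(2, 2, 2),
                                              transform=trimesh.transformations.translation_matrix((1, 1, 1))))
        np.testing.assert_allclose(box.centroid(), [1, 1, 1], atol=1e-12)

    def test_rejects_open_mesh(self):
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                              faces=[[0, 1, 2]])
        with pytest.raises(DomainError):
            MeshDomain(tri)


class TestVoxelMask:
    def test_symmetric_ball(self):
        mask = ball_mask(8, shape=(20, 20, 20))
        dom = VoxelMaskDomain(mask, (1, 1, 1))
        np.testing.assert_allclose(dom.centroid(), [10, 10, 10], atol=0.5)
        assert dom.volume() == pytest.approx(4 / 3 * np.pi * 8**3, rel=0.05)
        assert dom.inradius() == pytest.approx(8, abs=1.0)

    def test_spacing_validation(self):
        with pytest.raises(DomainError):
            VoxelMaskDomain(np.ones((3, 3, 3), bool), (1, 0, 1))
        with pytest.raises(DomainError):
            VoxelMaskDomain(np.zeros((3, 3, 3), bool), (1, 1, 1))

    def test_boundary_distance_center(self):
        mask = ball_mask(10, shape=(26, 26, 26))
        dom = VoxelMaskDomain(mask, (1, 1, 1))
        d = dom.distance_to_boundary([13.0, 13.0, 13.0])
        assert d == pytest.approx(10, abs=1.5)
        q = dom.closest_boundary_point([13.0, 13.0, 13.0])
        assert np.linalg.norm(q - 13.0) == pytest.approx(d, rel=1e-9)


class TestMaskToMesh:
    def test_ball_volume(self):
        mask = ball_mask(20, shape=(46, 46, 46))
        dom = mask_to_mesh(mask, (1, 1, 1))
        assert dom.volume() == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.05)
        np.testing.assert_allclose(dom.centroid(), [23, 23, 23], atol=0.5)

    def test_anisotropic_scaling(self):
        mask = ball_mask(6, shape=(16, 16, 16))
        iso = mask_to_mesh(mask, (1, 1, 1))
        aniso = mask_to_mesh(mask, (0.05, 0.05, 0.15))
        lo, hi = aniso.bounding_box()
        lo0, hi0 = iso.bounding_box()
        np.testing.assert_allclose((hi - lo), (hi0 - lo0) * [0.05, 0.05, 0.15],
                                   rtol=1e-9)

    def test_multi_component_rejected(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[2:4, 2:4, 2:4] = True
        mask[8:10, 8:10, 8:10] = True
        with pytest.raises(DomainError):
            mask_to_mesh(mask, (1, 1, 1))

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            mask_to_mesh(np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestRasterize:
    def test_single_object_volume(self, rng):
        dom = SphereDomain(12.0, center=(12, 12, 12))
        pat = ObjectPattern.from_arrays(dom, [[12, 12, 12]], [5.0])
        mask, labels, origin = rasterize_pattern(pat, (1, 1, 1))
        count = (labels == 1).sum()
        assert count == pytest.approx(4 / 3 * np.pi * 5**3, rel=0.10)

    def test_empty_pattern(self):
        dom = SphereDomain(5.0, center=(5, 5, 5))
        pat = ObjectPattern.from_arrays(dom, np.empty((0, 3)), np.empty(0))
        _mask, labels, _origin = rasterize_pattern(pat, (1, 1, 1))
        assert (labels == 0).all()

    def test_spacing_warning(self):
        dom = SphereDomain(5.0, center=(5, 5, 5))
        pat = ObjectPattern.from_arrays(dom, [[5, 5, 5]], [0.4])
        with pytest.warns(UserWarning):
            rasterize_pattern(pat, (1, 1, 1))


def test_domain_serialization_roundtrip(tmp_path):
    for dom in (SphereDomain(3.0, (1, 2, 3)), EllipsoidDomain((3, 2, 1))):
        back = domain_from_dict(dom.to_dict())
        np.testing.assert_allclose(back.centroid(), dom.centroid())
        assert back.kind == dom.kind
    mesh = MeshDomain(trimesh.creation.icosphere(subdivisions=2, radius=4.0))
    path = tmp_path / "dom.ply"
    mesh.to_ply(path)
    back = MeshDomain.from_ply(path)
    assert back.volume() == pytest.approx(mesh.volume(), rel=1e-6)
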