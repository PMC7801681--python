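"""Confined 3-D domains and the geometric queries the rest of the package needs.

A :class:`Domain` is a bounded, closed region of 3-D space — typically a cell
nucleus — inside which hard spherical objects live.  Four concrete
representations are provided:

* :class:`SphereDomain` — analytic ball, exact queries;
* :class:`EllipsoidDomain` — analytic axis-aligned ellipsoid; the
  closest-boundary-point query is solved numerically (vectorized bisection on
  the ellipsoid projection equation);
* :class:`MeshDomain` — closed (watertight) triangular boundary mesh in
  physical coordinates; containment uses the generalized winding number and
  boundary distances use brute-force closest-point-on-triangle queries;
* :class:`VoxelMaskDomain` — 3-D boolean grid with per-axis (possibly
  anisotropic) voxel spacing; boundary distances come from the Euclidean
  distance transform evaluated in physical units.

All coordinates and distances are in the same physical length unit as the
domain parameters (μm for real nuclei, "voxels" for synthetic benchmarks).
Voxel ``(i, j, k)`` of a grid with spacing ``(sx, sy, sz)`` has its center at
``((i+0.5)sx, (j+0.5)sy, (k+0.5)sz)``; grid axes map to physical ``(x, y, z)``
in index order.
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod

import numpy as np
import trimesh
from scipy import ndimage

from .errors import DomainError, OutsideDomainError

__all__ = [
    "Domain",
    "SphereDomain",
    "EllipsoidDomain",
    "MeshDomain",
    "VoxelMaskDomain",
    "mask_to_mesh",
    "rasterize_pattern",
    "domain_from_dict",
]


def _as_points(p) -> tuple[np.ndarray, bool]:
    """Coerce to an (M, 3) float array; report whether input was a single point."""
    a = np.asarray(p, dtype=float)
    if a.ndim == 1:
        if a.shape != (3,):
            raise ValueError(f"expected a 3-vector, got shape {a.shape}")
        return a[None, :], True
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected an (M, 3) array, got shape {a.shape}")
    return a, False


class Domain(ABC):
    """A bounded closed region of 3-D space."""

    kind: str

    # -- vectorized primitives (subclasses implement these) ------------------

    @abstractmethod
    def contains_points(self, points) -> np.ndarray:
        """Boolean mask: which points lie inside (or on the boundary of) the domain."""

    @abstractmethod
    def boundary_distances(self, points) -> np.ndarray:
        """Distance from each point to the domain boundary (points assumed inside)."""

    @abstractmethod
    def closest_boundary_points(self, points) -> np.ndarray:
        """Closest boundary point for each query point (points assumed inside)."""

    @abstractmethod
    def centroid(self) -> np.ndarray:
        """Volume centroid of the domain."""

    @abstractmethod
    def volume(self) -> float: ...

    @abstractmethod
    def inradius(self) -> float:
        """Largest boundary distance attainable inside the domain (may be a
        lower bound for mesh domains, where it is evaluated at the centroid)."""

    @abstractmethod
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned (lower, upper) corners enclosing the domain."""

    # -- scalar convenience API ----------------------------------------------

    def contains(self, p) -> bool:
        pts, single = _as_points(p)
        out = self.contains_points(pts)
        return bool(out[0]) if single else out

    def distance_to_boundary(self, p):
        """Distance from an interior point to the boundary; raises if outside."""
        pts, single = _as_points(p)
        inside = self.contains_points(pts)
        if not inside.all():
            raise OutsideDomainError(f"{(~inside).sum()} query point(s) outside the domain")
        d = self.boundary_distances(pts)
        return float(d[0]) if single else d

    def closest_boundary_point(self, p):
        pts, single = _as_points(p)
        inside = self.contains_points(pts)
        if not inside.all():
            raise OutsideDomainError(f"{(~inside).sum()} query point(s) outside the domain")
        q = self.closest_boundary_points(pts)
        return q[0] if single else q

    def contains_sphere(self, p, r: float) -> bool:
        """Whether a sphere of radius ``r`` centered at ``p`` fits entirely
        inside the domain (boundary contact allowed)."""
        if r < 0:
            raise ValueError("radius must be nonnegative")
        pts, single = _as_points(p)
        out = np.zeros(len(pts), dtype=bool)
        inside = self.contains_points(pts)
        if inside.any():
            out[inside] = self.boundary_distances(pts[inside]) >= np.asarray(r)
        return bool(out[0]) if single else out

    def sample_uniform(self, rng: np.random.Generator, n: int | None = None):
        """Uniform random point(s) over the domain volume.

        Default implementation: rejection sampling from the bounding box.
        """
        if self.volume() <= 0:
            raise DomainError("degenerate domain: zero volume")
        lo, hi = self.bounding_box()
        want = 1 if n is None else int(n)
        out = np.empty((want, 3))
        got = 0
        batch = max(4 * want, 64)
        while got < want:
            cand = rng.uniform(lo, hi, size=(batch, 3))
            keep = cand[self.contains_points(cand)]
            take = min(len(keep), want - got)
            out[got : got + take] = keep[:take]
            got += take
        return out[0] if n is None else out

    # -- serialization -------------------------------------------------------

    @abstractmethod
    def to_dict(self) -> dict:
        """JSON-serializable description (file-backed kinds store a path)."""


class SphereDomain(Domain):
    """Analytic ball of radius ``radius`` centered at ``center``."""

    kind = "analytic_sphere"

    def __init__(self, radius: float, center=(0.0, 0.0, 0.0)):
        if radius <= 0:
            raise DomainError("sphere radius must be positive")
        self.radius = float(radius)
        self.center = np.asarray(center, dtype=float)
        if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
            raise DomainError("center must be a finite 3-vector")

    def contains_points(self, points):
        pts, _ = _as_points(points)
        return np.linalg.norm(pts - self.center, axis=1) <= self.radius

    def boundary_distances(self, points):
        pts, _ = _as_points(points)
        return self.radius - np.linalg.norm(pts - self.center, axis=1)

    def closest_boundary_points(self, points):
        pts, _ = _as_points(points)
        v = pts - self.center
        nrm = np.linalg.norm(v, axis=1)
        # tie-break at the exact center: project along +x (deterministic)
        u = np.where(nrm[:, None] > 0, v / np.where(nrm[:, None] > 0, nrm[:, None], 1.0),
                     np.array([1.0, 0.0, 0.0]))
        return self.center + self.radius * u

    def centroid(self):
        return self.center.copy()

    def volume(self):
        return 4.0 / 3.0 * np.pi * self.radius**3

    def inradius(self):
        return self.radius

    def bounding_box(self):
        return self.center - self.radius, self.center + self.radius

    def sample_uniform(self, rng, n=None):
        want = 1 if n is None else int(n)
        u = rng.standard_normal((want, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = self.radius * rng.random(want) ** (1.0 / 3.0)
        out = self.center + u * r[:, None]
        return out[0] if n is None else out

    def to_dict(self):
        return {"kind": self.kind, "radius": self.radius, "center": self.center.tolist()}


class EllipsoidDomain(Domain):
    """Axis-aligned ellipsoid with semi-axes ``semi_axes`` centered at ``center``.

    The closest boundary point for an interior query ``y`` (center-relative)
    is ``x_i = e_i^2 y_i / (t + e_i^2)`` where ``t`` is the unique root of
    ``sum_i (e_i y_i / (t + e_i^2))^2 = 1`` on ``(-min(e)^2, 0]``.  The root is
    found by vectorized bisection; exactly-zero components are perturbed by a
    relative 1e-12 to stay off the degenerate branch.
    """

    kind = "analytic_ellipsoid"

    def __init__(self, semi_axes, center=(0.0, 0.0, 0.0)):
        self.semi_axes = np.asarray(semi_axes, dtype=float)
        self.center = np.asarray(center, dtype=float)
        if self.semi_axes.shape != (3,) or np.any(self.semi_axes <= 0):
            raise DomainError("semi-axes must be three positive lengths")

    def contains_points(self, points):
        pts, _ = _as_points(points)
        q = (pts - self.center) / self.semi_axes
        return np.einsum("ij,ij->i", q, q) <= 1.0

    def _project(self, points):
        """Closest boundary points, vectorized bisection (interior queries)."""
        e = self.semi_axes
        y = np.asarray(points, dtype=float) - self.center
        sign = np.where(y < 0, -1.0, 1.0)
        a = np.abs(y) + 1e-12 * e  # perturb off the degenerate branch
        e2 = e**2

        def f(t):
            return np.sum((e2 * a / (t[:, None] + e2)) ** 2 / e2, axis=1) - 1.0

        lo = np.full(len(a), -e2.min() * (1 - 1e-12))
        hi = np.zeros(len(a))
        # interior points have f(0) < 0 (strictly inside) — extend hi if on boundary
        bad = f(hi) > 0
        hi[bad] = np.linalg.norm(a[bad], axis=1) * e.max()
        for _ in range(120):
            mid = 0.5 * (lo + hi)
            pos = f(mid) > 0
            lo = np.where(pos, mid, lo)
            hi = np.where(pos, hi, mid)
        t = 0.5 * (lo + hi)
        x = e2 * a / (t[:, None] + e2)
        return self.center + sign * x

    def closest_boundary_points(self, points):
        pts, _ = _as_points(points)
        return self._project(pts)

    def boundary_distances(self, points):
        pts, _ = _as_points(points)
        return np.linalg.norm(pts - self._project(pts), axis=1)

    def centroid(self):
        return self.center.copy()

    def volume(self):
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semi_axes))

    def inradius(self):
        return float(self.semi_axes.min())

    def bounding_box(self):
        return self.center - self.semi_axes, self.center + self.semi_axes

    def sample_uniform(self, rng, n=None):
        want = 1 if n is None else int(n)
        u = rng.standard_normal((want, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = rng.random(want) ** (1.0 / 3.0)
        out = self.center + u * r[:, None] * self.semi_axes
        return out[0] if n is None else out

    def to_dict(self):
        return {"kind": self.kind, "semi_axes": self.semi_axes.tolist(),
                "center": self.center.tolist()}


def _winding_numbers(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Generalized winding number of each point w.r.t. an oriented closed mesh.

    Van Oosterom–Strackee solid angles summed over faces; ≈1 inside, ≈0
    outside for a watertight, consistently oriented mesh.  Points are
    processed in chunks to bound memory at O(chunk × faces).
    """
    tri = mesh.triangles  # (F, 3, 3)
    out = np.empty(len(points))
    chunk = max(1, int(2**22 / max(len(tri), 1)))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("pfi,pfi->pf", a, b) * lc
               + np.einsum("pfi,pfi->pf", b, c) * la
               + np.einsum("pfi,pfi->pf", c, a) * lb)
        omega = 2.0 * np.arctan2(num, den)
        out[s : s + chunk] = omega.sum(axis=1) / (4.0 * np.pi)
    return out


class MeshDomain(Domain):
    """Domain bounded by a closed triangular mesh in physical coordinates."""

    kind = "mesh"

    def __init__(self, mesh: trimesh.Trimesh, source_path: str | None = None):
        if not isinstance(mesh, trimesh.Trimesh):
            mesh = trimesh.Trimesh(vertices=np.asarray(mesh[0]), faces=np.asarray(mesh[1]),
                                   process=True)
        if not mesh.is_watertight:
            raise DomainError("mesh is not watertight (every edge must be shared by 2 faces)")
        if mesh.volume < 0:
            mesh.invert()
        self.mesh = mesh
        self.source_path = source_path

    @classmethod
    def from_ply(cls, path) -> "MeshDomain":
        mesh = trimesh.load(str(path), file_type="ply", process=True)
        return cls(mesh, source_path=str(path))

    def to_ply(self, path) -> None:
        self.mesh.export(str(path), file_type="ply", encoding="ascii")

    def contains_points(self, points):
        pts, _ = _as_points(points)
        return _winding_numbers(self.mesh, pts) > 0.5

    def _closest(self, pts):
        from trimesh.proximity import closest_point_naive

        closest, dist, _tri = closest_point_naive(self.mesh, pts)
        return np.asarray(closest), np.asarray(dist)

    def boundary_distances(self, points):
        pts, _ = _as_points(points)
        return self._closest(pts)[1]

    def closest_boundary_points(self, points):
        pts, _ = _as_points(points)
        return self._closest(pts)[0]

    def centroid(self):
        return np.asarray(self.mesh.center_mass)

    def volume(self):
        return float(self.mesh.volume)

    def inradius(self):
        # boundary distance at the centroid: a lower bound on the true inradius
        return float(self.boundary_distances(self.centroid()[None, :])[0])

    def bounding_box(self):
        b = self.mesh.bounds
        return np.asarray(b[0], dtype=float), np.asarray(b[1], dtype=float)

    def to_dict(self):
        d = {"kind": self.kind}
        if self.source_path is not None:
            d["path"] = self.source_path
        else:
            d["vertices"] = np.asarray(self.mesh.vertices).tolist()
            d["faces"] = np.asarray(self.mesh.faces).tolist()
        return d


class VoxelMaskDomain(Domain):
    """Domain defined by a 3-D boolean voxel mask with per-axis spacing.

    Boundary distances are the Euclidean distance transform of the mask
    (physical units, anisotropy-aware) interpolated at the query point; they
    measure distance to the nearest background voxel center, so carry an
    O(half-voxel) discretization bias near the surface.
    """

    kind = "voxel_mask"

    def __init__(self, mask, spacing, source_path: str | None = None):
        mask = np.asarray(mask).astype(bool)
        spacing = np.asarray(spacing, dtype=float)
        if mask.ndim != 3:
            raise DomainError("mask must be a 3-D array")
        if spacing.shape != (3,) or np.any(spacing <= 0):
            raise DomainError("spacing must be three strictly positive lengths")
        if not mask.any():
            raise DomainError("empty mask")
        self.mask = mask
        self.spacing = spacing
        self.source_path = source_path
        # pad so foreground touching the array border still sees background
        padded = np.pad(mask, 1)
        edt, idx = ndimage.distance_transform_edt(
            padded, sampling=spacing, return_indices=True)
        self._edt = edt[1:-1, 1:-1, 1:-1]
        self._bg_idx = idx[:, 1:-1, 1:-1, 1:-1] - 1  # nearest background voxel index
        self._centers_cache = None

    def _to_index(self, pts):
        return np.floor(pts / self.spacing).astype(int)

    def contains_points(self, points):
        pts, _ = _as_points(points)
        idx = self._to_index(pts)
        ok = np.all((idx >= 0) & (idx < np.array(self.mask.shape)), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if ok.any():
            ii = idx[ok]
            out[ok] = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def boundary_distances(self, points):
        pts, _ = _as_points(points)
        coords = (pts / self.spacing - 0.5).T  # fractional voxel-center coords
        return ndimage.map_coordinates(self._edt, coords, order=1, mode="nearest")

    def closest_boundary_points(self, points):
        pts, _ = _as_points(points)
        d = self.boundary_distances(pts)
        idx = np.clip(self._to_index(pts), 0, np.array(self.mask.shape) - 1)
        bg = self._bg_idx[:, idx[:, 0], idx[:, 1], idx[:, 2]].T
        bg_center = (bg + 0.5) * self.spacing
        v = bg_center - pts
        nrm = np.linalg.norm(v, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return pts + v / nrm * d[:, None]

    def voxel_centers(self) -> np.ndarray:
        """Physical centers of all foreground voxels (cached)."""
        if self._centers_cache is None:
            idx = np.argwhere(self.mask)
            self._centers_cache = (idx + 0.5) * self.spacing
        return self._centers_cache

    def centroid(self):
        return self.voxel_centers().mean(axis=0)

    def volume(self):
        return float(self.mask.sum()) * float(np.prod(self.spacing))

    def inradius(self):
        return float(self._edt.max())

    def bounding_box(self):
        idx = np.argwhere(self.mask)
        return idx.min(axis=0) * self.spacing, (idx.max(axis=0) + 1) * self.spacing

    def to_dict(self):
        d = {"kind": self.kind, "spacing": self.spacing.tolist()}
        if self.source_path is not None:
            d["path"] = self.source_path
        else:
            d["shape"] = list(self.mask.shape)
        return d


def mask_to_mesh(mask, spacing) -> MeshDomain:
    """Triangulate the boundary of a binary mask into a watertight mesh.

    Marching Cubes at iso-level 0.5 on the zero-padded mask, vertices mapped
    to physical coordinates under the voxel-center convention.  The mask must
    contain a single connected foreground component.
    """
    from skimage import measure

    mask = np.asarray(mask).astype(bool)
    spacing = np.asarray(spacing, dtype=float)
    if not mask.any():
        raise DomainError("empty mask")
    _labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        raise DomainError(f"mask has {n_comp} connected components, expected 1")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _normals, _vals = measure.marching_cubes(
        padded, level=0.5, spacing=tuple(spacing))
    verts = verts - 0.5 * spacing  # padded index i ↔ original center (i-0.5)·s
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    return MeshDomain(mesh)


def rasterize_pattern(pattern, spacing, pad_voxels: int = 1):
    """Voxelize an object pattern: domain mask plus integer label image.

    A voxel belongs to object ``i`` iff its center lies within ``r_i`` of the
    object centroid; labels follow the pattern's object labels.  Returns
    ``(mask, labels, origin)`` where ``origin`` is the physical coordinate of
    the grid corner (voxel (0,0,0) center sits at ``origin + 0.5*spacing``).
    """
    spacing = np.asarray(spacing, dtype=float)
    lo, hi = pattern.domain.bounding_box()
    origin = lo - pad_voxels * spacing
    shape = np.ceil((hi - origin) / spacing).astype(int) + pad_voxels
    radii = pattern.radii
    if len(radii) and spacing.max() > 2 * radii.min():
        warnings.warn("voxel spacing exceeds the smallest object diameter; "
                      "small objects may rasterize to zero voxels")
    idx = np.indices(shape)
    centers = (np.stack(idx, axis=-1) + 0.5) * spacing + origin
    flat = centers.reshape(-1, 3)
    mask = pattern.domain.contains_points(flat).reshape(shape)
    labels = np.zeros(shape, dtype=np.int32)
    for obj in pattern.objects:
        d2 = np.sum((flat - (obj.centroid - 0.0)) ** 2, axis=1).reshape(shape)
        labels[(d2 <= obj.radius**2)] = obj.label
    labels[~mask] = 0
    return mask, labels, origin


def domain_from_dict(d: dict, base_dir=None) -> Domain:
    """Rebuild a domain from its :meth:`Domain.to_dict` description."""
    import os

    kind = d.get("kind")
    if kind == "analytic_sphere":
        return SphereDomain(d["radius"], d.get("center", (0, 0, 0)))
    if kind == "analytic_ellipsoid":
        return EllipsoidDomain(d["semi_axes"], d.get("center", (0, 0, 0)))
    if kind == "mesh":
        if "path" in d:
            path = d["path"]
            if base_dir is not None and not os.path.isabs(path):
                path = os.path.join(base_dir, path)
            return MeshDomain.from_ply(path)
        return MeshDomain(trimesh.Trimesh(vertices=np.asarray(d["vertices"]),
                                          faces=np.asarray(d["faces"]), process=True))
    if kind == "voxel_mask":
        import tifffile

        path = d["path"]
        if base_dir is not None and not os.path.isabs(path):
            path = os.path.join(base_dir, path)
        mask = tifffile.imread(path).astype(bool)
        return VoxelMaskDomain(mask, d["spacing"], source_path=path)
    raise DomainError(f"unknown domain kind: {kind!r}")
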