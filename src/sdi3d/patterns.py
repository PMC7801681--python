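"""Object-pattern data model, extraction from labeled 3-D images, and file IO.

An :class:`ObjectPattern` is an ordered collection of hard spheres — centroid
``p_i``, equivalent radius ``r_i`` — inside a :class:`~sdi3d.geometry.Domain`.
Patterns extracted from segmented microscopy images represent each object
(e.g. a chromocenter) by the sphere with the same volume as its voxel mask.

Validity means two constraints, both with non-strict inequality (touching is
allowed): the hard-core constraint ``‖p_i − p_j‖ ≥ r_i + r_j`` for every pair,
and containment ``distance_to_boundary(p_i) ≥ r_i`` for every object.
Simulated patterns always satisfy both; patterns extracted from real images
may violate them slightly (touching or elongated objects), in which case
extraction returns a violation report rather than failing.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PatternFormatError
from .geometry import Domain, domain_from_dict, mask_to_mesh

__all__ = [
    "SpatialObject",
    "ObjectPattern",
    "MorphologyStats",
    "ViolationReport",
    "validate_pattern",
    "extract_pattern",
    "read_pattern",
    "write_pattern",
]

#: relative slack for float round-off when checking non-strict inequalities
_REL_EPS = 1e-9


@dataclass(frozen=True)
class SpatialObject:
    """A hard sphere: centroid (physical units), radius > 0, integer label."""

    centroid: np.ndarray
    radius: float
    label: int

    def __post_init__(self):
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        if self.centroid.shape != (3,) or not np.all(np.isfinite(self.centroid)):
            raise PatternFormatError("centroid must be a finite 3-vector")
        if not (self.radius > 0):
            raise PatternFormatError(f"radius must be positive, got {self.radius}")
        if self.label <= 0:
            raise PatternFormatError("label must be a positive integer")


class ObjectPattern:
    """Hard spheres in a confined domain."""

    def __init__(self, domain: Domain, objects, metadata: dict | None = None):
        self.domain = domain
        self.objects = list(objects)
        self.metadata = dict(metadata or {})
        labels = [o.label for o in self.objects]
        if len(set(labels)) != len(labels):
            raise PatternFormatError("object labels must be unique")

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def centroids(self) -> np.ndarray:
        if not self.objects:
            return np.empty((0, 3))
        return np.array([o.centroid for o in self.objects])

    @property
    def radii(self) -> np.ndarray:
        return np.array([o.radius for o in self.objects])

    @property
    def labels(self) -> np.ndarray:
        return np.array([o.label for o in self.objects], dtype=int)

    @classmethod
    def from_arrays(cls, domain, centroids, radii, labels=None, metadata=None):
        centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
        radii = np.atleast_1d(np.asarray(radii, dtype=float))
        if labels is None:
            labels = np.arange(1, len(radii) + 1)
        objs = [SpatialObject(c, float(r), int(l))
                for c, r, l in zip(centroids, radii, labels, strict=True)]
        return cls(domain, objs, metadata)

    def __repr__(self):
        return (f"ObjectPattern(n={self.n_objects}, domain={self.domain.kind}, "
                f"metadata={self.metadata})")


@dataclass
class ViolationReport:
    """Hard-core / containment violations of a pattern, with magnitudes."""

    pair_violations: list = field(default_factory=list)  # (label_i, label_j, magnitude)
    containment_violations: list = field(default_factory=list)  # (label, magnitude)

    @property
    def ok(self) -> bool:
        return not self.pair_violations and not self.containment_violations

    def __str__(self):
        if self.ok:
            return "valid pattern (no violations)"
        lines = [f"hard-core violation {i}-{j}: overlap {m:.6g}"
                 for i, j, m in self.pair_violations]
        lines += [f"containment violation {i}: protrusion {m:.6g}"
                  for i, m in self.containment_violations]
        return "\n".join(lines)


def validate_pattern(pattern: ObjectPattern) -> ViolationReport:
    """Check hard-core and containment constraints (touching allowed).

    A tiny relative slack absorbs float round-off so that exactly-touching
    configurations do not register as violations.
    """
    report = ViolationReport()
    n = pattern.n_objects
    if n == 0:
        return report
    p = pattern.centroids
    r = pattern.radii
    labels = pattern.labels
    scale = max(r.max(), 1.0)
    eps = _REL_EPS * scale
    if n >= 2:
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(p))
        for i in range(n):
            for j in range(i + 1, n):
                overlap = (r[i] + r[j]) - d[i, j]
                if overlap > eps:
                    report.pair_violations.append(
                        (int(labels[i]), int(labels[j]), float(overlap)))
    inside = pattern.domain.contains_points(p)
    bd = np.full(n, -np.inf)
    if inside.any():
        bd[inside] = pattern.domain.boundary_distances(p[inside])
    for i in range(n):
        protrusion = r[i] - bd[i]
        if protrusion > eps:
            report.containment_violations.append((int(labels[i]), float(protrusion)))
    return report


@dataclass
class MorphologyStats:
    """Per-object and per-domain morphology of an extracted pattern.

    ``per_object`` has one row per label with columns ``label``, ``volume``,
    ``equivalent_radius`` ( ``(3V/4π)^{1/3}`` ), ``sphericity``
    ( ``π^{1/3}(6V)^{2/3}/A``, 1 for a perfect sphere, inflated mesh surface
    area can push it slightly above 1 on coarse voxelizations ).
    Domain flatness and elongation are principal-axis ratios of the mask
    (``sqrt(λ2/λ3)`` and ``sqrt(λ1/λ2)`` for eigenvalues λ1 ≥ λ2 ≥ λ3).
    """

    per_object: pd.DataFrame
    domain_volume: float
    n_objects: int
    elongation: float
    flatness: float


def _mask_axis_ratios(mask, spacing):
    idx = np.argwhere(mask) * np.asarray(spacing)
    if len(idx) < 2:
        return 1.0, 1.0
    cov = np.cov((idx - idx.mean(axis=0)).T)
    ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
    ev = np.maximum(ev, 1e-12)
    return float(np.sqrt(ev[0] / ev[1])), float(np.sqrt(ev[1] / ev[2]))


def _label_sphericity(mask_lab, spacing):
    """Sphericity of one label's voxel set via its Marching-Cubes surface."""
    from skimage import measure

    padded = np.pad(mask_lab, 1).astype(np.float32)
    verts, faces, _n, _v = measure.marching_cubes(padded, level=0.5,
                                                  spacing=tuple(spacing))
    area = measure.mesh_surface_area(verts, faces)
    vol = mask_lab.sum() * float(np.prod(spacing))
    return float(np.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / area)


def extract_pattern(nucleus_mask, labels, spacing, build_domain_mesh: bool = True):
    """Extract an equivalent-sphere object pattern from a labeled 3-D image.

    Parameters
    ----------
    nucleus_mask : 3-D bool array
        Binary mask of the domain (e.g. the nucleus).
    labels : 3-D int array
        Label image of the objects (0 = background); every labeled voxel must
        lie inside ``nucleus_mask``.
    spacing : (sx, sy, sz)
        Physical voxel spacing; anisotropy is honoured in all measurements.
    build_domain_mesh : bool
        Triangulate the mask into a mesh domain (default); otherwise keep a
        voxel-mask domain (faster, half-voxel boundary bias).

    Returns
    -------
    (pattern, stats, report)
        The pattern (one equivalent sphere per label, centroid =
        volume-weighted mean of voxel centers), its morphology statistics,
        and the constraint-violation report.  Violations (touching or
        elongated real objects whose equivalent spheres overlap) are reported,
        not fatal.
    """
    from .geometry import VoxelMaskDomain

    nucleus_mask = np.asarray(nucleus_mask).astype(bool)
    labels = np.asarray(labels)
    spacing = np.asarray(spacing, dtype=float)
    if labels.shape != nucleus_mask.shape:
        raise PatternFormatError("labels and mask shapes differ")
    if np.any(labels[~nucleus_mask] > 0):
        raise PatternFormatError("labeled voxels outside the nucleus mask")

    voxel_volume = float(np.prod(spacing))
    ids = np.unique(labels)
    ids = ids[ids > 0]
    objs, rows = [], []
    for lab in ids:
        where = labels == lab
        count = int(where.sum())
        centroid = (np.argwhere(where) + 0.5).mean(axis=0) * spacing
        volume = count * voxel_volume
        radius = (3 * volume / (4 * np.pi)) ** (1 / 3)
        sph = _label_sphericity(where, spacing)
        objs.append(SpatialObject(centroid, radius, int(lab)))
        rows.append({"label": int(lab), "volume": volume,
                     "equivalent_radius": radius, "sphericity": sph})

    if build_domain_mesh:
        domain = mask_to_mesh(nucleus_mask, spacing)
    else:
        domain = VoxelMaskDomain(nucleus_mask, spacing)
    pattern = ObjectPattern(domain, objs,
                            metadata={"voxel_spacing": spacing.tolist()})
    elong, flat = _mask_axis_ratios(nucleus_mask, spacing)
    stats = MorphologyStats(
        per_object=pd.DataFrame(rows, columns=["label", "volume",
                                               "equivalent_radius", "sphericity"]),
        domain_volume=nucleus_mask.sum() * voxel_volume,
        n_objects=len(objs), elongation=elong, flatness=flat)
    report = validate_pattern(pattern)
    return pattern, stats, report


# ---------------------------------------------------------------------------
# File IO: one CSV per pattern (label,x,y,z,radius) + JSON sidecar holding the
# domain description and metadata.  Decimal text at 12 significant digits.
# ---------------------------------------------------------------------------

def _sidecar_path(csv_path) -> str:
    base, _ext = os.path.splitext(str(csv_path))
    return base + ".json"


def write_pattern(pattern: ObjectPattern, path) -> None:
    """Write a pattern as CSV (label,x,y,z,radius) plus a JSON sidecar."""
    path = str(path)
    df = pd.DataFrame({
        "label": pattern.labels if pattern.n_objects else np.array([], dtype=int),
        "x": pattern.centroids[:, 0] if pattern.n_objects else [],
        "y": pattern.centroids[:, 1] if pattern.n_objects else [],
        "z": pattern.centroids[:, 2] if pattern.n_objects else [],
        "radius": pattern.radii if pattern.n_objects else [],
    })
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = {"domain": pattern.domain.to_dict(), "metadata": pattern.metadata}
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_pattern(path, domain: Domain | None = None) -> ObjectPattern:
    """Read a pattern CSV (+ JSON sidecar for the domain unless one is given)."""
    path = str(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise PatternFormatError(f"cannot parse pattern file {path}: {exc}") from exc
    required = {"label", "x", "y", "z", "radius"}
    if not required.issubset(df.columns):
        raise PatternFormatError(
            f"pattern file {path} missing columns {sorted(required - set(df.columns))}")
    metadata = {}
    if domain is None:
        sidecar = _sidecar_path(path)
        if not os.path.exists(sidecar):
            raise PatternFormatError(f"missing domain sidecar {sidecar}")
        with open(sidecar) as fh:
            side = json.load(fh)
        if "domain" not in side:
            raise PatternFormatError(f"sidecar {sidecar} has no domain reference")
        domain = domain_from_dict(side["domain"], base_dir=os.path.dirname(path))
        metadata = side.get("metadata", {})
    if len(df) and (df["radius"] <= 0).any():
        raise PatternFormatError("pattern contains non-positive radii")
    return ObjectPattern.from_arrays(
        domain, df[["x", "y", "z"]].to_numpy(dtype=float),
        df["radius"].to_numpy(dtype=float), df["label"].to_numpy(dtype=int),
        metadata=metadata)
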