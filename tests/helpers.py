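"""Shared test utilities: brute-force descriptor oracles and pattern factories.

The oracles intentionally use plain double loops and no code from the
descriptor implementation, so they can serve as an independent check.
"""

import math

import numpy as np

from sdi3d import ObjectPattern, SphereDomain


def brute_force_distances(pattern, descriptor, positions=None):
    """Distance multiset behind one descriptor, by explicit loops."""
    pts = [tuple(c) for c in pattern.centroids]
    n = len(pts)

    def dist(a, b):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))

    if descriptor == "F":
        out = []
        for q in positions.points:
            out.append(min(dist(tuple(q), p) for p in pts))
        return np.array(out)
    if descriptor == "G":
        return np.array([min(dist(pts[i], pts[j]) for j in range(n) if j != i)
                         for i in range(n)])
    if descriptor == "Z":
        return np.array([max(dist(pts[i], pts[j]) for j in range(n) if j != i)
                         for i in range(n)])
    if descriptor == "H":
        return np.array([dist(pts[i], pts[j])
                         for i in range(n) for j in range(i + 1, n)])
    if descriptor == "B":
        return np.array([pattern.domain.distance_to_boundary(np.array(p))
                         for p in pts])
    if descriptor == "C":
        m = pattern.domain.centroid()
        return np.array([dist(p, tuple(m)) for p in pts])
    raise ValueError(descriptor)


def random_sphere_pattern(rng, n_max=15, radius=20.0):
    """A random (not hard-core) point pattern in a ball, for estimator tests."""
    n = int(rng.integers(2, n_max + 1))
    dom = SphereDomain(radius)
    pts = dom.sample_uniform(rng, n)
    radii = rng.uniform(0.1, 0.5, n)
    return ObjectPattern.from_arrays(dom, pts, radii)
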