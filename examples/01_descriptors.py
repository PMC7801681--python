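"""Estimate the six distance-distribution descriptors of one pattern.

Builds a completely random pattern of 10 spheres (radius 5) in a ball of
radius 30, then prints the mean of each descriptor's distance set and a few
CDF evaluations.
"""

import numpy as np

from sdi3d import (
    SphereDomain,
    estimate_boundary,
    estimate_F,
    estimate_pairwise,
    simulate_csr,
    summary_distances,
    uniform_positions,
)

rng = np.random.default_rng(0)
domain = SphereDomain(30.0)
pattern = simulate_csr(domain, np.full(10, 5.0), rng)

G, H, Z = estimate_pairwise(pattern)
B, C = estimate_boundary(pattern)
positions = uniform_positions(domain, 5000, 0)
F = estimate_F(pattern, positions)

print(f"pattern: {pattern.n_objects} objects in a ball of radius 30")
s = summary_distances(pattern)
print(f"mean nearest-neighbour distance (G set): {s.nearest:.2f}")
print(f"mean pair distance              (H set): {s.pair:.2f}")
print(f"mean farthest-neighbour distance (Z set): {s.farthest:.2f}")
print(f"mean boundary distance          (B set): {B.mean():.2f}")
print(f"mean distance to domain center  (C set): {C.mean():.2f}")
print(f"empty-space function F(15) = {F(15.0):.3f}  "
      "(fraction of space within 15 of an object)")
# G(x) <= H(x) <= ... the sandwich: per-object min <= any pair <= per-object max
x = 25.0
print(f"sandwich at x={x}: Z={Z(x):.2f} <= H={H(x):.2f} <= G={G(x):.2f}")
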