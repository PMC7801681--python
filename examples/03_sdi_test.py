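"""Goodness-of-fit of one pattern under one model: the SDI.

Simulates a border-attraction pattern and tests it against the completely
random model with the boundary-distance function B.  S is the maximal signed
deviation between the model-mean curve and the observed curve; the SDI is
the fraction of a second simulation set whose S falls strictly below the
observed S.  An SDI near 0 means the observed boundary distances are smaller
than the model predicts (objects hug the border); near 1, larger.
"""

import numpy as np

from sdi3d import (
    ModelSpec,
    SphereDomain,
    compute_sdi_multi,
    simulate_border_biased,
    uniform_positions,
)

rng = np.random.default_rng(2)
domain = SphereDomain(30.0)
radii = np.full(10, 5.0)

# objects attracted to the boundary (accept outright within mu=5 of it)
pattern = simulate_border_biased(domain, radii, "attraction", 5.0, 5.0, rng)

spec = ModelSpec("csr", radii=radii)
positions = uniform_positions(domain, 5000, 0)
res = compute_sdi_multi(pattern, spec, ["F", "G", "H", "B", "C", "Z"],
                        n_sim1=99, n_sim2=99, positions=positions, rng=rng)

print("border-attraction pattern tested against the completely random model")
print(f"{'descriptor':>10s} {'S':>8s} {'x*':>7s} {'SDI':>6s}")
for d, r in res.items():
    print(f"{d:>10s} {r.S:8.3f} {r.x_star:7.2f} {r.sdi:6.3f}")
print("\nborder-attraction signature: B-SDI near 0 (boundary distances smaller"
      "\nthan random) and C-SDI near 1 (objects far from the domain center)."
      "\nSingle-pattern SDIs are noisy; population-level tests (example 04)"
      "\naggregate them over many patterns.")
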