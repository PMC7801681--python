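"""Population-level model testing: SDI uniformity over many patterns.

Under a model that fits, per-pattern SDIs are uniform on [0, 1]; systematic
departures reveal the direction of misfit.  Here 40 completely random
patterns are tested against their own model (uniform SDIs expected) and 40
border-attraction patterns against the random model (B-SDI mass near 0).
"""

import numpy as np

from sdi3d import (
    ModelSpec,
    SphereDomain,
    compute_sdi_multi,
    simulate_border_biased,
    simulate_csr,
    test_uniformity,
)

rng = np.random.default_rng(3)
domain = SphereDomain(30.0)
radii = np.full(10, 5.0)
spec = ModelSpec("csr", radii=radii)


def sdi_sample(draw, n=40):
    out = []
    for _ in range(n):
        res = compute_sdi_multi(draw(), spec, ["B"], 49, 49, rng=rng)
        out.append(res["B"].sdi)
    return out


matched = sdi_sample(lambda: simulate_csr(domain, radii, rng))
mismatched = sdi_sample(lambda: simulate_border_biased(
    domain, radii, "attraction", 5.0, 5.0, rng))

for name, sdis in [("random patterns vs random model", matched),
                   ("attraction patterns vs random model", mismatched)]:
    t = test_uniformity(sdis, descriptor="B", model="csr")
    print(f"{name}: mean B-SDI={np.mean(sdis):.3f}, "
          f"KS D={t.statistic:.3f}, p={t.p_value:.2g}")
print("\nthe matched population passes uniformity; the border-attraction "
      "population\nconcentrates near 0 and is rejected.")
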