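"""From a labeled 3-D image to a pattern and its morphology statistics.

Builds a synthetic segmented stack (a ball-shaped domain mask plus two
labeled objects), extracts the equivalent-sphere pattern with anisotropic
voxel spacing, and prints per-object morphology.  Real inputs would be
nucleus/chromocenter TIFF stacks from a segmentation pipeline.
"""

import numpy as np

from sdi3d import extract_pattern

shape = (48, 48, 24)  # e.g. fewer planes along z
spacing = (0.1, 0.1, 0.25)  # micrometres; z coarser than xy
ii, jj, kk = np.indices(shape)
# domain: ellipsoidal mask filling the stack
mask = (((ii - 23.5) / 22) ** 2 + ((jj - 23.5) / 22) ** 2
        + ((kk - 11.5) / 10) ** 2) <= 1.0

labels = np.zeros(shape, dtype=np.int32)
labels[((ii - 14) ** 2 + (jj - 16) ** 2 + ((kk - 12) * 2.5) ** 2) <= 36] = 1
labels[((ii - 33) ** 2 + (jj - 30) ** 2 + ((kk - 10) * 2.5) ** 2) <= 25] = 2
labels[~mask] = 0

pattern, stats, report = extract_pattern(mask, labels, spacing)

print(f"domain volume: {stats.domain_volume:.2f} um^3, "
      f"elongation {stats.elongation:.2f}, flatness {stats.flatness:.2f}")
print(stats.per_object.to_string(index=False,
                                 float_format=lambda v: f"{v:.4f}"))
print("\ncentroids are in physical units (um); the equivalent radius is the "
      "radius\nof the sphere with the object's volume; sphericity is 1 for a "
      "perfect sphere.")
print("constraint violations:", "none" if report.ok else report)
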