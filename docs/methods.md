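# Methods

This note documents the statistical machinery implemented in `sdi3d`: the
models and their assumptions, the estimators and their conventions, the
numerical choices, and what the synthetic validation does and does not
establish.

## Data model and constraints

A pattern is an ordered set of hard spheres (centroid `p_i`, radius `r_i`,
integer label) inside a bounded closed domain `D`.  Two constraints define
validity, both with non-strict inequality so that exact touching is legal:

* hard-core: `‖p_i − p_j‖ ≥ r_i + r_j` for all pairs;
* containment: `dist(p_i, ∂D) ≥ r_i` for all objects.

Simulators always enforce both.  Patterns extracted from segmented images
represent each object by its *equivalent sphere* (same volume as the voxel
mask, radius `(3V/4π)^{1/3}`); real touching or elongated objects can make
equivalent spheres overlap, so extraction returns a violation report instead
of failing.  Centroids are binary-mask-weighted means of voxel centers
(intensity weighting is not used; the choice matters little for compact
objects and keeps extraction independent of imaging calibration).

Sphericity is `ψ = π^{1/3} (6V)^{2/3} / A` with `A` the surface area of the
object's Marching-Cubes mesh — 1 for a perfect sphere.  The staircase bias
of voxelized surfaces inflates `A` by several percent, so ψ of a rasterized
ball plateaus around 0.92–0.95 rather than 1; values slightly above 1 can
occur for tiny objects and are tolerated.

## Domains

Four interchangeable domain backends answer the same queries (containment,
boundary distance, closest boundary point, centroid, volume, uniform
sampling):

* analytic sphere — all queries exact; uniform sampling by direction ×
  cube-root radius;
* analytic axis-aligned ellipsoid — closest boundary point via vectorized
  bisection on the ellipsoid projection equation `Σ (e_i y_i/(t+e_i²))² = 1`;
  exactly-zero coordinates are perturbed by a relative 1e-12 to avoid the
  degenerate branch of the projection;
* watertight triangular mesh — containment by generalized winding number
  (Van Oosterom–Strackee solid angles), closest point by brute force over
  triangles; meshes are produced from binary masks by Marching Cubes at
  iso-level 0.5 on the zero-padded mask, with no post-smoothing;
* voxel mask with per-axis spacing — boundary distances from the
  anisotropy-aware Euclidean distance transform interpolated at the query
  point.  These measure distance to the nearest *background voxel center*
  and so carry an O(half-voxel) bias near the surface; the mesh backend is
  the default for extracted patterns where this matters.

Voxel `(i,j,k)` has its center at `((i+0.5)s_x, (j+0.5)s_y, (k+0.5)s_z)`;
all distances are computed in physical units, so anisotropic stacks (z
spacing ≠ xy spacing, the usual confocal situation) are handled uniformly.

## Descriptors

Six empirical distance CDFs: F (position→nearest centroid, over evaluation
positions), G (nearest neighbour), H (all pairs), B (boundary distance),
C (distance to domain centroid), Z (farthest neighbour).  All use the
strict-inequality indicator `1{d < x}`; evaluation at a jump abscissa
returns the pre-jump value.  F and its relatives measure distances to
*centroids*, not sphere surfaces — the surface variant is deliberately not
provided, since the conditional-simulation null uses the same convention and
any offset cancels.

No edge-corrected estimators (Kaplan–Meier, border correction) are used:
edge effects are absorbed by conditioning the null models on the observed
domain.

Evaluation positions for F: all foreground voxel centers when the pattern
comes from an image; otherwise `L` uniform positions with a fixed per-pattern
seed (default `L = 10,000`), *shared* between the observed pattern and all
its simulations so position sampling adds no variance to the comparison.

## Models

All models are conditioned on domain, N, and radii.

**Completely random (csr).**  Sequential insertion: uniform candidate
positions, rejected on overlap, so each placement is uniform conditional on
feasibility.  Dead-ends are handled by the two documented mechanisms: after
`restart_threshold = 1000` failed attempts for one object the configuration
is cleared and the insertion order re-randomized; `max_restarts = 100`
exhausted restarts raise a packing error.

**Border-biased.**  As csr with an extra acceptance rule on the candidate's
boundary distance `d`: attraction accepts outright when `d ≤ μ`, else with
probability `exp(−((d−μ)/σ)²/2)`; repulsion mirrors it.  The synthetic
benchmark uses μ = 5 (attraction), μ = 15 (repulsion), σ = 5, with 10
objects of radius 5 in a ball of radius 30 — voxel units throughout.

**Orbital.**  Each object uniform on the iso-surface of its prescribed
boundary distance.  Sphere domains sample the shell analytically; other
domains use rejection onto the iso-surface within `orbit_tolerance`
(default 1% of the mean radius).

**Maximal repulsion.**  Metropolis minimization of
`E = −(1/N) Σ_i min_{j≠i} ‖p_i − p_j‖` from a csr (or orbital) start.
Proposals are uniform in a ball of radius δ around the current centroid
(δ initialized to the mean radius, adapted ×0.9 / ÷0.9 toward 30%
acceptance); invalid proposals count as rejections.  Uphill moves are
accepted with probability `exp(−βΔE)`; β₀ is calibrated from 100 probe moves
so initial uphill acceptance is ≈ 0.5, then grows geometrically ×1.05 per
sweep (N proposals).  The returned configuration is the *best visited* one,
which insulates results from schedule details.  Convergence is declared when
the best energy changes by less than a relative 1e-4 over **three
consecutive** windows of 50·N proposals (a single stable window proved too
eager: for N = 2 it occasionally stopped >2% short of the antipodal optimum
2(R−r); with three windows the worst observed error over 100 runs is 0.5%).
The move budget is 2000·N proposals; exhausting it is reported in the
energy trace and a warning, never an exception.  The orbit-constrained
variant projects each proposal back to its iso-distance surface
(renormalization for spheres; gradient line search along the
boundary-distance direction otherwise).  The sphere-domain annealer is
numba-compiled — it runs tens of thousands of times inside the Monte-Carlo
test machinery; other domains use a plain-Python twin, cross-checked against
the same analytic optimum.

## The SDI test

Per pattern, model and descriptor: average the descriptor over `n₁ = 99`
conditioned simulations; find `x*`, the abscissa maximizing the absolute
deviation between the observed curve and the first-set mean; record
`S = mean(x*) − obs(x*)`.  A second, independent set of `n₂ = 99`
simulations each gets its own `S` (its own `x*`, treated exactly like an
observation) against the same first-set mean, and

    SDI = #{S_sim < S_obs} / n₂.

**Sign convention.**  `S > 0` when the observed curve lies *below* the model
mean, i.e. when the observed distances are larger than the model predicts.
With this orientation: repulsion (G shifted right) gives G-SDI near 1;
attraction to the border (B shifted left) gives B-SDI near 0; clustering
(H shifted left) gives H-SDI near 0.

**Exactness of the sup.**  All curves are step functions, so the sup of a
difference is attained immediately to the right of a jump.  Deviations are
evaluated as right-limits on the union of all jump abscissae — no
discretization grid and no approximation.  Abscissae that agree to a
relative 1e-9 are merged first: orbit distances reconstructed through a
unit-vector round-trip differ from their conditioning values by ~1 ulp, and
without merging such float jitter manufactures spurious micro-deviations.
Ties in `|deviation|` break toward the smallest abscissa; ties
`S_sim = S_obs` count as not-below.

SDI values are discrete (multiples of 1/n₂).  Population uniformity is
tested with the two-sided Kolmogorov–Smirnov test (asymptotic p-value)
applied to the discrete values without continuity correction; at n₂ = 49–99
the discreteness shifts the KS statistic by ≲ 0.02, far below the rejection
thresholds in use.

**Degenerate descriptors under orbital conditioning.**  The orbital models
fix every object's boundary distance, so B of every simulation equals B of
the observed pattern exactly; in a spherical domain the same holds for C
(distance to center = R − boundary distance).  For these combinations S ≡ 0
and the SDI collapses to 0 by the tie rule: B and C carry no goodness-of-fit
information against orbital nulls and are excluded from the orbital
self-consistency checks (F, G, H, Z remain informative).

**Envelopes** are pointwise order statistics (3rd smallest/largest of 99 ≈
2.5/97.5 percentiles), clipped to bracket the mean (raw order statistics can
cross it for near-degenerate 0/1 curves, e.g. single-object descriptors).
They are diagnostic; inference uses the SDI only.  No multiple-testing
correction is applied across descriptors; reports show all p-values side by
side.

**Matched distance comparisons.**  Per pattern, the observed mean
nearest/pair/farthest distance is paired with the mean of the same summary
over conditioned simulations; pairs are compared with the two-sided Wilcoxon
signed-rank test.

## Synthetic validation: what it shows

The generator reproduces the benchmark conditions (ball of radius 30, 10
objects of radius 5; border-bias parameters as above) and the validation
suite establishes, at a reduced tier chosen to keep everything desk-sized
(50 patterns, 49+49 simulations, 2,000 F-positions; 1,000 patterns per
radius for the size-bias check):

* estimators agree exactly with an independent brute-force oracle, and the
  `Z ≤ H ≤ G` sandwich holds at every jump;
* SDIs are uniform when patterns are tested against their generating model
  (csr with all six descriptors; orbital and orbit-constrained maximal
  repulsion with F, G, H, Z);
* border-biased patterns tested against csr are detected with the expected
  directions (attraction: B-SDI low, G-SDI high; repulsion: B-SDI high);
* under csr, larger objects sit closer to the boundary (spacing strictly
  decreasing in r) and relatively closer to it after normalization — the
  latter asserted as a significant positive trend, because the effect
  between adjacent small radii (~4e-4) is below Monte-Carlo noise at any
  desk-scale sample size;
* the annealer reaches the N = 2 analytic optimum 2(R−r) within 2% (observed
  ≤ 0.5%) with a monotone best-energy trace, and converged energies separate
  from csr energies at p < 10⁻³;
* orbital outputs preserve their orbits to within tolerance (observed
  ~1e-15 in spheres).

What this does *not* show: synthetic spheres are perfectly spherical,
perfectly segmented and mutually exchangeable.  Real nuclei add segmentation
error, equivalent-sphere approximation error for elongated chromocenters,
domain-shape irregularity, and biological heterogeneity across nuclei; the
population KS test treats each pattern's SDI as one draw, which absorbs
heterogeneity in geometry and object counts but not systematic segmentation
bias.

## Known limitations

* The voxel-mask backend's half-voxel boundary-distance bias makes the mesh
  backend preferable for B-based inference on image data.
* The mesh closest-point query is brute force over triangles — fine for
  tens of queries on 10³-face meshes, slow for dense F-positions on large
  meshes (use uniform positions or the voxel backend there).
* Annealing hyperparameters (β schedule, δ adaptation, window length) are
  heuristics; the best-visited contract and the energy trace expose, rather
  than hide, residual non-convergence.
* `compare_mean_distances` requires ≥ 6 patterns (Wilcoxon needs the ranks),
  and the KS uniformity test requires ≥ 10 SDIs.
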