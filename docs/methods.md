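# Methods

## Registration model

The pipeline deforms a triangulated template surface onto a target scan in
two stages, each iterating the same correspondence → outlier-weighting →
transform-update loop.

**Correspondence model.** For the floating surface's current vertex
positions, a row-stochastic affinity matrix over the target's vertices is
built from the k nearest neighbors (`k = 3` by default, both directions)
with Gaussian weights `exp(−d²/(2σᵢ²))`. The bandwidth is adaptive per
query point, `σᵢ = bandwidth_scale × dᵏᵢ` with `dᵏᵢ` the distance to the
k-th neighbor. `bandwidth_scale` defaults to 1/3: at that setting the k-th
neighbor carries relative weight e^−4.5 ≈ 0.01, so the fused position
interpolates the nearest samples. A full-width kernel (`bandwidth_scale =
1`) gives the k-th neighbor weight e^−0.5 ≈ 0.61, which pulls every
correspondence toward the local k-neighborhood centroid — a bias of roughly
half the target's sampling distance that we measured directly (3.7 mm
single-shot correspondence error on a 2 mm warp of an 80 mm-radius
surface) and that makes dense correspondence *worse* than rigid-only
alignment. Rows with an exact (numerically zero-distance) match collapse
onto the coincident set — the σ→0 limit of the kernel — which makes
self-correspondence an exact identity and lets a perfectly initialized
rigid problem terminate at the exact solution instead of orbiting a
smoothing-biased fixed point.

Correspondences are symmetric ("push–pull"): the push estimate takes each
floating vertex to the weighted mean of its target neighbors; the pull
estimate transposes the target→floating affinity so target samples claim
floating vertices, and the two are averaged per floating vertex
(`push_pull_balance = 0.5`). Floating vertices receiving no pull mass fall
back to push. Pull resists the tangential sliding and collapse that
one-directional closest-point matching produces when template and target
sampling densities differ.

**Outlier model.** Deterministic flags: a correspondence is discarded
(weight 0) when its dominant target neighbor lies on a hole rim (an edge
used by exactly one face), on an oversized triangle (longest edge > 3 × the
median edge length), on a vertex with no incident face, or when the fused
correspondence normal opposes the floating vertex normal (front surface
matched to back). Stochastic weights: iteratively re-weighted Gaussian
weights `w = exp(−d²/(2κ²σ²))` with `σ² = Σwd²/Σw`, `κ = 3`, 10 updates.
The two compose multiplicatively. Flagged/zero-weight vertices do not
influence the transform estimate but are moved by it, so the template stays
coherent across missing data.

**Scaled rigid stage.** The weighted similarity Procrustes problem is
solved in closed form (weighted centroids, SVD of the weighted
cross-covariance with determinant sign correction, trace-corrected variance
ratio for the scale). Iteration stops when the shape-fit RMS improves by
less than 1e-5 × the target bounding-box diagonal, at 30 iterations, or
aborts with a diagnostic after 5 consecutive RMS increases. Scale
estimation can be frozen for analyses that must preserve size. An optional
landmark initialization solves the same closed form on the landmark pairs.

**Visco-elastic non-rigid stage.** Per iteration t: correspondences and
inlier weights are recomputed; the raw velocity `v = c − x` is smoothed by
`passes_viscous(t)` Gaussian convolutions over the k-NN graph (k = 10) of
the current vertex positions; the accumulated displacement `d ← d + v` is
then smoothed by `passes_elastic(t)` convolutions of the same kernel; and
`x = x₀ + d`. The smoothing kernel is Gaussian in inter-vertex distance
(bandwidth = k-th-neighbor distance), multiplied by inlier weights floored
at 1e-6 so zero-weight regions inherit motion from inlier neighbors rather
than freezing. Pass counts anneal linearly, 50 → 1 over 60 iterations by
default: heavy smoothing early (noisy correspondences, near-rigid motion)
relaxing to fine local adjustment. Smoothing the *total* field (not a
separate elastic energy term) is the implemented reading of elastic
regularization; it is isolated in one operation. Stopping is by iteration
count; an optional coverage threshold (target shape-fit RMS in mm) is
disabled by default because a universal mm threshold is scan-dependent.
The loop contains no randomness: identical inputs give bit-identical
output, and output topology always equals the template's.

**Shape-fit RMS** is the RMS over template vertices of the exact
point-to-triangle distance to the target surface. Closest-point queries
prune candidates to the faces incident to the 8 nearest target vertices
(searched only over vertices referenced by a face, so hole-interior
orphans are invisible) and evaluate the exact projection on those; tests
verify equality with an all-triangles scan.

## Landmark transfer

A landmark is embedded as its closest surface point, stored as (triangle
index, barycentric weights), and reconstructed on any mesh sharing the
template topology. Off-surface components of manual indications are
treated as digitizing noise and discarded by the projection. Leave-one-out
automatic landmarking pools all other specimens' indications in template
space (coordinate-wise arithmetic mean, re-projected onto the template
surface so the embedding stays valid) and reconstructs the average on the
held-out registered specimen; the result lies exactly on that surface and
is bitwise independent of the specimen's own manual indications. A gross
error screen flags any indication farther than 6 × the RMS repeat scatter
from its per-specimen landmark mean.

## Statistics

- **GPA**: center; optionally scale to unit centroid size; iteratively
  rotate to the evolving mean (proper rotations only) until the mean moves
  < 1e-10. Deterministic given input order.
- **Procrustes ANOVA**: aligned configurations flattened to 3p-vectors;
  sequential (Type I) sums of squares accumulated over all coordinates
  (Goodall trace form) via incremental orthonormal bases, so the
  decomposition sums exactly to the total SS. Nested terms are expressed as
  interactions after the parent main effect. F = MS_term/MS_residual;
  p-values by residual randomization of the per-term reduced model
  (999 permutations by default, seeded). With p = 1 landmark on one axis
  this reduces exactly to classical univariate ANOVA, which the tests
  check against statsmodels Type-I tables.
- **ICC(A,1)**: two-way random effects, absolute agreement, single
  measurement — chosen because agreement, not correlation, is what
  validates a replacement method; cross-checked against pingouin.
- **Levene's test** defaults to the median-centered (Brown–Forsythe)
  variant, appropriate when the compared values are themselves SDs and
  non-normal; mean centering is available.
- **Bland–Altman** limits are mean ± 1.96 × sample SD (ddof = 1) of paired
  differences.
- **PCA compactness** counts components to reach 95%/98% explained
  variance: a minimum-description-length view of registration consistency.

## Synthetic fixtures

Generators are pure functions of their seed. Surfaces are icospheres at
facial scale (radius 80 mm): `bumpy_sphere` adds seeded smooth radial
bumps (sum of Gaussians of great-circle angle, default amplitude 8% of
radius — anatomical-relief scale); `face_like` adds fixed nose/brow/mouth
bumps and names 19 landmark vertices mirroring a standard facial roster
(7 midline, 12 bilateral). Ground-truth warps are sums of Gaussian RBFs
(default length scale 40 mm) with coefficients scaled to a prescribed peak
displacement; because the registration's smoothness prior is Gaussian
convolution, these warps are representable and recovery error measures the
algorithm, not model mismatch. `degrade_scan` grows disk-shaped hole
patches to a target face fraction, adds i.i.d. Gaussian vertex jitter, and
pushes chosen vertices outward along their normals to create spikes and
oversized triangles.

The simulated landmark study is a balanced crossed design,
`configuration(ind, obs, iter) = base + individual + observer +
individual×observer + iteration noise`, each effect i.i.d. Gaussian per
landmark coordinate. Defaults mirror a two-observer, three-iteration
study of 41 individuals with 19 landmarks: σ_individual = 3 mm (biological
shape variation), σ_observer = 0.5 mm (systematic placement bias),
σ_interaction = 0.2 mm, σ_iteration = 0.4 mm (digitizing repeat noise, the
magnitude typical of careful facial landmarking). Expected sequential-SS
fractions for this design follow the standard balanced-ANOVA expectations
(e.g. E[SS_individual] = (n_i−1)(n_o·n_it·σ²_ind + σ²_iter)), which is the
oracle the variance-recovery checks use.

What the fixtures do *not* emulate: scanner noise correlated along stripes,
texture-guided manual landmarking (the reason some real landmarks are
easier for humans than for geometry-only registration), expression
variation, and re-triangulated (non-shared-topology) targets. Passing
tests therefore demonstrate algorithmic correctness and robustness to the
modeled artifact classes, not end-to-end accuracy on clinical scans.

## Problem sizes and numerical choices

Registration checks run on 642–2562-vertex spheres (the full pipeline in
seconds), landmark studies on 10–41 simulated specimens; these sizes were
chosen so every property that should hold at scale is already measurable
at them. Degenerate inputs are handled explicitly rather than by NaN:
zero-area normal umbrellas give zero normals and a flag; coincident
reference points give uniform affinities; all-zero residuals give unit
inlier weights; a saturated ANOVA model reports zero residual SS and
infinite F; zero-variance ICC tables return 1 when literally identical and
raise otherwise. Rank-deficient designs and collinear similarity-fit
support raise errors naming the defect.

## Known limitations

- Correspondence is purely geometric; no texture or curvature features, so
  landmarks that humans place by color contrast are predicted only as well
  as geometry allows.
- Smoothing neighborhoods are Euclidean k-NN, not geodesic: across narrow
  gaps (nostrils, lips) motion can leak between anatomically distant
  regions.
- The permutation ANOVA caches projection bases, costing O(n²) memory per
  term — fine for landmark studies (n ≤ a few hundred configurations), not
  for thousands.
- PLY support is read-only; OBJ is the canonical interchange format.
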