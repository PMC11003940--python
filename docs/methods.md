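# Methods

This note records the models, parameter choices and numerical decisions
behind `facedissect`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic data does and does not
emulate.

## The synthetic face population

**Template.** The face is a procedural height field over an elliptical
domain (half-axes 85 × 100 mm, dome height 55 mm) with a Gaussian nose
ridge and tip bump, two eye depressions and a mouth groove, triangulated on
a regular grid. The grid is symmetric about the midline, so the eight
bilateral landmark pairs mirror exactly in x. The `resolution` parameter is
the grid sampling per axis; the default (81) yields ≈ 4700 vertices,
echoing the vertex scale of a decimated clinical scan, and coarser
templates (31–41) are used in tests where mesh resolution is not the
quantity under study. Landmarks are snapped to the nearest template vertex
at 26 named feature positions.

**Population model.** An individual's true landmarks are

    template + region offset + age drift + sex offset + ε,   ε ~ N(0, σ_ind² I)

with two landmarking replicates each adding independent N(0, σ_meas²)
noise (optionally per-landmark, to mimic the fact that some landmarks, e.g.
zygion, are much harder to place than others). Defaults: σ_ind = 1 mm,
σ_meas = 0.5 mm, region offsets of ±1.0–1.5 mm on nose projection, nose
width, face width and chin height, strictly monotone from north to south;
a small linear age drift (−0.02 to −0.03 mm/yr on chin and nose tip) and a
0.6 mm sex effect on face width give the covariate-adjustment code real
signal to remove. The source study reports only significance levels, not
effect sizes, so these magnitudes are free parameters of the generator:
they are chosen once to be of the order of plausible soft-tissue
differences (a millimetre against a millimetre of individual variation)
and are documented rather than fitted. Ages are N(49, 12.7²) clipped to
17–83; sexes are balanced Bernoulli draws.

**Mesh warp.** Each individual's surface is the template deformed by radial-
basis interpolation of the 26 landmark displacements. The kernel is the
Wendland C² compactly supported RBF with support 2.5 × bandwidth
(default bandwidth 30 mm): exact at the landmarks, smooth, and identically
zero far from any landmark. A globally supported (Gaussian) kernel at this
bandwidth makes the interpolation matrix badly conditioned for closely
spaced landmarks (alare/subalare are ~7 mm apart) and the resulting
coefficients ring at long range, violating the locality the warp is meant
to provide; the compact kernel keeps the condition number in the hundreds.

**What the generator does not emulate.** No texture, asymmetry of real
faces, non-Gaussian shape variation, registration error of dense
correspondence, or realistic Han Chinese facial statistics. Passing tests
therefore demonstrate the *statistical machinery* (calibration, recovery of
planted structure, geometric correctness), not anthropometric realism.

## Alignment and reliability

GPA follows the standard Gower scheme: center every configuration, rotate
each onto the current consensus with the Kabsch SVD solution constrained to
det(R) = +1 (faces must never mirror), update the consensus to the mean,
and iterate until the consensus RMS change is below 1e-8 mm (max 100
iterations; consensus initialized from the first configuration). Scaling is
deliberately not removed, so centroid sizes — absolute facial dimensions —
survive alignment.

Replicate reproducibility is the SD across individuals of the signed
replicate difference per landmark × axis, computed in the raw pre-alignment
frame (landmarking happens before alignment); coordinates with SD ≤ 1 mm
are classed moderate-or-high. Under the generator, the difference of two
independent N(0, σ²) errors has SD σ√2, which the tests verify. ICC uses
the two-way mixed-effects consistency form: ICC(3,1) =
(MS_S − MS_E)/(MS_S + (k−1)MS_E) and ICC(3,k) = (MS_S − MS_E)/MS_S, with
exact F-bound 95% confidence intervals; pingouin serves as an independent
oracle in the tests.

## Landmark phenotypes

* **Geodesics.** Fast marching solves |∇U| = 1 over the triangulation. The
  per-triangle update assumes a planar unit-gradient front, solves the
  resulting quadratic for the arrival time, and accepts the root only when
  the characteristic passes through the triangle interior (both barycentric
  gradient coefficients non-positive); otherwise the one-sided edge update
  applies. Obtuse corners simply fail the interior test and fall back to
  edge updates — a slight overestimate, negligible on the near-uniform
  acute triangulations this package produces (icosphere quarter-arc error
  ≈ 1.3%, flat-grid error ≈ 0.2%); meshes with many obtuse triangles would
  need the unfolding refinement. Landmarks snap to the nearest vertex
  within 2 mm. An edge-graph Dijkstra is kept in the tests as an upper
  bound oracle, never as the production path.
* **Curvature.** A quadric (Monge patch) is fitted by least squares to the
  mesh vertices within 10 mm (≥ 6 neighbours required), in a tangent frame
  from the local covariance; principal curvatures are the eigenvalues of
  the shape operator, with normals oriented away from the mesh centroid so
  convex regions (nose tip) get positive mean curvature. Curvatures are
  computed on the surface as-is; no smoothing is applied by default.
* **Manhattan distances** are axis-dependent and therefore defined in the
  GPA consensus frame, which fixes the axes deterministically. All other
  families are rigid-motion invariant (verified to 1e-6 relative).
* **Proportion indices** are always the smaller distance as a percentage of
  the larger, hence in (0, 100]. The shipped battery of 32 indices and the
  10 hull regions are documented stand-ins assembled from standard facial
  indices; studies with their own definitions can substitute both.
* **Angles** emit all three vertex angles per unordered triple in vertex
  index order (3·C(26,3) = 7800); Heron areas clamp a negative radicand
  (collinear triple, rounding) to zero and are cross-checked against the
  cross-product formula.

## Facial segmentation

Vertex similarity is the RV coefficient between the n×3 displacement
matrices of two template vertices across the sample — the natural
generalization of squared correlation to 3D displacement blocks, in [0, 1].
Splits use the symmetric normalized Laplacian: the sign pattern of the
Fiedler vector partitions the segment, zero entries join the smaller side,
and a degenerate eigenvector falls back to a median split. Run to 7 levels
this yields 127 segments whenever no branch hits the minimum-size guard
(default 10 vertices; disabled where the exact 2^L − 1 count is the point).
Segmentation presumes template correspondence (equal vertex count and
order); for external data, dense registration is a declared prerequisite,
not something this package implements.

Per-segment PCA retains components by Horn's parallel analysis: eigenvalues
must exceed the 95th percentile of matching-rank eigenvalues from 100
column-permuted null datasets (seeded; ≥ 20 permutations enforced).
Retention stops at the first failure, and score signs are fixed by making
each component's largest-magnitude loading positive, so results are
bit-reproducible from (data, seed).

Segment surface areas assign each face to the segment holding the majority
(≥ 2) of its vertices. Faces whose three vertices fall in three different
segments are dropped, so per-level totals undercount slightly; the loss is
a boundary-band effect that shrinks with mesh resolution (≤ 2% while
segments stay much larger than the edge length, ~8% for ~18-vertex segments
on a 1200-vertex test mesh). Moran's I uses k = 8 nearest-neighbour weights
on the (x, y) vertex locations, symmetrized and row-standardized — the
classical formulation leaves w_ij open, so both k and the standardization
are configurable. The permutation-null mean −1/(n−1) and the
affine-invariance of I are property-tested.

## Population statistics

* **Screen.** Regions are coded ordinally by latitude (north=1, central=2,
  south=3) and each phenotype is Spearman-correlated with the code
  (average-rank ties, two-sided t-approximation — adequate at the battery's
  sample sizes; a Kruskal–Wallis mode treats regions as unordered).
  Significance uses the Bonferroni threshold α/P over the P phenotypes
  actually screened; significant phenotypes are *heterogeneous*, the rest
  *homogeneous*. Family-wise error and power are verified by simulation
  with planted truth.
* **PLS-DA.** NIPALS PLS2 on autoscaled X against the centered one-hot
  label matrix. The component count grows while cross-validated Q² gains at
  least 0.01 (7 folds, seeded shuffle) — a documented interpretation, since
  the commercial tool that popularized the workflow does not publish its
  rule. VIP_j = √(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a); ΣVIP² = p is an
  algebraic identity asserted for every fitted model, and VIP > 1 is the
  conventional selection rule.
* **PERMANOVA.** Sums of squares partitioned from pairwise distances
  (default: Euclidean on standardized phenotypes), pseudo-F =
  (SS_B/df_B)/(SS_W/df_W), p = (1 + #{F_π ≥ F})/(1 + n_π) with 999 seeded
  permutations by default. The univariate Euclidean case reduces exactly to
  one-way ANOVA R², and scikit-bio's implementation is the cross-check.
* **χ²** uses no continuity correction (the design-balance table is 3×2).
* **Age adjustment** replaces each phenotype by its least-squares residual
  on age plus the phenotype mean; it is exactly orthogonal to age and
  idempotent.

## Problem sizes and determinism

Tests and the acceptance script run on reduced problem sizes chosen so that
each property is tested at the scale where it is meaningful: coarse
templates (31–41 grid, ~700–1200 vertices) for segmentation and pipeline
runs, the default template for vertex-count and symmetry contracts,
n = 60–300 individuals for calibration and recovery experiments, and
200-replicate simulations for type-I error and null-uniformity checks.
Every stochastic stage takes an explicit seed and is bit-reproducible from
(configuration, seed).

## Known limitations

* Dense correspondence is assumed, not computed; real scan data must be
  registered to the template externally.
* The fast-marching solver is first order and uses edge fallbacks at
  obtuse corners; expect ~1–2% geodesic error at the default resolutions.
* Segment surface areas inherit the majority-rule boundary band described
  above.
* The landmark dictionary, proportion-index battery and hull regions are
  serviceable defaults, not a claim about any particular study's
  supplementary definitions.
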