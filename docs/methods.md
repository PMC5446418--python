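# Methods

## Model and procedure

`scalehub` treats hub detection in structural connectomes as an estimation
problem over nodal scales.  The observed data are per-subject streamline
endpoint pairs on a shared template surface with a spherical
parameterization.  The pipeline estimates, per nodal scale K:

1. **Node definition.** The template sphere is partitioned into K
   similar-size parcels by k-means on the 3D Euclidean distances between
   unit-sphere vertex coordinates.  Because node placement at a given K is
   arbitrary, the partition is redrawn R times with independent seeds and
   all downstream nodal maps are averaged over repeats.
2. **Network construction.** Each streamline endpoint is assigned to the
   parcel of its nearest template vertex (endpoints farther than a snap
   tolerance from any vertex are discarded).  Two parcels are connected
   when at least `min_fibers` streamlines terminate with one endpoint in
   each; the edge weight is the raw fiber count.  Intra-parcel streamlines
   never form edges.
3. **Hubness.** Nodal betweenness centrality is computed with exact
   geodesic-count accounting on inverse-weight edge lengths; each repeat's
   map is z-normalized, projected piecewise-constantly to the surface,
   averaged over repeats, and smoothed with a surface diffusion kernel.
   The group map X_K is the mean of the subjects' z-normalized maps.
4. **Scale integration.** H_IS_ST is the pointwise mean of X_K over the
   scale set; H_IS_SC is its z-score.  Hubs are vertices strictly above
   mean + `threshold_sd`·SD (population SD), per scale and integrated.
5. **Validation.** Per scale, single-scale hubs split into those confirmed
   by the integrated hub set and those not; a two-sample t-test compares
   nodal local efficiency (mean inverse geodesic distance to all other
   nodes, averaged over repeats and subjects and projected to the surface)
   between the two groups, with a Kolmogorov–Smirnov normality check.

The model assumes a single shared template (cross-subject surface
registration is the identity), symmetric nonnegative fiber-count weights,
and that stronger connections are functionally "shorter" (inverse-weight
metric).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `scales` | 100..600 step 100 | nodal scales integrated; the reference protocol's range, spanning coarse atlases to fine random parcellations |
| `n_repeats` | 20 | random parcellations per scale; averages out node-placement bias |
| `min_fibers` | 3 | streamline support required for an edge; suppresses spurious connections of deterministic tractography |
| `fwhm_mm` | 20 | surface smoothing of subject hub maps; reduces inter-subject spatial variability |
| `threshold_sd` | 1 | hub cut in SD units above the map mean; the conventional hub definition |
| `snap_tolerance_mm` | 2 | max endpoint-to-vertex distance; generous for vertex-snapped synthetic endpoints, leaves slack for real data |

The demonstration and acceptance runs use a scaled-down configuration —
icosphere(4) template (2,562 vertices vs ~84k in a full cortical model),
scales {50, 100, 150} with 5 repeats, 10 subjects × 20,000 tracts — chosen
so a complete multi-seed study runs in minutes on one CPU while keeping
roughly the full protocol's ratio of vertices per parcel at the coarse end.

## Synthetic cohort generator

The generator plants a known hub architecture so recovery is testable:

* **Modules**: Voronoi cells of farthest-point-sampled seed vertices on the
  sphere (default 4), mimicking large-scale modular wiring.
* **Connectors**: one spatially contiguous cap per adjacent module pair,
  centered on the boundary, jointly covering `connector_fraction` (default
  0.12) of vertices.  Inter-module fibers terminate inside a connector cap
  with probability `p_connector_route` (default 0.75); the remainder run
  direct.  Concentrating inter-module traffic on small caps gives connector
  parcels elevated betweenness at every nodal scale — the scale-stable hub
  ground truth.  Direct inter-module fibers spread over many parcel pairs
  and are largely removed by the 3-fiber edge threshold, which mirrors how
  sparse spurious connections behave in real count matrices.
* **Fiber mixture**: `short_fiber_rate` (default 0.30) of streamlines are
  U-fibers (endpoints within 12 mm, lengths uniform on [20, 30) mm); long
  fibers split evenly between intra- and inter-module, lengths lognormal
  clipped to [30, 200] mm.  The 20 and 200 mm limits mirror standard
  tractography termination bounds; the 30 mm boundary separates the two
  pools so that a zero short-fiber rate implies no sub-30 mm streamline.
  Only endpoint positions and a length scalar enter the framework, so
  streamline geometry is not traced.
* **Subjects** (default 10, 20,000 tracts each) share the architecture and
  differ by sampling noise; per-subject seeds derive from the master seed
  through numpy's SeedSequence keyed on the subject index.

What the generator does **not** emulate: folded cortical geometry and
registration error, distance-dependent tractography biases (gyral bias,
crossing fibers), graded module membership, hemispheric asymmetries, and
subject-level architecture variability.  Passing the recovery tests
therefore shows the estimator is correct and well-calibrated under the
assumed generative structure, not that it is robust to real acquisition
confounds.

## Numerical choices

* **Smoothing** is an explicit graph-heat iteration
  `x ← x − (λ/d_max)·L·x` with λ = 0.5 and L the combinatorial Laplacian.
  The operator is symmetric, so the map mean is preserved exactly and the
  spectrum lies in [0, 1] (variance never increases; isolated vertices are
  fixed points).  The iteration count is calibrated from the heat-equation
  diffusion time t = FWHM²/(16 ln 2) via m·λ·h² ≈ 2t (h = mean edge
  length).  The kernel is convention-dependent; exactness is unnecessary
  because downstream z-scoring absorbs the scale.
* **k-means** uses farthest-point initialization (near-equal-area seeds),
  assignment ties to the lowest centroid index, empty clusters reseeded to
  the vertex farthest from its assigned centroid, and convergence when no
  label changes (cap 300 iterations).  Because plain Lloyd leaves
  singleton parcels once parcels shrink to a few vertices, a deterministic
  equalization pass follows: the smallest parcel repeatedly absorbs the
  boundary vertex nearest its centroid from a meaningfully larger parcel
  until the max/min size ratio falls to 3.  This trades strict Voronoi
  optimality for the similar-size requirement while preserving contiguity.
* **Betweenness** uses Brandes' algorithm (networkx) with edge lengths
  `w_max/w`: dividing by the maximum weight instead of 1 keeps the metric
  identical up to a constant while making edge lengths bit-identical under
  uniform rescaling of all fiber counts, so geodesic ties cannot flip with
  the units of the weights.  Unordered-pair summation without the
  (n−1)(n−2) constant; disconnected pairs contribute zero.  Tests verify
  that the ordered-pair convention and the sample-vs-population SD choice
  leave the final z-maps unchanged.
* **Normalization** uses population SD throughout; per-repeat nodal maps
  are z-normalized before projection (a switch selects per-subject-map
  normalization instead), and the group map z-normalizes at vertex level.
  Constant maps are rejected with an explicit degenerate-map error;
  repeats with constant BC are skipped with a warning.
* **Hub threshold** is a strict inequality at mean + k·SD; a constant map
  yields an empty hub set.
* **Endpoint snapping** breaks exact nearest-vertex ties toward the lower
  vertex index.
* **KS normality** defaults to the naive estimated-parameter test (the
  conventional software behavior); a Lilliefors-corrected variant is
  available because the naive test is anticonservative.
* **Efficiency contrast** treats nodes (vertices carrying group-averaged
  efficiency) as the unit of observation, matching a per-scale regional
  comparison; pooled-variance Student's t is the default with Welch
  optional.  Groups under 2 members are flagged untestable rather than
  tested.

## Design choices where the design was open

* The short-association ratio needed an operational definition: it counts
  (a) parcels whose intra-parcel streamline support reaches the edge
  threshold and (b) supra-threshold inter-parcel connections with median
  streamline length under 30 mm, against the K(K−1)/2 possible
  connections.  This reproduces the qualitative behavior (the ratio falls
  steadily as K grows) rather than any particular printed magnitude.
* A bundled published hub table is used as an internal-consistency check:
  its strength and score columns must be related by one affine (z-score)
  transform.  Fitting the transform from two anchor rows reproduces the
  other scores to ≲5·10⁻⁷ relative error, except one row whose printed
  score deviates by 0.088 — exactly a transposed-digit variant of the
  predicted value — which is treated as a typographical error and excluded.
* Hemispheres are tagged per vertex and parcellated jointly on the
  synthetic single-sphere template; a per-hemisphere mode is available via
  the tag.

## Known limitations

* Hub maps are convention-dependent (smoothing kernel construction,
  inverse-weight metric); comparisons across software should re-derive
  maps under one convention.
* The vertex-level efficiency contrast inherits within-parcel value
  duplication from piecewise-constant projection, inflating its nominal
  degrees of freedom; it is used directionally, not for calibrated
  inference.
* No streamline filtering, length/volume weighting, or probabilistic
  tractography support; weights are raw counts by design.
* Alternative centralities (degree, closeness, eigenvector) are out of
  scope; betweenness is the implemented hub statistic.
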