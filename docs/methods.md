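# Methods

## Pipeline model and assumptions

The pipeline assumes a co-registered pair of grids: an 8-bit power-Doppler
(PD) magnitude volume and a binary region mask representing the manually
segmented placental region (decidua + placenta, embryo and myometrium
removed).  Voxel spacing in mm is required metadata — scanners differ and no
default is defensible; readers error if it is absent and no override is
given.  All grids use a fixed (z, y, x) axis order, 0-based indices, and
voxel-centre physical coordinates, so a volume and its mask always traverse
identically regardless of on-disk format (NIfTI, multi-page TIFF, MetaImage).

**Thresholding.**  A voxel enters the vascular volume iff intensity ≥ τ
(default τ = 100 of 255) and the mask is set.  The comparison is inclusive by
default because the operative definition of the included voxels is the
intensity band from the threshold to 255; an exclusive switch
(`threshold_inclusive = false`) is provided since strict-inequality wording
also circulates for the same protocol.  No component filtering or despeckling
is applied by default — artefact removal in the source protocol is manual —
but `min_component_voxels` exists for phantom experiments.  uPVV (cm³) is
exactly voxel count × voxel volume / 1000, so it inherits rasterization
error but no model error.

**Skeletonization.**  Thinning uses the 3D medial-axis algorithm of
scikit-image (`skimage.morphology.skeletonize`, the Lee 6-subiteration
simple-point family): 26-connected foreground, 6-connected background,
topology-preserving, idempotent on thin inputs.  The downstream measures
depend only on these properties, not on the particular peeling schedule, so
any compliant thinning would do.  Connectivity decisions are made on the
voxel grid (metric-free); spacing enters only through distances.

**Local radius.**  "Layers peeled to reach the centre" is implemented as the
Euclidean distance transform of the selection sampled at skeleton voxels
(mm to nearest background voxel).  Iteration counts depend on anisotropy and
peel schedule; the EDT is the rotation-robust estimator of the same quantity.
A `peel_iterations` mode (chessboard chamfer distance, i.e. 26-neighbourhood
peel counts, converted to mm via the mean neighbour distance) is available
for comparison with iteration-counting implementations.  By either
convention a one-voxel-wide line has radius one voxel unit.

**Classification.**  Neighbour counts are taken over the full thinned
skeleton, before exclusions.  Excluded classes — isolated voxels (0
neighbours) and clusters (≥ 5 neighbours, the residue of hollow signal that
a topology-preserving thinning cannot reduce to a curve) — are then removed
from the traversal graph; segments terminate where a path meets a cluster
rather than connecting through noise.  A voxel with exactly 4 neighbours is
always a crossing point: the class is defined by neighbour count alone, and
no geometric test distinguishes a true 4-way crossing from two tangent
vessels.

**Segments and lengths.**  Segments are maximal vessel-point chains; within
the vessel-point subgraph every voxel has degree ≤ 2, so components are
paths or cycles.  A direct adjacency between two non-vessel nodes is a
segment with zero interior vessel points and is included in the
average-length mean.  A pure vessel-point cycle (anastomotic loop) counts as
one closed segment with interior = component size; loops are anatomically
expected and must not be dropped.  Total network length uses the literal
voxel-count formula (included voxels × mean neighbour distance d̄).  On a
single chain this overestimates the edge-path length by one step (n voxels
vs n−1 steps); on straight-tube phantoms the ratio to true centreline length
stays within [0.9, 1.3].  An `edge_sum` mode sums true centre-to-centre
distances over adjacent included pairs for users who prefer geometric
length.  d̄ is computed per scan from the skeleton itself; for a skeleton
with no adjacent pair it is undefined and the mean face-neighbour spacing is
returned with a warning.  Average thickness averages the per-voxel radius
over all included skeleton voxels (per-voxel, not per-segment, averaging —
the closest reading of a mean over peeled layers).

**Degenerate inputs.**  Empty selection → empty skeleton, zero counts, zero
total length; means over empty sets (average vessel length with no segments,
thickness with all voxels excluded) are NaN with a warning, never silently 0.
Zero-denominator density ratios are NaN and flagged (`pv_defined`,
`upvv_defined`).  All sums and means are order-independent, so results do
not depend on enumeration order.

## Phantoms

Phantoms are unions of capsules (segments with radius, in voxels) on the
grid; a voxel is vessel iff its centre lies within radius of an edge.
Capsule rasterization (rather than 1-voxel lines) makes tube thickness
well-defined, matching the EDT radius estimator.  Ground truth — endpoint
(degree-1), bifurcation (degree-3) and crossing (degree-4) counts, exact
polyline length, component count — always comes from the node/edge graph,
never from the voxelization.

**Clean-junction family.**  Whether a thick Y-junction thins to exactly one
3-neighbour voxel depends on its digital geometry: oblique junctions can
smear a bifurcation over two or three adjacent voxels (each then counting 3
neighbours), exactly as in clinical data.  For exact-recovery validation the
random-tree generator therefore restricts itself to a documented family:
integer lattice nodes, arms along axis/face-diagonal unit steps, and
bifurcation direction triples drawn from a frozen catalogue of the 96 (out
of 216 candidate) triples that provably thin to a single 3-neighbour voxel,
stable across arm lengths 10–16 steps at radius 3
(`upvs/_junction_catalog.py`, regenerable with
`scripts/derive_clean_junctions.py`).  Arms additionally keep a clearance of
2·radius + 4 voxels between non-incident edges.  Within this family,
endpoint and bifurcation counts are recovered exactly (verified over 60
random 5-bifurcation trees); outside it the method still works but junction
voxel counts may exceed graph truth, which is a property of digital
skeletons generally, not of this implementation.

**Artefacts** emulate the three noise phenomena relevant downstream:
one-voxel-thick supra-threshold stripe planes, hollow spherical shells
(which thinning cannot collapse, leaving cluster voxels), and isolated
supra-threshold voxels placed with one-voxel clearance so they survive as
single skeleton voxels.  All randomness flows through one seeded generator.

## Synthetic cohorts

`synth_cohort` emulates the longitudinal study design this method is used
in: default 214 subjects, scheduled visits at 7/9/11 weeks gestational age
with attendance probabilities 0.44/0.80/0.60 (reproducing per-week sample
sizes near 94/170/129), complication prevalence 0.252, covariate prevalences
(nulliparity 0.57, IVF/ICSI 0.407, male foetus 0.495) matching the cohort
the design is modelled on.  Each quantity follows a quadratic-in-GA median
trajectory through anchor values at 7/9/11 weeks; characteristic anchors
were derived from typical density-ratio levels (per cm³ uPVV) multiplied by
uPVV anchors of 0.5/1.5/3.0 cm³, with PV anchors 10/30/60 cm³ — realistic
first-trimester values chosen once.  Noise is multiplicative log-normal
(characteristics are positive and right-skewed): a subject-level random
intercept (sd 0.30 on the log scale) shared across visits plus per-visit
noise (sd 0.25).  Complicated pregnancies scale characteristics by 0.9 and
uPVV by 0.8 (PV by 0.85): modest characteristic reductions with a stronger
volume reduction, so density ratios are *higher* in the complicated stratum,
the pattern seen clinically.  GA jitters uniformly ±0.5 week around the
scheduled visit.

What the generator does **not** emulate: speckle and attenuation physics,
spatial correlation between characteristics of one scan beyond the shared
intercept, visit-level dropout correlated with outcome, and measurement
error correlated with image quality.  Tests passing on these cohorts
validate the statistics pipeline's correctness and calibration, not clinical
effect sizes.

`simulate_lmm_cohort` generates data exactly from the additive-Gaussian
mixed model (y = β₀ + β₁·GA + β₂·GA² + group block + subject intercept +
residual) and exists so that mixed-model recovery and type-I-error checks
test the estimator against its own generating process; using the log-normal
cohort there would confound estimator calibration with deliberate model
misspecification.

## Statistics

* Spearman correlations use midranks for ties; for n ≤ 8 the p-value is an
  exact permutation enumeration, otherwise the t-approximation.
* PCA standardizes the seven characteristics first (counts and lengths
  differ by orders of magnitude; covariance PCA would trivially load on the
  vessel-point count) — i.e. correlation-matrix PCA.  Components are
  sign-fixed (largest-magnitude loading positive); explained-variance
  fractions sum to 1; zero-variance columns are dropped with a warning.
* Mann–Whitney U is exact for combined n ≤ 20 without ties; otherwise the
  normal approximation with tie and continuity corrections.
* Mixed models are fitted by maximum likelihood (not REML) so nested models
  are comparable: the covariate block (main effect + GA and GA²
  interactions, 3 df) is tested with a likelihood-ratio χ² test.
  Non-convergence is reported via the `converged` flag.
* Visits map to the nearest scheduled week within ±1 week; others are
  excluded from per-week comparisons.
* No multiplicity correction by default (per-comparison α = 0.05);
  Benjamini–Hochberg is available via `adjust=True`.

## Validation scale choices

The acceptance run uses 100 random ≤ 20³ grids for the classification
oracle, 5 random clean trees, tube radii {2, 3, 5}, all 66 group-size
partitions with combined n ≤ 12 for Mann–Whitney exactness, and 200
replicates of 200 subjects × 3 visits for mixed-model coverage and type-I
error — sizes at which every check is stable across seeds while the whole
suite completes in minutes on one CPU.

## Known limitations

* Exact junction-count recovery is guaranteed only on the documented
  clean-phantom family; digital skeletons of oblique thick junctions can
  legitimately carry more than one branching voxel per anatomical
  bifurcation.
* The voxel-count total-length formula overestimates per-chain by one step;
  use `length_mode="edge_sum"` when geometric length matters.
* Radius near tube ends is biased low (the EDT sees the cap); thickness
  validation excludes voxels within one radius of the ends, but real
  network-wide averages include such voxels at every endpoint.
* The classifier cannot separate two tangent vessels from a true crossing
  (both are 4-neighbour voxels), and maternal vs embryonic vessels are not
  distinguishable from PD magnitude at all.
* GE Kretz `.vol` files are not parsed; convert/export to NIfTI, TIFF or
  MetaImage first.  4D (time-resolved) data, resampling and registration are
  out of scope.
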