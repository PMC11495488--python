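# Methods

`trabkit` quantifies trabecular (cancellous) bone architecture in the
articular head of long-limb bones and analyses how that architecture changes
across an ontogenetic series. The pipeline has four stages — standardized
orientation, spherical ROI extraction with Otsu segmentation, voxel
morphometry with a mean-intercept-length (MIL) fabric tensor, and
cohort-level statistics — plus a synthetic generator that supplies phantoms
and cohorts with known ground truth in place of µCT scan data.

## Coordinate and unit conventions

Volumes are `(slice, row, column)` arrays mapping to world `(Z, Y, X)`;
voxels are isotropic with edge length in µm (scan-realistic range ~24–47 µm,
any positive size accepted). Thickness and spacing are reported in mm;
trabecular number in mm⁻¹. The standard anatomical frame puts the
metaphysis axis on +Z (proximal up), the lateral head–neck contact chord on
±Y, and the articular surface toward −X. Fabric axes are sign-free; the
canonical representative has Z ≥ 0, plunge is the elevation above the X–Y
plane in [0, 90]°, azimuth is measured from +X toward +Y in [0, 360)°. (The
upper-hemisphere representative is chosen so that, e.g., the axis
(1, 1, √2)/2 reports azimuth 45°; the lower-hemisphere mirror would report
225°, an axially identical orientation, and the equal-area projection is
unaffected.)

## Synthetic generators

**Rod phantoms.** Binary lattices of cylindrical struts of fixed radius.
Strut axes follow a von Mises–Fisher distribution around a mean axis with
concentration κ (κ = 0 isotropic; κ → ∞ parallel); positions follow a
*stationary line process*: for each strut the perpendicular-plane offset is
drawn uniformly from a disk covering the grid's projection, which makes
foreground density spatially homogeneous. (Anchoring lines at points
uniform inside the box — the obvious alternative — over-weights the grid
center through chord-length bias; we measured up to +0.07 BV/TV excess in a
central ROI at 50% density before adopting the stationary form.) Struts are
added until the grid foreground fraction is within ±0.02 of the target;
exact targeting is ill-posed on a discrete grid, and a single strut that
overshoots the band raises an error rather than clipping silently. The
ground-truth report (achieved BV/TV, strut radius, drawn axes) always
equals a direct voxel recount.

Finite phantoms are only *statistically* isotropic: n randomly oriented
struts carry a quadrupole fluctuation of order 1/√n in their axis
second-moment, which appears as genuine fabric anisotropy of roughly the
same size. At 128³ with radius-5 struts a 20%-density lattice holds only
~65 struts and its intrinsic DA sits near 0.10; isotropy checks tighter
than that need thinner or denser struts (≳150 struts keeps intrinsic DA
safely below 0.1).

**Whole-bone mocks.** A sphere-capped shaft: spherical head of outer radius
R with a solid cortical shell, rod-phantom interior, optional growth-plate
slab, and a hollow cylindrical shaft, rendered to 8-bit grayscale (bone
200, background 40) with additive Gaussian noise specified as a fraction of
that class separation. The label volume (0 background / 1 trabecular / 2
cortical) and five landmarks (metaphysis midpoints, two lateral contacts,
one articular-surface point) are returned alongside.

**Cohorts.** One row per specimen × element for five age groups of sizes
13/11/10/7/14. Each metric is drawn log-normally with the group mean and
coefficient of variation taken from the reference ontogenetic tables
(means in cm for thickness/spacing as published, converted to mm); a
normal-noise alternative sits behind a switch. All metrics are strictly
positive, which is what motivates the log-normal default. Group-level
log body mass and the orientation concentrations are free parameters (the
reference tables do not print them): logBM rises 0.15 → 1.02 with CVs
30% → 6%, and plunge means rise from ~15° (2 months, azimuth concentrated
along the anterior/posterior axis, von Mises κ = 4) to ~80° in adults with
the femur lagging the humerus by one age class — the qualitative pattern
the cohort is meant to emulate. The generator reproduces group means,
dispersions and sample sizes; it does not model within-specimen correlation
between metrics beyond the shared body-mass draw, measurement error, or
left/right asymmetry, so passing cohort tests demonstrates the statistics
stage, not biological realism.

## Orientation

Alignment is landmark-driven (landmarks are inputs; automated anatomical
landmarking is out of scope). The rotation maps the distal→proximal
metaphysis axis to +Z and the lateral chord, orthogonalized against Z, to
±Y; `lateral_contact_a − lateral_contact_b` defines the provisional +Y and
the X/Y pair is flipped together (keeping det = +1) if the articular point
would otherwise land at positive X. Resampling uses nearest-neighbour (or
trilinear for grayscale; refused for binary input) on the axis-aligned
bounding box of the transformed corners with a 2-voxel pad (pad exposed;
near-integer bounds are snapped so exact 90° turns and the identity
reproduce the input grid). Mirroring of left elements is an X-axis flip
in-grid. Rigid motion conserves binary foreground counts to well under 5%.

## ROI and segmentation

The interior box ray-marches from the head center along the six axis
directions to the innermost cortical voxel (the published procedure placed
this box interactively; the ray-march is the deterministic
operationalization). The spherical ROI is centered on the box and its
radius is the exact Euclidean distance from that (possibly half-voxel)
center to the nearest cortical voxel minus one voxel — the margin keeps
cortex strictly excluded under discrete sampling — capped to stay inside
the grid; radii under 3 voxels are refused. Otsu's threshold maximizes
between-class variance on the ROI-only histogram (256 bins for 8-bit input,
native integer bins otherwise) with ties broken at the midpoint of the
maximizing range; voxels strictly above the threshold are bone. `purify`
keeps the largest 26-connected bone component and fills 6-connected marrow
cavities sealed off from the ROI border (the standard foreground/background
connectivity duality), and is idempotent. For synthetic rod lattices the
measurement protocol skips purification: sphere clipping legitimately
disconnects struts, and keep-largest would erase a parallel-strut phantom.

## Morphometry

**BV/TV** is the voxel count ratio inside the sphere.

**MIL fabric.** Directions are a golden-spiral lattice on the hemisphere
(quasi-uniform), rotated by a seeded random rotation; 512 directions by
default (≥ 64 enforced). For each direction, parallel test lines at
2-voxel spacing are swept through the sphere and sampled at 1-voxel steps;
marrow→bone transitions between consecutive in-sphere samples count as
intercepts, and MIL(ω) = total in-sphere line length × BV/TV ÷ intercepts.
The tensor M is the least-squares fit of 1/MIL(n)² = nᵀMn over the sampled
directions; ellipsoid radii are r = 1/√eigenvalue (descending), the primary
axis e₁ belongs to r₁, and DA = 1 − r₃/r₁ ∈ [0, 1) (the bounded-at-one
convention consistent with observed values in the 0.16–0.43 range;
eigenvalue-ratio alternatives are not used). Directions with zero
intercepts raise an error suggesting a larger ROI or coarser spacing. DA
repeatability across direction-lattice seeds is ~0.02 on dense lattices;
on sparse phantoms the spread reflects the phantom's own finite-strut
anisotropy (see above), not estimator noise — sub-voxel jitter and finer
line spacing leave it unchanged.

**TbTh/TbSp.** Model-independent local thickness: the thickness at a voxel
is the diameter of the largest sphere containing it that fits in the
structure, computed by openings over an inscribed-sphere radius ladder
(radii = Euclidean distance transform values floor-quantized at 0.5 voxel;
each rung r paints all voxels within r of centers with EDT ≥ r, ascending
so larger spheres win). Floor quantization matters: rounding up can leave
the top rung without centers so the largest sphere is never painted.
TbTh averages over bone voxels; TbSp applies the same transform to marrow
restricted to the sphere. Accuracy is ±1 voxel on slabs and balls and
~±10% on strut diameters.

**TbN** defaults to the plate model (BV/TV ÷ TbTh); an intercept estimator
(mean intercepts per mm of test line over the MIL directions) is available,
and the method used is stamped into output provenance. The two disagree
systematically on rod-like structures (plate ≈ intercept × ~2 at moderate
density); published per-group values cannot be reconciled exactly with
either formula from group means alone, so the choice is recorded rather
than hidden.

**Azimuth folding.** Before correlation or ordination, azimuth is folded by
||x − 180| − 90| into [0, 90], pairing axially equivalent compass directions
(359° with 1°) and expressing azimuth as position between the
anterior/posterior and medial/lateral planes.

## Cohort statistics

Body mass: logBM = a·log₁₀(circumference) + b with (a, b) mandatory config
— the external scaling equation's coefficients are study-specific and are
never defaulted. CV = 100·sd/mean (sample sd). Correlation matrices are
Pearson by default; a partial mode (−p_ij/√(p_ii·p_jj) from the precision
matrix) is provided because the cited software routine computes partial
correlations and which quantity the published table holds is ambiguous.
PCA is an eigendecomposition of the covariance of centered (optionally
unit-scaled; default raw) columns, with the folded azimuth mandatory in
place of raw azimuth and a deterministic sign convention (largest-magnitude
loading positive). Unit scaling is worth enabling when degree-valued angle
columns would otherwise dominate the raw-value ordination.

Group differences use the tie-corrected Kruskal–Wallis H with a χ²(k−1)
p-value (all-tied input returns H = 0, p = 1); Dunn post-hoc z-statistics
use pooled midranks with tie term Σ(t³−t)/(12(N−1)) and are gated on the
omnibus test at α = 0.05 (adjustment: none by default, matching the cited
post-hoc implementation's default; Bonferroni/Holm available). At the
study's sample size (N = 55, five groups) the χ² approximation is mildly
conservative — long-run null rejection ≈ 0.044–0.048 at α = 0.05, verified
against R's `kruskal.test` — which is inherent to the approximation, not an
implementation artifact.

Allometry: OLS polynomials of degree 1–4 on (logBM, metric), with the
degree chosen by seeded 10-fold cross-validation (lowest mean held-out MSE;
ties resolved to the smallest degree within numerical tolerance so exact
low-degree data never selects a higher degree on round-off). Slope
inference uses the separate linear fit on log₁₀-transformed metrics — the
isometric references are log-log exponents: 0 for the unitless BV/TV and
DA, +1/3 for the linear TbTh and TbSp, −1/3 for TbN — and isometry is
assessed by whether the 95% slope CI covers the reference (a pragmatic
operationalization; no specific test statistic is prescribed by the source
description). Descriptive polynomial curves may be fitted on raw values;
both scales are recorded.

Orientation display uses the Lambert equal-area lower-hemisphere
projection, r = √2·sin((90° − plunge)/2), normalized so horizontal axes lie
on the unit circle and vertical ones at the center; px = r·sin(azimuth),
py = r·cos(azimuth).

## Reproducibility and problem sizes

Every stochastic stage derives its seed from a single global seed plus the
stage name (`derive_seed`, always < 2³¹); identical configuration and seed
give bit-identical phantoms, cohorts, and report JSON. The shipped test
suite and acceptance studies use sizes chosen to exercise the estimators at
realistic resolution while staying desk-scale: 64³ lattice fixtures for
unit tests, a 3×3 recovery grid (BV/TV 0.2/0.35/0.5 × κ 0/5/100) at 128³
with 512 MIL directions, 50-specimen allometry simulations, 30k–100k
replicate null calibrations, and 500-replicate cohort recoveries.

## Known limitations

- Phantoms are rod lattices; plate-like and anatomically realistic
  microarchitecture, and any mechanical (finite-element) validation, are out
  of scope.
- Sparse lattices (≲100 struts) carry intrinsic finite-sample anisotropy
  ~1/√n that no fabric estimator can remove; isotropy validation should use
  dense lattices.
- The χ²-approximate Kruskal–Wallis test is ~0.5pp conservative at N = 55.
- TbN's plate-model and intercept estimators disagree on rod-dominated
  structures; comparisons across studies must match estimators.
- Cohort draws are independent across metrics given body mass; real
  trabecular metrics co-vary more strongly.
- Landmarks are trusted inputs; no automated detection or error model.
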