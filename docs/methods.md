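# Methods

This note documents the measurement models implemented in `awvct`, the
parameters that matter, what the digital phantom does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Coordinate conventions

Volumes are indexed `values[i, j, k]` with x (axis 0) increasing toward the
patient's left, y toward posterior and z toward superior — the patient's
right lung has the smaller x centroid and the trachea enters near the top
slices. This matches DICOM patient coordinates for axial series. Voxel
indices are 0-based; world coordinates are mm (`world = origin +
index·spacing`); volumes are reported in ml (mm³/1000). Masks must match
their CT's geometry to within 10⁻⁴ mm in spacing and 10⁻³ mm in origin.

## Digital chest phantom

The phantom is a validation substrate, not an anatomical model. An airway
tree of straight cylindrical branches (full binary tree; generation *g* has
radius `root_radius·taper^g` and length `branch_length·taper^g`; children
deflect by a fixed angle in a branching plane that rotates 90° per
generation) is voxelized into a grid between two ellipsoidal "lungs".
Default conditions: root radius 4 mm, taper 0.75, branch length 24 mm,
branching angle 35°, 0.5 mm isotropic voxels — sized so that a depth-4 tree
(15 branches, terminal radii ≈ 1.7 mm) fits a 192³ grid, spanning the
central-airway size range where CT measurement is considered reliable.

Attenuation model: lumen −1000 HU, wall 0 HU, normal parenchyma −870 HU,
emphysematous parenchyma −980 HU, extra-pulmonary background +50 HU. These
straddle the −950 HU emphysema threshold so that density masking is
non-trivial. A Gaussian blur in mm (default σ = 0.6 mm) emulates the
scanner point-spread function and optional Gaussian noise (HU) emulates
quantum noise; truth masks are never blurred. Exact-recovery validations
(LAV% equality, Dice, TAC) are run with blur and noise at zero, because a
blurred phantom genuinely changes the measurand: an isolated −980 HU voxel
averaged with −870 HU neighbours rises above −950 HU, so LAV% equality
only holds pre-blur.

Two deliberate geometry choices:

- **Lumen is an exact finite cylinder** (so voxel volume → Σπr²L as spacing
  → 0) while the **wall is a capsule** (rounded ends), sealing bifurcation
  elbows and branch tips.
- **Wall thickness is `0.3·radius` floored at 1.0 mm.** A rasterized shell
  thinner than the voxel diagonal (0.87 mm at 0.5 mm spacing) is not
  watertight under 26-connectivity, and real small airways have
  proportionally thick walls.

Emphysema is placed by seeded sampling of exactly `round(fraction ·
n_parenchyma)` parenchymal voxels (scattered by default; optionally
clustered around seeded centers), giving exact fraction control for LAV%
validation. Same seed ⇒ bit-identical phantom.

What the phantom does **not** emulate: cardiac silhouette and fissures,
curved/tapering-within-branch airways, reconstruction-kernel-specific noise
texture and edge enhancement, respiratory motion, vessels abutting airway
walls. Passing phantom tests therefore demonstrates correctness of the
geometry/counting/measurement machinery, not clinical accuracy on scanner
data.

The cohort simulator draws predictors (AWV%, LAV%, WA%, TAC, age, BMI,
pack-years) from a multivariate normal with configurable means/SDs and
correlation, and generates outcomes (%FEV₁, RV/TLC) as a stated linear
combination of z-scored predictors plus Gaussian noise. Default scales
follow typical male COPD cohorts (age 71 ± 9 yr, BMI 22 ± 3, pack-years
63 ± 35, LAV% 29 ± 9, WA% 58 ± 5, TAC 212 ± 51, %FEV₁ 61 ± 20,
RV/TLC 42 ± 7); the default standardized coefficients are 0.35 (AWV%),
−0.50 (LAV%), −0.26 (WA%), 0.21 (TAC) for %FEV₁ and −0.28/0.24/−0.17/−0.17
for RV/TLC, with noise SD 0.72 giving model R² ≈ 0.5. A CAT symptom score
(0–40, integer) is coupled negatively to %FEV₁ so that roughly 55% of a
default cohort is symptomatic (CAT ≥ 10).

## Airway segmentation

Iterative-threshold region growing: starting from a trachea seed at the
initial threshold (default −960 HU), the connected component containing
the seed is extracted from `HU < T`; `T` is relaxed in steps (default 4 HU)
toward a maximum (default −850 HU). If one step multiplies the region
volume by more than the leakage factor (default 2.0) the region has burst
into the parenchyma and the previous threshold is kept (rollback).
Connectivity is 26 by default; all parameters sit in the `seg` config
block, and the accepted threshold and rollback events are logged and
recorded in the provenance file.

The trachea seed is the most central, near-circular air component
(< −900 HU, mean in-plane area > 20 mm²) in the top 10% of axial slices;
the returned voxel is taken at the component's median slice, away from
blurred end voxels.

The segmented tree is the **air-filled lumen**; walls are never included.
Under PSF blur a fixed sub-air threshold necessarily sits inside the true
boundary, so the blurred-phantom lumen is underestimated (Dice ≈ 0.76 at
σ = 0.6 mm vs ≈ 1.0 unblurred). This is inherent to threshold growing, not
a defect of the implementation; AWV% is a ratio and the bias applies to
every scan equally.

## Skeleton and branch graph

The lumen mask is thinned with topology-preserving 3-D thinning
(scikit-image). One degenerate input exists: a perfectly even-symmetric
axis-aligned cylinder can be annihilated entirely; if thinning empties a
non-empty mask, the mask is nudged with a one-sided one-voxel dilation and
thinning is retried.

Graph construction: skeleton voxels are nodes of a 26-adjacency graph;
voxels of degree ≥ 3 that touch each other are merged into a single
bifurcation node at their centroid; maximal degree-2 chains become
branches with polyline length in mm. The result must be a tree (cycles
raise an error); the root is the most cranial endpoint, branches are
oriented proximal→distal, and generation numbers count bifurcations from
the root (trachea = 0).

Terminal branches shorter than 2 mm (default) are pruned as voxelization
spurs and the adjacent chains re-merged; pruning is idempotent and never
removes the root branch. 2 mm is below any genuine branch length in both
the phantom (terminal branches ≥ 10 mm) and adult central airways.

Lobar partition takes two branch ids as subtree roots (RUL and RMLL);
descendants inclusive get the labels, ancestors are "trachea", the rest
"other". TAC counts RUL + RMLL branches only. On phantoms the two children
of the main bifurcation serve as lobar roots (`"auto"` in the config);
anatomical identification of lobar bronchi on patient scans is out of
scope and the ids must be supplied.

## Airway volume (AWV) and FWHM wall measures

Every lumen voxel is assigned to the branch of its nearest centerline
point (KD-tree in mm space); AWV is the voxel volume of RUL+RMLL-assigned
voxels. Assignment makes subtree volumes exactly additive; the phantom
recovery error (≈ 8% at depth 4) comes from voxelization and from junction
voxels attributed across the trachea/lobe boundary.

Cross-sections are resampled planes (default 0.1 mm pixels) orthogonal to
the centerline tangent, which is taken from a 5-point moving-average
smoothed polyline with a ±2 mm central difference. 64 rays are cast from
the center; per ray:

1. lumen minimum = lowest HU on the inner half of the ray;
2. wall peak = **first** local maximum beyond the minimum with ≥ 150 HU
   contrast over it — deliberately not the global maximum, which can sit in
   the mediastinum or chest wall further out;
3. outer plateau = attenuation floor (median of a small window around the
   first local minimum) within 4 mm beyond the peak — deliberately not a
   "far end of the ray" estimate, which exceeds the wall peak for sections
   near the pleura where rays leave the lung;
4. inner boundary at the first outward crossing of (minimum + peak)/2,
   outer boundary at the crossing of (peak + plateau)/2 beyond the peak.

Rays without a usable peak or plateau are excluded; a section is invalid if
more than 25% of rays fail. Ai is the shoelace area of the inner-boundary
polygon, WA the outer polygon area minus Ai, WA% = 100·WA/(Ai+WA) ∈
[0, 100).

**Known bias.** The half-maximum rule is exact for walls thick relative to
the blur; a thin wall attenuates the peak and pulls the inner boundary into
the lumen, and convex-boundary curvature adds a second inward bias when the
radius approaches the blur width. A 1D edge-profile analysis at σ = 0.6 mm,
wall 1 mm gives ≈ −13% area bias at r = 4 mm, which the implementation
reproduces; at wall ≥ 3 mm the family r = 2–5 mm is recovered within 10%
(−9.9% worst case at r = 2 mm). The test suite asserts both behaviours:
accuracy on thick-walled annuli and a monotone negative bias on
thin-walled/small ones. This mirrors the clinical caveat that CT
underestimates small-airway lumen size.

Branch-level values average cross-sections at 25/50/75% of branch length;
path-level values (e.g. an RB1-like and an RB10-like path) average their
segmental and sub-segmental branches with equal weight, and the overall
mean weights the listed paths equally, skipping invalid ones.

## Lung metrics

Lungs: `HU < −320`, minus the airway mask (tracheal air would otherwise
bridge the two lungs), connected components with border-touching and
sub-lung-size components discarded, axial-slice hole filling (fills vessels
and airway walls while keeping the subtracted trachea out), two largest
components kept. Left/right by centroid x (right = smaller x); a fused mask
is cut at the minimum-area sagittal plane near the midline. LAV% is the
strict fraction `100·#(HU < −950)/#region`; CT-TLV and rLV are voxel
volumes in ml. The lung mask excludes airway lumen, so tracheal air never
counts as emphysema.

## Indices

- `AWV% = 100·AWV/rLV` (AWV is lumen volume; walls excluded).
- pTLC from a registry of male reference equations; default
  `7.99·height(m) − 7.08` L (ECSC). Any study using pTLC-normalized indices
  should state the equation; results are equation-sensitive, which is why
  the registry is swappable at config level without code changes.
- `Ai/V^(2/3)` converts the volume to mm³ before exponentiation so the
  ratio is dimensionless, then reports ×100.
- GOLD grade from %FEV₁ with inclusive lower bounds (≥ 80 → 1, ≥ 50 → 2,
  ≥ 30 → 3, else 4); symptomatic ⇔ CAT ≥ 10 (inclusive); CAT is bounded
  0–40.
- Cohort summary: mean ± sample SD (n−1); flags as count and
  integer-rounded percent; single-observation SD is null, never 0.

## Statistics

Pearson r by the product-moment formula with a two-sided p from the
t-transform (n−2 df), pairwise deletion, ≥ 3 complete pairs; zero-variance
variables yield an undefined flag rather than an exception. Regressions
z-score the outcome and all independent variables with sample SDs and fit
OLS (statsmodels); VIF_j = 1/(1−R²_j) from regressing variable j on the
others; perfect collinearity raises an error naming the offenders.
Complete-case analysis per model. The two-group comparison defaults to
Welch's t-test (pooled variance available); ANOVA is one-way fixed-effects.
p-values are reported raw; no multiplicity correction is applied, and a
test decision threshold of 0.05 is only ever applied by the caller.

The test suite validates this layer against independent oracles: a
loop-written product-moment implementation (agreement to 10⁻¹²),
parameter recovery on simulated cohorts with known standardized
coefficients (±0.05 at n = 2000), unit VIFs on trigonometric orthogonal
designs, F = t² on two groups, null-calibration of ANOVA p-values (KS
against uniform), and a type-I error rate of the group comparison inside
[0.04, 0.06] at 10⁴ null replicates.

## Orchestration, determinism, problem sizes

`run_subject` executes read → seed/grow (or import an external mask) →
skeleton/graph/partition → TAC/AWV → lung metrics → FWHM paths → indices,
writing masks (NIfTI), the graph (JSON), metrics (JSON with a unit
sidecar) and a provenance record (config hash, package version, accepted
threshold, seed voxel). Configuration is a flat YAML with one block per
stage; unknown keys are errors. All computation is deterministic given the
input and config: rerunning a subject produces byte-identical metrics
JSON, which the acceptance script verifies.

Validation problem sizes were chosen so the whole suite runs comfortably
on a laptop-class single core: phantoms up to depth 4 on 192³ grids at
0.5 mm for the ground-truth recovery suite, 160³-ish grids for pipeline
tests, n = 2000 cohorts for coefficient recovery and 10⁴ replicates for
test calibration. Accuracy statements above refer to these conditions.

## Known limitations

- Threshold-based lumen segmentation underestimates under PSF blur (see
  above); no sub-voxel surface reconstruction is attempted.
- FWHM Ai is biased low for thin-walled, small airways — quantified and
  tested rather than corrected.
- Lobar subtree roots are supplied, not anatomically detected.
- Left-lung airway analysis is intentionally excluded from AWV% (cardiac
  motion corrupts left-sided airway segmentation on real scans); lung
  volumes are still computed bilaterally.
- DICOM support is read-only and assumes a single axial series; NIfTI
  volumes are assumed axis-aligned with the documented orientation.
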