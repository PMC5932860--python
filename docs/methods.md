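# Methods

## The measurement

The quantity of interest is wall deformation of the thoracic aorta over the
cardiac cycle, measured on a triangulated lumen surface. For each triangle
the in-plane deformation gradient `F` maps the two reference edge vectors
(phase 0, the end-diastolic configuration), expressed in an orthonormal
frame of the reference triangle's plane, onto the deformed edge vectors in
the deformed triangle's frame; this linear map is exact for the two
independent edges. The Green–Lagrange tensor `E = (FᵀF − I)/2` is then a
finite-strain measure that vanishes identically under any rigid motion of
the mesh — the property that motivates measuring strain rather than
displacement on a vessel that translates and rotates with the heartbeat.
Strain is total-Lagrangian: every phase is compared with phase 0 directly,
not accumulated incrementally, matching the single end-diastolic
segmentation that defines the material reference.

Peak principal strain amplitude (PPSA) is the temporal maximum over the
cycle of the largest eigenvalue of `E`, in percent. The default regional
reduction takes each element's own temporal peak and then the area-weighted
regional mean ("element-peak"); the alternative order — regional mean per
phase, then temporal peak ("peak-of-mean") — is computed and written
alongside it, since the two orderings differ in the presence of phase
heterogeneity and both are defensible readings of "mean peak systolic
strain". Elements whose area falls below 1e-9 mm² in any phase are excluded
from maps and means and counted in the run manifest. PPSA is reported
signed; a warning is emitted if it is globally negative (pure contraction),
which distension of a pressurised lumen should not produce.

## Segmentation and meshing

The reference lumen mask is obtained by thresholding (Otsu by default, or a
user threshold), keeping the largest connected component, and closing with
a one-voxel structuring element; an externally supplied mask bypasses this
entirely. The package deliberately does not reimplement geodesic
active-contour segmentation: segmentation quality is not the quantity under
study, and on well-contrasted lumens thresholding is adequate.

The surface is extracted by marching cubes at the 0.5 level of the
indicator field low-pass filtered with a 1-voxel Gaussian. The filtering
matters: marching cubes on the raw binary mask reproduces the voxel
staircase, overestimating surface area by ~9% on a digitised sphere,
whereas the smoothed indicator recovers the underlying surface to ~0.3% in
area while staying within one voxel of the true boundary.

Decimation is quadric-error-metric edge collapse (area-weighted plane
quadrics, optimal collapse position by solving the 3×3 normal system,
link-condition and normal-flip guards), implemented in-repo. Smoothing is
Taubin's shrink/inflate low-pass filter (uniform graph Laplacian, λ = 0.5,
μ = −0.53) followed by one uniform rescale about the centroid that restores
the enclosed volume exactly; "volume preserving" is thus a contract (< 1%
drift for decimation, machine precision for smoothing), not an aspiration.
The decimated, smoothed mesh is frozen: node and triangle indices never
change downstream. Default mesh budget is 8000 faces for the standalone
mesh command; the pipeline demonstration uses 3000 faces, which keeps
per-element strain noise and tracking cost balanced at the phantom's
resolution.

## Feature tracking

Per mesh node and phase pair (n, n+1), block matching maximises the
normalised cross-correlation (NCC) between a 7³-voxel patch around the node
in phase n and candidate patches within a ±5-voxel search in phase n+1.
Three details dominate accuracy on smooth vessels:

1. **Presmoothing (σ = 1.2 voxels).** The rasterised lumen edge is about
   one voxel wide; its correlation peak is tent-shaped, and any parabola
   fit on such a peak locks onto the integer lattice. After Gaussian
   presmoothing the peak is locally quadratic and subvoxel refinement —
   per-axis parabola fits on directly resampled NCC with a shrinking
   stencil (0.5, 0.25, 0.1 voxels) — is unbiased to ~0.05 voxel.

2. **The aperture problem.** A contrast-filled lumen is featureless along
   its own surface, so a single patch constrains only the displacement
   component along the surface normal; tangential NCC is flat and its
   argmax is arbitrary. A small quadratic shift penalty (0.05 of the NCC
   scale at full search radius) breaks these ties toward the smallest
   displacement. The surviving tangential ambiguity is resolved globally:
   the per-phase field is the minimiser of
   `Σᵢ cᵢ (n̂ᵢ·(dᵢ − d̂ᵢ))² + α Σ₍ᵢⱼ₎ |dᵢ − dⱼ|²`
   over the mesh graph — a least-squares reconstruction that trusts each
   raw match `d̂ᵢ` only along its normal `n̂ᵢ` (confidence `cᵢ` = peak NCC)
   and fills the tangential null space with the smoothest consistent
   field. Any rigid velocity field satisfies the data term exactly with
   it being smooth, so rigid motion passes through the reconstruction
   undamped; this is essential for the rigid-motion null.

3. **Reference anchoring.** Sequential accumulation of phase-to-phase
   estimates lets material-identity errors compound. Each sequential
   estimate therefore only *predicts* the node position; the final
   position at phase k is obtained by re-matching the phase-0 patch
   directly in phase k within a ±2-voxel window around the prediction,
   followed by the same normal-constrained reconstruction. The smoothness
   weight differs between the two roles: per-step fields (predictions
   only) use α = 20, anchored total fields (which become the mesh) use
   α = 1, because total fields are larger and over-smoothing them shrinks
   the recovered strain.

Cycle closure — the distance by which the mesh, propagated through the full
periodic cycle and matched back to the phase-0 volume, misses its reference
position — is always computed and reported as a quality metric. Optional
drift correction redistributes the closure residual linearly across phases
(off by default; when enabled the corrected cycle closes exactly, and the
pre-correction residual is still recorded).

## The phantom

The synthetic series emulates what gated CTA shows of the aorta: a bright
tube (default 400 vs 0 background) on a 0.625 mm isotropic grid, 10 phases,
with the wall moving radially by a factor `1 + ρ(s)·a_k` about a static
centerline, where `a_k = sin(πk/n)` is a half-sine amplitude peaking at
mid-cycle (the systole analogue) and returning to zero — the motion is
periodic by construction, which is what makes cycle-closure testing
meaningful. Geometries: a straight finite cylinder (closed-form strain,
optional axial stretch) and a candy-cane curved aorta — straight ascending
limb, semicircular arch of centerline radius 2.5·r, straight descending
limb — with optionally region-specific distension blended over a 4 mm
transition at the joints. Rasterisation is anti-aliased (intensity ramps
linearly over one voxel of signed distance), so subvoxel wall motion is
visible to tracking; noise is additive Gaussian, seeded. An optional rigid
translation/rotation is superimposed with the same temporal profile.

Ground truth is analytic. For radial scale `s_r = 1 + ρa` the
circumferential Green–Lagrange strain is `(s_r² − 1)/2`; on the arch a
point at tube angle φ also carries the torus axial stretch
`(c + r·s_r·cosφ)/(c + r·cosφ)`, which stays below the circumferential
stretch whenever r < c, so the regional closed forms (8.32 / 5.125 /
3.045% for 8/5/3% distension) hold in region interiors. The closed forms
are verified in the tests against finite differences of the displacement
map itself (an independent construction) to 1e-6.

What the phantom does *not* emulate: CT physics (beam hardening, streaks,
dose modulation), branch vessels, patient-specific anatomy, wall thickness
(the surface is the lumen boundary, not a shell), and material texture
within the lumen. Consequently, passing the phantom demonstrates the
geometric and numerical fidelity of the pipeline — segmentation bias, mesh
processing, tracking accuracy under the aperture problem, strain
kinematics, regional bookkeeping — but not robustness to scanner artefact
or anatomical complexity.

## Regional resolution

Four cut planes (point + downstream normal): sinotubular junction,
brachiocephalic artery, left subclavian artery, diaphragm. Elements are
classified by centroid. On a folded vessel a plane's half-space also cuts
the opposite limb, so plane-interval membership alone is ambiguous; claims
are resolved by proximity to the chord between the claiming segment's two
plane anchors. Elements proximal to the STJ or distal to the diaphragm are
excluded; "global" is the area-weighted mean over the three included
segments (element weighting switchable to uniform). Landmarks are
user-supplied JSON — anatomical landmark detection is out of scope — and
the phantom provides its construction planes as ground truth.

## Hemodynamics and statistics

Derived indices are computed exactly by their clinical formulas: peak
gradient `4v²`; stroke volume `D² × 0.785 × VTI_LVOT` (continuity); AVA
`D² × 0.785 × VTI_LVOT/VTI_AV`; MAP `DBP + PP/3`; SVR `80 × MAP/CO` with
CO in L/min from SV × HR; SAC `SVi/PP`; Ea `0.9 × SBP/SVi`; Zva
`(SBP + MG)/SVi`; low-flow low-gradient = MG < 40 mmHg and SVi < 35 mL/m².
Missing inputs yield absent outputs, never errors; zero denominators warn
and yield absent outputs. Note that evaluating a nonlinear index at
cohort-mean inputs does not reproduce the cohort mean of per-patient
values; the tests therefore check formulas, not cohort tables.

The coefficient of variation is within-subject SD (root-mean-square method,
`√(mean(d²)/2)`) over the grand mean, ×100; the SD-of-differences variant
is available behind a flag. The ICC is the two-way random-effects,
absolute-agreement, single-measure ICC(2,1) from the subject-by-rater
variance decomposition, with the standard F-distribution confidence
bounds; it matches pingouin's independent implementation to 1e-9 in the
tests. OLS goes through statsmodels with an explicit rank check that names
collinear columns; one-way ANOVA and t-tests go through scipy. No
multiple-testing correction is applied (two-sided p ≤ 0.05 convention).

## Problem sizes, tolerances, determinism

The validation suite runs the full pipeline at 96³ × 0.625 mm × 10 phases
with 3000-face meshes (the demonstration conditions) and smaller 48³/64³
phantoms for unit-level checks. Numerical contracts: analytic strain
recovery to 1e-6; rigid null to 1e-9 strain through direct kinematics and
0.5% through imaging; cycle closure under 0.5 voxel noise-free; regional
recovery within ±15% relative under 5%-contrast noise; mesh volume drift
under 1%. A single integer seed drives every stochastic element (phantom
noise, test constructions); identical configuration and seed reproduce all
pipeline outputs byte for byte.

## Known limitations

- Tracking assumes the lumen boundary is the dominant local image feature;
  adjacent bright structures (calcification, branch ostia) would capture
  patches and are not modelled.
- The normal-constrained reconstruction resolves tangential motion only up
  to the smoothness prior; genuinely unobservable tangential motion (e.g.
  axial rotation of a perfectly symmetric straight tube) is reported as
  zero — harmless for strain, as such motions are strain-free.
- In-plane triangle strain is a membrane measure; transmural/shell effects
  and wall thickness are out of scope.
- The per-element temporal maximum in PPSA is an order statistic and
  inherits an upward bias under per-phase noise; the regional mean of the
  alternative "peak-of-mean" aggregation is the noise-robust counterpart
  and is always written next to it.
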