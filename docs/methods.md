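# Methods

`carotidseg` implements an end-to-end pipeline for multi-class
segmentation of the carotid bifurcation in 3D contrast-enhanced MR
angiography (CE-MRA) and for automated quantification of bifurcation
geometry.  Because the clinical cohorts such pipelines are trained on are
not redistributable, the package ships a synthetic phantom generator
with exactly known geometry; every quantitative guarantee in the test
suite is phrased as parameter recovery or self-consistency on phantoms.

## Coordinate conventions

Arrays are indexed `(x, y, z)` with x the left–right (sagittal) axis,
y anterior–posterior, z inferior–superior.  Voxel `(i, j, k)` has its
centre at `origin + (i, j, k) * spacing` in millimetres; all geometry is
computed in physical mm, so anisotropic spacing is handled everywhere.
The convention is fixed and asserted, never inferred from image content.
NIfTI is the on-disk format for volumes and label maps (label codes:
0 background, 1 CCA, 2 ICA, 3 ECA; bilateral 6-class maps use 4–6 for
the right side and are remapped to 1–3 per side by the sagittal split).

## Phantom generator

A phantom is three straight (optionally sinusoidally undulating) branch
centerlines meeting at a branch point: the CCA runs caudal→cranial along
+z; ICA and ECA leave the branch point in the x–z plane at ±θ/2 from +z,
so the bifurcation angle is exactly θ by construction.  The lumen is a
varying-radius tube: a voxel is lumen when its centre lies within the
local radius of the nearest centerline point, and it takes that point's
branch as its truth label — the same nearest-centerline rule that the
automatic bulb division uses, so truth and division agree by
construction away from the bulb.  The carotid bulb is modelled as a
raised-cosine radial dilation (factor `bulb_scale`, default 1.2) over
the last 5 mm of the CCA and first 5 mm of the ICA; this deliberately
reproduces the hard part of the problem — there is no intensity edge
between branches inside the bulb, only geometry.  An optional stenosis
carves a Gaussian-profile diameter reduction at the ICA midpoint.

Intensities emulate bright-blood CE-MRA: lumen 1000, background 100
(arbitrary units), Gaussian point-spread blur of 0.5 mm, additive
Gaussian noise with SD 20, all seeded.  The label map is noise-free
truth and is bit-identical across noise levels.  Default voxel spacing
is 0.48 × 0.48 × 0.50 mm, the reconstructed resolution of the
acquisitions being emulated; branches are 30 mm long so that the 2 cm
length standardization has material to cut.

Cohort sampling draws branch diameters and the angle uniformly from the
study population mean ± 2 SD (CCA 6.5–10.9 mm, ICA 4.7–10.3 mm, ECA
3.7–7.7 mm, θ 22.7–76.3°), rejecting geometrically infeasible draws
(daughter wider than the dilated CCA).  Because the draws are
independent, a cohort member can have a wider ECA than ICA; downstream
code treats the label map, not the wider-daughter heuristic, as
authoritative when both are available.

One numerical caveat drove a generator design choice: parallel 3D
thinning deletes an entire tube segment when the tube axis lies exactly
between voxel columns (the final two-voxel-wide symmetric column has no
unique centre and is removed wholesale).  A real scanner lattice is
never aligned with the vessel's symmetry planes, so the rasterizer
anchors the grid with the branch point at a fixed non-central fractional
voxel position (0.28, 0.34, 0.41).  The centerline machinery is
additionally robust to partial skeleton retraction (see below), which
can still occur for particular diameter/grid alignments.

What the phantoms do *not* emulate: vessel-wall signal, plaque,
time-of-flight artefacts, bilateral anatomy in one volume, contrast
timing variation, curved or tapering parent vessels, and inter-subject
background anatomy.  Passing the phantom harness therefore demonstrates
the pipeline's geometric and algorithmic correctness, not clinical
performance.

## Preprocessing

Volumes are normalized to zero mean and unit variance over all voxels
(the simplest faithful reading; a body-masked variant would slot into
the same config key) and split in the sagittal plane at `floor(Nx/2)`
(half-open halves, origins corrected so physical coordinates are
preserved), reducing bilateral segmentation from 6 classes to 3 per
side.  An optional mirror flag flips the right half along x so both
sides present the same chirality; it is off by default because
mirroring breaks the mm-coordinate correspondence of the mirrored half.

## Network

A multi-scale 3D patch-based convolutional network: one full-resolution
pathway plus down-sampled pathways with factors 3 and 5, each an
identical stack of valid (unpadded) convolutions with independent
weights.  Kernels may be anisotropic; the defaults elongate the first
layers along z (`3×3×5`), matching both the anisotropic voxel and the
z-running vessels.  The default stack has 8 convolutional layers with
feature maps decreasing in the deeper layers (32, 32, 24, 24, 24, 24,
16, 16); coarse-pathway features are upsampled by nearest-neighbour
repetition to the common resolution, concatenated, and passed through
two fully-connected (1×1×1 convolution) layers and a softmax
classifier over 4 classes.  `NetworkConfig.toy()` is the desk-scale
configuration used throughout the tests (2 conv layers, 8 feature maps,
16-wide FC layers, 13³-voxel output tiles); the exact layer-by-layer
sizing of a full-scale instance is a config choice, not a fixed
constant.

Receptive-field arithmetic is exposed (`receptive_field`): for valid
convolutions the field per axis is `1 + Σ(kernel−1)`, times the pathway
factor in full-resolution voxels.  For the toy config the three
pathways see 5×5×7, 15×15×21 and 25×25×35 voxels per output voxel.

The sub-sampled pathways read the volume on an *absolute* coarse grid
(cells of `factor` voxels anchored at index 0, sampled at cell centres)
rather than a tile-centred one.  This makes tiled full-volume inference
exactly partition-independent — the prediction is identical whatever
tile size covers the volume — which the test suite asserts bit-for-bit.
Out-of-volume context is edge-replicated.  Ties in the final argmax go
to the lowest class code.

### Cost function

Training minimizes `1 − soft-F_β` aggregated over foreground classes,
with β = 2.  On soft confusion counts (TP = Σ p·t etc., summed over the
batch) the default form is

    F_β = (1+β²)·TP / ((1+β²)·TP + β²·FN + FP),

i.e. F_β of precision and recall — the Tversky-style loss whose β = 1
case is exactly the Dice loss (asserted against the metrics module).
β = 2 weights recall (sensitivity) over precision.  A literal
specificity/sensitivity form — the same functional shape evaluated on
(specificity, sensitivity) — is implemented behind
`loss_variant="specificity_sensitivity"`: on class-imbalanced volumes
specificity saturates near 1 and that form carries almost no gradient,
so it exists for comparison, not as the default.  Both forms have
analytic gradients (the denominators TN+FP and TP+FN are constants of
the batch in the specificity form, which makes its gradient
particularly simple).

### Optimization

All training runs on NumPy: forward convolutions are einsum contractions
over sliding windows, gradients are analytic (verified against central
finite differences to 1e-5), and problem sizes are chosen for a single
CPU.  The default optimizer is Adam (lr 3e-3, β₁ 0.9, β₂ 0.999):
the soft-F_β gradient scales inversely with the batch's soft-count
sums, so a fixed-step method needs per-problem rate tuning, and momentum
SGD in particular lingers in an over-segmenting transient at toy scale.
Plain momentum SGD with a decayed schedule remains available
(`optimizer: sgd`).  The classifier bias is initialized with a
background prior (+2 on the background logit), since most voxels are
background and the foreground-only cost gives no direct gradient on
pure-background batches.

Training segments are output tiles with the per-pathway input context
that feeds them; half the tiles (configurable) are centred on uniformly
drawn foreground voxels, the rest on background voxels.  All sampling,
initialization and shuffling derive from explicit seeds; two runs with
the same seeds produce identical loss histories on one thread.

At the repository's operating point — 8 training phantoms, 2 validation,
10 epochs, 48 segments per volume — training takes a few minutes on one
CPU and reaches whole-vessel validation DSC ≈ 0.96–0.98 (the acceptance
floor is 0.7).

## Post-processing

Three stages, in the order applied:

1. **Component cleanup** — per class, the largest 26-connected component
   is kept; every other component is relabelled to the adjacent
   non-background class with the largest contact surface (ties to the
   lowest class code) or removed when isolated.  The rule iterates to a
   fixed point; a safety pass then enforces exactly one component per
   present class.  Connectivity is configurable (6 or 26).
2. **Boundary smoothing** — per class, binary opening then closing with
   a 2×2×2 element.  Opening and closing are reference-point-independent
   set operations (union of element translates contained in / covering
   the mask), so the even element introduces no net shift in the
   composite.  Conflicts after closing resolve to the class with the
   nearest centroid; voxels vacated by every class return to the nearest
   original class; additions outside the original foreground union are
   discarded — the union, and hence the foreground voxel count, is
   preserved exactly.
3. **Radial crop** — foreground farther than 20 mm (Euclidean, physical
   mm) from the bifurcation centre is removed; the centre comes from the
   centerline module's branch point.

The full chain is idempotent and changes < 2% of foreground on clean
phantom truth (measured ≈ 0%).

## Centerlines and branch division

The lumen mask is skeletonized by 3D topological thinning and condensed
into a tree: nodes are endpoints and junctions (adjacent junction voxels
clustered), edges are the degree-2 voxel chains between them.  Terminal
spurs shorter than 3 mm (in mm, hence resolution independent) are
pruned; sub-3 mm parallel paths and self-loops are treated as thinning
artefacts, and genuinely cyclic skeletons are rejected.

The bifurcation junction is selected by the caudal + two-cranial
direction pattern among degree-3 junctions, preferring junctions whose
three incident paths are all long (skeleton fans at flat-cut tube ends
have at least one short path).  Because thinning places the raw junction
inside the bulb — and can retract a branch entirely for unluckily
grid-aligned tubes — the branch point is *refined*: straight lines are
fitted to the three incident paths over an arc window beyond the bulb
(6–20 mm) and their least-squares mutual intersection is taken,
falling back to the raw junction if the fit wanders more than 10 mm.

Branch centerlines are then reconstructed in three steps: (1) path
points are kept only where they lie along the fitted branch direction
(projection beyond a trim distance, lateral deviation bounded) — for the
daughters the trim extends to the arc where the two tubes separate,
`(r₁+r₂+1)/(2·sin(θ/2))`, because the union skeleton is midline-biased
while the lumina overlap; (2) each kept path is prolonged beyond the
skeleton's end by a tube tracker that steps along the terminal direction
and re-centres every step on the lumen centroid within the local radius
(distance transform), stopping at the mask boundary; (3) a second
least-squares intersection of lines refitted to the kept+tracked points
re-anchors all three branches at a final branch point, and the bulb
region is bridged by straight fill segments along the fitted directions.
On default phantoms the recovered branch point is within ~0.1 mm of
truth.

**Division** labels every foreground voxel with the branch of its
nearest centerline point (physical mm; ties to the lowest class code) —
a partition of the mask.  ICA vs ECA is disambiguated by mean lumen
radius (the ICA is anatomically the wider daughter), with an explicit
`ica_side` override.  **Length standardization** removes voxels whose
nearest centerline point lies at arc ≥ 2 cm from the branch point
(inclusive, so a zero length empties the mask); it is monotone in the
cut length and never relabels surviving voxels.

On noise-free default phantoms, division agrees with truth on ≥ 99.9% of
foreground voxels, and every disagreeing voxel's nearest truth
centerline point lies within ~1 mm arc of the branch point.
Disagreement locality is measured along the vessel (arc length of the
nearest centerline point) rather than radially, because the bulb surface
itself lies ≈ 5.2 mm Euclidean from the branch point under default
geometry — a radial bound smaller than that is unsatisfiable even for a
single-voxel boundary wiggle on the bulb equator, while the arc-length
measure expresses exactly the claim of interest: all residual ambiguity
is confined to the bulb.

## Geometric analysis

Per divided, length-standardized bifurcation:

* **Diameter profiles** — at each centerline point, the plane normal to
  the local tangent is sampled at quarter-voxel pitch out to 8 mm; the
  area of the in-plane connected component containing the centerline
  point (so a neighbouring branch crossing the plane is not counted)
  gives an equivalent-circle diameter `d = 2√(A/π)`, measured inside the
  branch's own class mask.  Profiles exclude 2 mm at the branch ends
  and, near the branch point, everything up to the daughter-separation
  arc (computed as in division): inside that region the planes cut
  through the bulb and the merged lumina, and a "branch diameter" is not
  well defined there.  Daughter centerlines are matched to label-map
  classes by majority vote when labels are available, which is what
  makes the analysis correct when the ECA happens to be wider than the
  ICA.
* **Mean branch diameter** — arithmetic mean of the profile.
* **Diameter ratios** — ICA/CCA and ECA/CCA.
* **Bifurcation angle** — between vectors from each daughter's first
  centerline point (at the branch point) to the arc-length midpoint of
  its standardized (2 cm) centerline; "midpoint" is read as the
  arc-length midpoint since no operational definition is standard.
  Centerlines are smoothed (moving average, window 9 points, endpoints
  preserved) before all measurements.

Cohort statistics report mean, sample SD (n−1) and coefficient of
variation (SD/mean) per parameter.

Measured recovery across a 50-phantom sweep spanning the cohort ranges:
branch-diameter RMSE ≈ 0.04–0.08 mm, angle RMSE ≈ 0.3°, ratio RMSE
≤ 0.01 — comfortably within the acceptance bands (0.5 mm, 5°, 0.05).

## Evaluation metrics

Confusion-count scores per class (one-vs-rest) and for the
whole-bifurcation foreground union: Dice (DSC), Matthews correlation
(MCC), F₂, F₀.₅ and true-positive ratio (TPR).  The union scores are
insensitive to ICA/ECA class swaps — bulb-division disagreement is not
counted there, mirroring how whole-vessel quality is reported.
Degenerate conventions (documented and tested): empty truth and empty
prediction give Dice = TPR = 1 and MCC = 0; empty truth with non-empty
prediction gives Dice = 0.  F₁ is algebraically identical to Dice and
the suite asserts this on random counts.  All scores are verified
against an exhaustive voxel-loop oracle to 1e-12 on random volumes.

Fleiss' κ summarizes multi-rater ordinal quality scores (the 0–4
adjustment-need scale); the implementation delegates to statsmodels and
is tested against an explicit hand computation of P̄ and P̄ₑ, with a
seeded uniform-rating null giving κ ≈ 0.  Equal rater counts per subject
are required; κ is reported as NaN when chance agreement is exactly 1.

## Problem sizes and determinism

Everything is sized for one CPU: unit suite plus acceptance properties
run in a few minutes; the toy training criterion is the longest single
item (~2–3 minutes).  Every stochastic component — phantom noise, cohort
draws, segment sampling, weight initialization, rating nulls — takes an
explicit integer seed, and `scripts/acceptance.py` derives all of its
seeds from a single `--seed` argument.

## Known limitations

* Phantom branches are straight tubes with circular cross-sections;
  tortuosity is a small sinusoidal perturbation, not realistic vessel
  curvature, and the diameter profile's circularity assumption is exact
  on phantoms by construction (the elliptical-tube test probes the
  area-based definition instead).
* The thinning-based skeleton is repaired, not replaced: a severely
  retracted skeleton still costs accuracy in the branch-point fit
  (≈ 1 mm in the worst sweep case versus ≈ 0.1 mm typically).
* The specificity-based loss variant is faithful to its printed form but
  nearly non-informative under class imbalance; it is deliberately not
  the default.
* Division locality degrades gracefully at narrow angles (< 30°), where
  the daughters' lumina stay merged for over a centimetre and the
  boundary between them is a knife edge; agreement stays above 95% but
  disagreements extend farther up the bulb than at typical angles.
* Training at full clinical scale (hundreds of epochs-hours on GPU) is
  out of scope; the network is the same architecture family at toy
  scale, not a reproduction of any particular trained model.
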