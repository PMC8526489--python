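# Methods

This note documents the models, defaults and numerical choices behind
`isatlas`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate and data conventions

Volumes are indexed `(x, y, z)` with `z` the slice index of an exported 2D
series; voxels are voxel-centred and 0-based, so voxel `(i, j, k)` sits at
physical position `(i·dx, j·dy, k·dz)` µm. The micro-CT pipeline assumes
isotropic voxels (the reference data use 3.9 µm); confocal inputs may be
anisotropic and carry a per-axis voxel size. Intensities are 8-bit; float
arrays (averaged templates) are treated as living on the same 0–255 scale.
Label 0 is background; every other id must appear in the field's catalog.

Transform chains map **fixed-space physical coordinates to moving-space
physical coordinates** (pull-back resampling). The total map is
`x ↦ A(x) + Σ_g d_g(x)`: an affine about the fixed-image physical centre
(applied as scale, shear, intrinsic Z-Y-X Euler rotation, translation) plus
cubic B-spline displacement fields evaluated at the *fixed-space* position.
Chains serialize to JSON losslessly (coefficients kept to 1e-9 µm).

## Similarity metric

Normalized mutual information in the Studholme form
`NMI = (H(A)+H(B)) / H(A,B)` with Shannon entropies (natural log) of a
joint histogram; 64 bins per channel by default, linear interpolation of
the moving image, and both-zero voxel pairs excluded — after brain
extraction the background is forced to 0 and would otherwise dominate the
statistic. 8-bit data are binned over the fixed range [0, 255]; float data
over their own min/max. Degenerate single-cell histograms score 2.0 by
convention in the public `nmi()`.

Two guards keep the *optimizer* away from NMI's known pathologies: a
candidate transform keeping fewer than a quarter of the voxel pairs kept by
the starting transform, or collapsing the histogram to a single cell,
scores −∞. Without them the search can increase NMI indefinitely by pushing
the images apart — and the brain's rough mirror symmetry offers a genuine
decoy optimum (one optic lobe matched onto the other) that a
centre-of-mass translation initialization avoids.

## Optimization

Both registrations use derivative-free coordinate descent — robust without
analytic NMI gradients and bit-deterministic (ties keep the incumbent).

*Affine* (6/9/12 DOF): a multiresolution pyramid (Gaussian-smoothed ×4, ×2,
×1 downsampling; levels below ~12 voxels per axis are skipped as
structureless), translation steps from 2 coarse voxels halving to 0.25 fine
voxels, with rotation/scale/shear steps coupled so one step moves the
volume edge by about one translation step. The returned score is evaluated
on the full-resolution objective and never falls below the score of the
initialization. Typical recovery accuracy on noise-free 64³ phantoms is
≲0.1 voxel translation, ≲0.3° rotation and 1–2% scale.

*B-spline FFD*: one control-point lattice per elastic round, spacing at
least 4 voxels, covering the domain plus a one-cell margin. Control points
are visited in lattice order; each of the three displacement components is
tried at ±step (2, 1, 0.5, 0.25 voxels) with **exact incremental
histogram updates** over the point's support region, evaluated on a
stride-2 voxel lattice; accepted moves must improve the objective by more
than 1e-9 (absolute), which stops float-noise drift on perfectly aligned
pairs. Displacements are capped at 0.4 × spacing per component as a
folding guard — cheap and sufficient at this deformation scale; an optional
bending-energy penalty (squared second differences of the lattice, weight 0
by default) is available. All-background support regions are skipped.

## Iterative shape averaging

Reference = specimen with total labelled volume closest to the cohort
median (ties to the lower index). Affine stage: 6-DOF then 9-DOF onto the
reference, each stage initialized from the previous; the reference keeps an
identity chain and participates in the average. Templates accumulate in
float32; registration sees them quantized to uint8 so fixed and moving
histograms share the 0–255 footing (an asymmetric float range measurably
biases the metric). Five elastic rounds by default; the control spacing
starts at extent/4 and halves each round, floored at 4 voxels (so the
schedule is non-increasing, not strictly decreasing, on small volumes).
Each round is initialized from the specimen's accumulated chain and appends
one grid. The logged per-round score is the mean NMI of each original
specimen against the new template through its chain.

Labels are propagated with nearest-neighbour sampling and fused by
shape-based averaging: per label, signed Euclidean distance maps (negative
inside, physical µm; `scipy.ndimage.distance_transform_edt` on both sides)
are averaged across specimens and each voxel takes the label with the
smallest negative mean distance, ties to the smallest id, strict `< 0` for
foreground. A label absent from one specimen contributes +∞ (the structure
drops out) unless `skip_missing` averages only the specimens that have it.

### Separate standardization of small structures

The central-complex group is tiny and low-contrast, so the main metric
barely sees it. The substructure pass crops a padded (8-voxel) bounding box
around the listed labels in the affinely aligned specimens, masks the crop
intensities to a dilated vicinity of the structures, and runs a short ISA:
a rigid 6-DOF, centre-of-mass-initialized pre-alignment followed by three
elastic rounds. A purely elastic sub-pipeline cannot recover a coherently
translated cluster from the ghosted multi-copy average (measured Dice 0 on
a ±2-voxel jitter fixture), which is why the rigid stage exists. The fused
substructure is placed into the main atlas with a 6-DOF registration
estimated *inside the crop box* — blurred per-label mask images by default,
falling back to vicinity-masked template intensity when strict fusion left
no trace of the structures — and the placement is composed with the crop
offset. On cohorts where the main pipeline already resolves the small
structures the patch is roughly neutral; its value shows when the main
pipeline fails them.

## Neuron transfer

Confocal stacks are registered through their landmark reconstructions, not
raw intensities — fluorescence and CT grey values are incomparable, the
reconstructed neuropil shapes are not. Each landmark gets a distinct grey
level, Gaussian-blurred (σ = 1.5 voxels, scaled per axis on anisotropic
grids). Pipeline: 12-DOF affine at atlas resolution, an affine refinement
against the atlas labels resampled to the confocal grid (the coarse atlas
grid otherwise limits accuracy under anisotropy), a single B-spline
refinement (spacing = extent/8), and application of the chain to the dye
channel on the atlas-aligned confocal-resolution grid. The neuron channel
is only resampled, never thresholded. Per-landmark Dice is reported after
the affine and after the elastic step; the elastic optimizes mask NMI, which
tracks but does not strictly bound per-landmark Dice — small (~0.01)
regressions of one landmark can occur on some realizations while the
others improve.

## Synthetic phantoms

The generator emulates the statistical structure the pipeline assumes: a
shared multi-compartment brain (remaining-neuropil ellipsoid, paired
three-shell optic-lobe stacks with the medulla thickest, antennal-lobe
spheres, mushroom-body blocks, a sub-1% central-complex cluster), bright
non-brain clutter (muscle-like blobs, a retina-like shell) strictly outside
the brain mask, per-specimen 9-DOF affines (defaults: ≤5 voxels
translation, ≤10° rotation, isotropic scale 0.95–1.05), a smooth random
B-spline warp (spacing 16 voxels, coefficient σ = 2 voxels, clipped at the
folding guard) and additive Gaussian noise (σ = 5 grey levels) with
clip-and-quantize. Those defaults are the study conditions of the recovery
benchmarks; geometry proportions mirror the real volumetry qualitatively
(optic lobes > 25% of the brain, central complex < 1%). The optic-lobe
shells deliberately graze the grid boundary, as in a cropped scan.
Everything is a pure function of (spec, seed); the default cohort is ten
specimens at 96³, but the recovery benchmarks run a fast profile — four
specimens at 48³ — chosen so a full five-round ISA finishes in minutes on
one CPU.

What the phantoms do **not** model: beam hardening, ring artifacts,
partial-volume texture, staining gradients, anatomical variation beyond a
smooth warp, or left-right asymmetries. Passing recovery tests therefore
demonstrates the machinery (metric, optimizers, fusion, bookkeeping), not
performance on real micro-CT contrast.

### Ground truth for pipeline recovery

The fused atlas lives on the reference specimen's grid. Template-anchored
ISA reproduces, to first order, the *reference's* anatomy (that is why the
protocol picks a median-volume reference), so recovery is scored against
the ground-truth template labels pulled through the reference's full known
generating chain. Empirically the fused labels sit much closer to this
target (median Dice ≈ 0.9 across seeds) than to the affine-only pose of the
template (≈ 0.84), confirming the anchoring analysis.

## Preprocessing

The shrink-wrap of sparse scaffold annotations is closing (ball radius, 5
voxels by default) → hole filling → largest connected component, re-united
with the annotated voxels so the mask always contains the scaffold.
Intensity normalization stretches the nonzero support linearly to [0, 255]
with half-up rounding (half-up everywhere, for cross-platform
determinism); statistics exclude exact zeros so masking does not pin the
minimum. The stretch maps the nonzero minimum to 0, which moves those
voxels into the excluded class — a second pass is a no-op only up to one
grey level on dense-histogram (brain-like) data, and that is the form in
which idempotence is asserted. Percentile clipping is available but off by
default. Sparse XY-slice annotations are completed by linear interpolation
of per-slice 2D signed distance maps between bracketing annotated slices,
thresholded at 0, smallest-distance wins on overlaps; a label present on
only one end of an interval claims only the nearer half (nearest-slice
copy) with a warning.

## Volumetry

Volume = voxel count × voxel volume; composite structures (CX, OL, MB) are
sums over a group-membership table shipped as JSON and editable for other
species. Relative volumes divide by the *top-level* denominator (ungrouped
structures + group totals), so members are never double-counted; exclusion
sets (e.g. laminae and ocellar plexi, for comparison with atlases that lack
them) remove structures from numerator and denominator alike. Cohort
statistics use the sample SD (n−1); both the mean of per-specimen
percentages and the percentage of the fused atlas are reported, since the
two differ in general. Rounding (1 decimal for percent, half-up) happens
only at serialization. Atlas extents multiply voxel counts by voxel sizes,
rounded half-up to whole µm; cross-atlas ratios are integer percents of
voxel counts.

## Known limitations

- The affine search is local; initial misalignments far beyond the phantom
  magnitudes (e.g. >90° rotations) are out of capture range.
- NMI on 48³ volumes with 64 bins is a sparse-histogram estimate; scores
  are comparable within a run, not across image sizes.
- Shape-based fusion is binary per label: partial-volume boundaries are
  resolved by the sign of the mean distance, and structures thinner than
  the registration residual (the 1-voxel lamina shell at the fast profile)
  fuse with visibly lower Dice than blob-like structures.
- The elastic optimizer fits one grid per round greedily; it does not
  revisit earlier grids, so very large coherent deformations must be
  absorbed by the affine stage.
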