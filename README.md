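# isatlas — iterative shape averaging for insect standard brains

`isatlas` builds **standard brain atlases** from cohorts of 3D grey-value
scans, following the workflow used to construct the *Bombus terrestris*
(buff-tailed bumblebee) standard brain from micro-CT data: per-specimen
brain extraction and intensity normalization, groupwise alignment by
**iterative shape averaging (ISA)**, **shape-based fusion** of the
propagated neuropil segmentations, neuropil **volumetry**, and transfer of
confocal **neuron reconstructions** into the finished atlas.

It is aimed at insect neuroanatomists who want a scriptable, fully
deterministic re-implementation of that pipeline — and at method developers
who want a compact, tested reference for NMI-driven affine + B-spline
registration and distance-map label fusion, exercised end-to-end on
synthetic phantoms with known ground truth.

## The method

**Similarity.** All registrations maximize normalized mutual information
(Studholme form) over a joint intensity histogram (64 bins, background
pairs excluded):

```
NMI(A, B) = (H(A) + H(B)) / H(A, B),   NMI ∈ [1, 2]
```

**Transforms.** A chain `x ↦ A(x) + Σ_g d_g(x)` maps fixed-space physical
coordinates (µm) to moving-space coordinates: one affine `A` with 6 / 9 / 12
degrees of freedom (rigid; + scale; + shear) about the fixed-image centre,
followed by cubic **B-spline free-form deformations** `d_g` on control-point
lattices of decreasing spacing. Optimization is derivative-free coordinate
descent with halving step schedules; elastic control points are updated with
exact incremental histogram bookkeeping, so a full five-round ISA run on a
desk-scale cohort takes minutes, not hours.

**ISA.** The specimen whose total segmented volume is closest to the cohort
median becomes the reference. Every other specimen is registered to it with
a 6-DOF then 9-DOF affine; the aligned intensities are averaged; then five
elastic rounds follow, each registering every specimen onto the current
average and re-averaging, with a finer control grid per round. The final
chains deform each specimen's label field (nearest-neighbour), and the
deformed segmentations are fused by **shape-based averaging**: per label,
the signed Euclidean distance maps (negative inside) are averaged and the
voxel goes to the label with the smallest negative mean distance.

Small neuropils (the central-complex group) carry little mutual information
and are standardized separately on a cropped, vicinity-masked region, then
placed back with a rigid transform.

## Worked example

Build an atlas from a synthetic 4-specimen cohort (48³ voxels at 3.9 µm,
±5-voxel translations, ±10° rotations, 2-voxel random warps, grey-level
noise σ=5) and score it against the known ground truth:

```
$ python analysis/02_build_atlas.py --n 4 --grid 48 --seed 1
reference specimen: phantom03
per-round mean NMI: [1.30318, 1.33258, 1.348, 1.35339, 1.35569]
...
median Dice over structures >= 500 voxels: 0.9103
```

The per-round mean NMI rises as the template sharpens and the cohort
converges onto it; the fused segmentation recovers every structure larger
than 500 voxels with a median Dice above 0.9 against the ground-truth
labels expressed in atlas space. `results/atlas_recovery.csv` lists the
per-structure scores; the atlas itself (`template.nrrd`, `labels.nrrd`,
per-specimen transform chains) lands in `scratch/atlas/`.

The other drivers follow the same pattern: `analysis/01_simulate_cohort.py`
writes a cohort with ground truth, `analysis/03_volumetry_tables.py`
reproduces the published volumetry and atlas-extent tables, and
`analysis/04_register_neuron.py` carries a simulated dye-filled neuron from
an anisotropic confocal stack into the atlas.

## Package layout

| module | contents |
| --- | --- |
| `isatlas.core` | `Volume`, `LabelField`, `SpecimenSet`, shared errors |
| `isatlas.io` | 8-bit image series, NRRD (+ label catalog sidecars), resampling |
| `isatlas.preprocess` | scaffold→mask shrink-wrap, masking, 0–255 normalization, sparse-slice label interpolation |
| `isatlas.registration` | NMI, affine + B-spline FFD registration, transform chains |
| `isatlas.isa` | reference selection, affine stage, ISA loop, substructure standardization |
| `isatlas.fusion` | signed distance maps, shape-based label averaging |
| `isatlas.volumetry` | label volumes, cohort statistics, relative volumes, atlas extents |
| `isatlas.neuron` | confocal neuron-channel transfer into the atlas |
| `isatlas.phantoms` | synthetic cohort / confocal-stack generators with ground truth |
| `isatlas.pipeline` | validated configuration + end-to-end `run_pipeline` |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
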