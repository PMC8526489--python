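"""Synthetic phantom cohorts with known ground truth.

The generator emulates what the pipeline assumes about its real inputs: a
cohort of specimens sharing one multi-compartment "brain" — a large
remaining-neuropil (RN) matrix, paired three-shell optic-lobe stacks
(LA/ME/LO analogs), paired antennal-lobe spheres, mushroom-body blocks and a
small central-complex cluster (CBU/CBL/PB/NO analogs) — surrounded by bright
non-brain clutter ("muscle" blobs and a "retina" shell), with each specimen
perturbed by a known 9-DOF affine, a smooth random B-spline warp and
additive Gaussian noise.  Compartment proportions qualitatively mirror real
volumetry: the optic lobes are over a quarter of the brain, the central
complex under one percent.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import LabelField, SpecError, SpecimenSet, Volume
from .registration import AffineParams, BSplineGrid, TransformChain, apply_transform

#: catalog of the phantom brain; ids are stable across the package
PHANTOM_CATALOG: dict[int, str] = {
    1: "RN",
    2: "AL-l", 3: "AL-r",
    4: "LA-l", 5: "ME-l", 6: "LO-l",
    7: "LA-r", 8: "ME-r", 9: "LO-r",
    10: "MB-l", 11: "MB-r",
    12: "PB", 13: "CBU", 14: "CBL", 15: "NO",
}

#: group memberships used for phantom volumetry
PHANTOM_GROUPS: dict[str, list[str]] = {
    "CX": ["PB", "CBU", "CBL", "NO"],
    "OL": ["LA-l", "ME-l", "LO-l", "LA-r", "ME-r", "LO-r"],
    "MB": ["MB-l", "MB-r"],
}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic cohort.

    Geometry is expressed in fractions of the grid edge so one spec scales
    between the full-size (96³) and fast (48³) profiles.  Magnitudes follow
    the study conditions the pipeline is meant to survive: a few voxels of
    translation, ~10° rotations, scale a few percent, a smooth warp of ~2
    voxels and single-digit grey-level noise.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_um: float = 3.9
    structure_grey: dict[str, int] = field(default_factory=lambda: {
        "RN": 90, "AL-l": 160, "AL-r": 160,
        "LA-l": 180, "ME-l": 140, "LO-l": 200,
        "LA-r": 180, "ME-r": 140, "LO-r": 200,
        "MB-l": 170, "MB-r": 170,
        "PB": 220, "CBU": 200, "CBL": 210, "NO": 230,
    })
    smooth_sigma_vox: float = 1.0
    # clutter
    n_muscle_blobs: int = 6
    muscle_grey: int = 240
    retina_grey: int = 220
    # specimen perturbation magnitudes
    max_translation_vox: float = 5.0
    max_rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.95, 1.05)
    warp_spacing_vox: float = 16.0
    warp_sd_vox: float = 2.0
    noise_sd: float = 5.0
    seed: int = 0

    def scaled(self, n: int) -> "PhantomSpec":
        """The same phantom on an n³ grid."""
        return replace(self, shape=(n, n, n))


# fractional geometry of the template brain (fractions of the grid edge)
_OL_CENTER_DX = 0.36
_OL_RADII = (0.06, 0.13, 0.15)   # LO ball, ME shell outer, LA shell outer
_AL_CENTER = (0.16, 0.32)        # |dx| from mid, y fraction offset from mid (negative = ventral)
_AL_RADIUS = 0.07
_MB_CENTER = (0.14, 0.18)        # |dx|, +y (dorsal)
_MB_HALF = (0.07, 0.09, 0.12)
_RN_SEMI = (0.32, 0.26, 0.22)


def _grids(shape):
    ax = [np.arange(n, dtype=np.float64) for n in shape]
    return np.meshgrid(*ax, indexing="ij")


def make_template(spec: PhantomSpec) -> tuple[Volume, LabelField, Volume]:
    """Build the ground-truth brain: (intensity volume, labels, brain mask).

    Compartments are painted into the RN matrix; any overlap between two
    non-RN compartments raises :class:`SpecError`.  Clutter lives strictly
    outside the brain mask.  Deterministic given ``spec.seed``.
    """
    n = float(min(spec.shape))
    cx, cy, cz = [(s - 1) / 2.0 for s in spec.shape]
    X, Y, Z = _grids(spec.shape)
    labels = np.zeros(spec.shape, dtype=np.int32)
    by_name = {v: k for k, v in PHANTOM_CATALOG.items()}

    # RN matrix ellipsoid
    rn = ((X - cx) / (_RN_SEMI[0] * n)) ** 2 + ((Y - cy) / (_RN_SEMI[1] * n)) ** 2 + (
        (Z - cz) / (_RN_SEMI[2] * n)
    ) ** 2 <= 1.0
    labels[rn] = by_name["RN"]

    def paint(mask: np.ndarray, name: str) -> None:
        clash = labels[mask]
        offenders = sorted(set(int(v) for v in np.unique(clash)) - {0, by_name["RN"]})
        if offenders:
            names = [PHANTOM_CATALOG[o] for o in offenders]
            raise SpecError(f"compartment {name} overlaps {names}")
        labels[mask] = by_name[name]

    for side, sgn in (("l", -1.0), ("r", +1.0)):
        ox = cx + sgn * _OL_CENTER_DX * n
        r2 = (X - ox) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        r = np.sqrt(r2)
        paint(r <= _OL_RADII[0] * n, f"LO-{side}")
        paint((r > _OL_RADII[0] * n) & (r <= _OL_RADII[1] * n), f"ME-{side}")
        paint((r > _OL_RADII[1] * n) & (r <= _OL_RADII[2] * n), f"LA-{side}")
        ax_ = cx + sgn * _AL_CENTER[0] * n
        ay = cy - _AL_CENTER[1] * n
        paint((X - ax_) ** 2 + (Y - ay) ** 2 + (Z - cz) ** 2 <= (_AL_RADIUS * n) ** 2, f"AL-{side}")
        mx = cx + sgn * _MB_CENTER[0] * n
        my = cy + _MB_CENTER[1] * n
        paint(
            (np.abs(X - mx) <= _MB_HALF[0] * n)
            & (np.abs(Y - my) <= _MB_HALF[1] * n)
            & (np.abs(Z - cz) <= _MB_HALF[2] * n),
            f"MB-{side}",
        )

    # small central-complex cluster
    paint(
        ((X - cx) / (0.045 * n)) ** 2 + ((Y - cy) / (0.03 * n)) ** 2 + ((Z - cz) / (0.03 * n)) ** 2 <= 1.0,
        "CBU",
    )
    paint(
        ((X - cx) / (0.035 * n)) ** 2 + ((Y - (cy - 0.06 * n)) / (0.02 * n)) ** 2
        + ((Z - cz) / (0.02 * n)) ** 2 <= 1.0,
        "CBL",
    )
    paint(
        (np.abs(X - cx) <= 0.06 * n) & (np.abs(Y - (cy + 0.06 * n)) <= 0.013 * n)
        & (np.abs(Z - cz) <= 0.013 * n),
        "PB",
    )
    no = np.zeros(spec.shape, dtype=bool)
    for sgn in (-1.0, 1.0):
        no |= (X - (cx + sgn * 0.07 * n)) ** 2 + (Y - (cy - 0.05 * n)) ** 2 + (
            Z - cz
        ) ** 2 <= (0.02 * n) ** 2
    paint(no, "NO")

    # watertight brain mask
    mask = ndimage.binary_fill_holes(ndimage.binary_closing(labels > 0, iterations=2))

    grey = np.zeros(spec.shape, dtype=np.float64)
    for lid, name in PHANTOM_CATALOG.items():
        grey[labels == lid] = spec.structure_grey[name]
    if spec.smooth_sigma_vox > 0:
        grey = ndimage.gaussian_filter(grey, spec.smooth_sigma_vox)
    grey[~mask] = 0.0

    # clutter outside the brain
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC1]))
    clutter = np.zeros(spec.shape, dtype=np.float64)
    for side_sgn in (-1.0, 1.0):
        ox = cx + side_sgn * _OL_CENTER_DX * n
        r = np.sqrt((X - ox) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
        clutter[(r > 0.18 * n) & (r <= 0.21 * n)] = spec.retina_grey
    for _ in range(spec.n_muscle_blobs):
        c = rng.uniform(0.1, 0.9, size=3) * np.array(spec.shape)
        semi = rng.uniform(0.03, 0.08, size=3) * n
        blob = ((X - c[0]) / semi[0]) ** 2 + ((Y - c[1]) / semi[1]) ** 2 + ((Z - c[2]) / semi[2]) ** 2 <= 1
        clutter[blob] = spec.muscle_grey
    if spec.smooth_sigma_vox > 0:
        clutter = ndimage.gaussian_filter(clutter, spec.smooth_sigma_vox)
    clutter[mask] = 0.0
    if spec.n_muscle_blobs == 0 and spec.retina_grey == 0:
        clutter[:] = 0.0

    vol = np.clip(np.floor(grey + clutter + 0.5), 0, 255).astype(np.uint8)
    return (
        Volume(vol, spec.voxel_size_um),
        LabelField(labels, spec.voxel_size_um, dict(PHANTOM_CATALOG)),
        Volume(mask.astype(np.uint8), spec.voxel_size_um),
    )


def _sample_chain(spec: PhantomSpec, rng: np.random.Generator, center) -> TransformChain:
    v = spec.voxel_size_um
    t = tuple(rng.uniform(-spec.max_translation_vox, spec.max_translation_vox, 3) * v)
    r = tuple(np.deg2rad(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg, 3)))
    s_iso = rng.uniform(*spec.scale_range)
    affine = AffineParams(t=t, r=r, s=(s_iso,) * 3, h=(0.0, 0.0, 0.0), dof=9, center=tuple(center))
    chain = TransformChain(affine)
    if spec.warp_sd_vox > 0:
        spacing = spec.warp_spacing_vox * v
        cap = 0.4 * spacing
        if 3.0 * spec.warp_sd_vox * v > cap:
            raise SpecError(
                f"warp sd {spec.warp_sd_vox} voxels violates the folding guard "
                f"(3·sd must stay below 0.4 × spacing = {cap / v:.2f} voxels)"
            )
        extent = tuple(n_ * v for n_ in spec.shape)
        grid = BSplineGrid.for_domain(extent, spacing, (v,) * 3)
        coeffs = rng.normal(0.0, spec.warp_sd_vox * v, size=grid.coeffs.shape)
        grid.coeffs = np.clip(coeffs, -cap, cap)
        chain = chain.with_grid(grid)
    return chain


def make_specimen(
    template: tuple[Volume, LabelField, Volume], spec: PhantomSpec, specimen_seed: int
) -> tuple[Volume, LabelField, Volume, TransformChain]:
    """Deform the template into one synthetic specimen.

    Returns (intensity, labels, warped brain mask, ground-truth chain); the
    chain maps specimen-grid physical coordinates into template space, i.e.
    ``specimen(x) = template(chain(x)) + noise``.
    """
    tvol, tlab, tmask = template
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, specimen_seed]))
    center = tuple((n_ - 1) * v / 2.0 for n_, v in zip(spec.shape, (spec.voxel_size_um,) * 3))
    chain = _sample_chain(spec, rng, center)
    vol = apply_transform(tvol, chain, "linear")
    lab = apply_transform(tlab, chain)
    mask = apply_transform(tmask, chain, "nearest")
    data = vol.data.astype(np.float64)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(np.floor(data + 0.5), 0, 255).astype(np.uint8)
    return Volume(data, spec.voxel_size_um), lab, mask, chain


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline has to recover."""

    template_volume: Volume
    template_labels: LabelField
    template_mask: Volume
    chains: list[TransformChain]
    specimen_masks: list[Volume]


def make_cohort(spec: PhantomSpec, n: int, seed: int | None = None) -> tuple[SpecimenSet, GroundTruth]:
    """Generate an n-specimen cohort plus its ground-truth bundle."""
    if n < 2:
        raise ValueError(f"a cohort needs n >= 2 specimens, got {n}")
    if seed is not None:
        spec = replace(spec, seed=int(seed))
    template = make_template(spec)
    vols, labs, masks, chains = [], [], [], []
    for i in range(n):
        v, l, m, c = make_specimen(template, spec, i + 1)
        vols.append(v)
        labs.append(l)
        masks.append(m)
        chains.append(c)
    cohort = SpecimenSet(vols, labs, [f"phantom{i:02d}" for i in range(n)])
    return cohort, GroundTruth(template[0], template[1], template[2], chains, masks)


def atlas_space_truth(truth: GroundTruth, reference_index: int) -> LabelField:
    """Ground-truth labels expressed in atlas (reference-specimen) space.

    Template-anchored shape averaging reproduces, to first order, the
    reference specimen's anatomy; the known generating chain of the reference
    maps atlas-grid coordinates into template space, so pulling the template
    labels through it gives the configuration a perfect pipeline would fuse.
    """
    return apply_transform(truth.template_labels, truth.chains[reference_index])


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap score 2|A∩B| / (|A|+|B|) between two binary masks."""
    denom = int(a.sum()) + int(b.sum())
    return 2.0 * float(np.logical_and(a, b).sum()) / denom if denom else 0.0


def per_structure_dice(
    labels: LabelField, truth_labels: LabelField, min_voxels: int = 0
) -> dict[str, float]:
    """Dice per catalogued structure, optionally restricted to structures
    with at least ``min_voxels`` ground-truth voxels."""
    out = {}
    for lid, name in sorted(truth_labels.catalog.items()):
        gt = truth_labels.data == lid
        if int(gt.sum()) >= max(1, min_voxels):
            out[name] = dice_coefficient(labels.data == lid, gt)
    return out


# --------------------------------------------------------------------------
# confocal-like stacks
# --------------------------------------------------------------------------

@dataclass
class PolylineSpec:
    """A bright neuron-like 3D polyline confined to one named structure."""

    structure: str = "CBL"
    n_points: int = 6
    radius_um: float = 4.0
    brightness: int = 255


@dataclass
class ConfocalStack:
    """A neuron channel plus landmark neuropil labels on one (possibly
    anisotropic) confocal grid."""

    neuron: Volume
    landmarks: LabelField

    def __post_init__(self) -> None:
        if self.neuron.shape != self.landmarks.shape:
            raise ValueError("neuron channel and landmark labels must share one grid")
        if not np.allclose(self.neuron.voxel_size, self.landmarks.voxel_size):
            raise ValueError("neuron channel and landmark labels must share voxel sizes")
        if not (self.landmarks.data > 0).any():
            raise ValueError("a confocal stack needs at least one landmark label")


def _rasterize_polyline(points_vox: np.ndarray, shape, voxel_size, radius_um: float) -> np.ndarray:
    """Antialiased tube around a polyline, 0..1 intensity."""
    acc = np.zeros(shape, dtype=np.float64)
    vs = np.asarray(voxel_size, dtype=np.float64)
    for p, q in zip(points_vox[:-1], points_vox[1:]):
        seg_len = float(np.linalg.norm((q - p) * vs))
        steps = max(2, int(seg_len / (0.25 * min(vs))) + 1)
        for t in np.linspace(0.0, 1.0, steps):
            c = p + t * (q - p)
            lo = np.maximum(0, np.floor(c - radius_um / vs - 2).astype(int))
            hi = np.minimum(shape, np.ceil(c + radius_um / vs + 3).astype(int))
            sl = tuple(slice(a, b) for a, b in zip(lo, hi))
            ax = [np.arange(a, b, dtype=np.float64) for a, b in zip(lo, hi)]
            G = np.meshgrid(*ax, indexing="ij")
            d2 = sum(((g - ci) * v) ** 2 for g, ci, v in zip(G, c, vs))
            acc[sl] = np.maximum(acc[sl], np.exp(-d2 / (2 * (radius_um / 2.0) ** 2)))
    return acc


def make_confocal_like(
    template: tuple[Volume, LabelField],
    polyline: PolylineSpec,
    voxel_size_um: tuple[float, float, float],
    seed: int = 0,
    landmark_names: tuple[str, ...] = ("CBL", "AL-l", "MB-l"),
    affine_magnitudes: tuple[float, float, float] | None = (5.0, 8.0, 0.05),
    shear_max: float = 0.05,
    background_level: float = 25.0,
) -> tuple[ConfocalStack, TransformChain, Volume]:
    """Simulate a confocal scan of landmark neuropils plus a filled neuron.

    The template's landmark structures and a bright antialiased polyline
    inside ``polyline.structure`` are pushed through a sampled 12-DOF affine
    (``affine_magnitudes`` = max translation voxels / rotation deg / scale
    deviation; ``None`` for identity) and resampled onto the requested —
    typically anisotropic — grid with background fluorescence texture.

    Returns (stack, ground-truth chain mapping stack space → template space,
    neuron channel in template space before deformation).
    """
    tvol, tlab = template
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCF]))
    ids = tlab.ids_by_name()
    for nm in landmark_names:
        if nm not in ids:
            raise ValueError(f"landmark {nm!r} not present in template catalog")
    struct_id = ids[polyline.structure]
    voxels = np.argwhere(tlab.data == struct_id)
    if voxels.size == 0:
        raise ValueError(f"structure {polyline.structure!r} empty in template")
    # smooth polyline through random voxels of the structure, ordered along x
    pick = voxels[rng.choice(len(voxels), size=polyline.n_points, replace=True)]
    pick = pick[np.argsort(pick[:, 0], kind="stable")].astype(np.float64)
    neuron_t = _rasterize_polyline(pick, tlab.shape, tlab.voxel_size, polyline.radius_um)
    neuron_template = Volume((neuron_t * polyline.brightness), tlab.voxel_size)

    keep = np.isin(tlab.data, [ids[nm] for nm in landmark_names])
    lm_data = np.where(keep, tlab.data, 0).astype(np.int32)
    lm_template = LabelField(lm_data, tlab.voxel_size, dict(tlab.catalog))

    center = tuple((n_ - 1) * v / 2.0 for n_, v in zip(tlab.shape, tlab.voxel_size))
    if affine_magnitudes is None:
        affine = AffineParams.identity(12, center)
    else:
        mt, mr, ms = affine_magnitudes
        v0 = min(tlab.voxel_size)
        affine = AffineParams(
            t=tuple(rng.uniform(-mt, mt, 3) * v0),
            r=tuple(np.deg2rad(rng.uniform(-mr, mr, 3))),
            s=tuple(rng.uniform(1 - ms, 1 + ms, 3)),
            h=tuple(rng.uniform(-shear_max, shear_max, 3)),
            dof=12, center=center,
        )
    chain = TransformChain(affine)

    extent = tuple(n_ * v for n_, v in zip(tlab.shape, tlab.voxel_size))
    out_shape = tuple(max(1, int(round(e / v))) for e, v in zip(extent, voxel_size_um))
    landmarks = apply_transform(lm_template, chain, out_shape=out_shape, out_voxel=voxel_size_um)
    neuron = apply_transform(neuron_template, chain, "linear", out_shape=out_shape, out_voxel=voxel_size_um)

    # the dye channel is separate from the counterstain channel that the
    # landmark reconstructions come from: only faint autofluorescence here
    bg = ndimage.gaussian_filter(rng.uniform(0, 2 * background_level, size=out_shape), 2.0)
    data = np.clip(np.floor(np.maximum(neuron.data, bg) + 0.5), 0, 255).astype(np.uint8)
    stack = ConfocalStack(Volume(data, voxel_size_um), landmarks)
    return stack, chain, neuron_template
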