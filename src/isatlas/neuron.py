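"""Transfer of a confocal neuron channel into atlas space.

A dye-filled neuron is imaged together with background fluorescence that
reveals a few landmark neuropils.  Those landmarks are reconstructed as a
label field on the confocal grid and drive the registration: a 12-DOF affine
maps the stack's landmark masks onto the matching atlas labels, the atlas is
resampled to the (typically anisotropic) confocal resolution so the neuron
keeps its native detail, a B-spline elastic step refines the landmark match,
and the resulting chain resamples the neuron channel onto the atlas-aligned
confocal-resolution grid.

The similarity is NMI on Gaussian-blurred label masks rather than raw
intensities — confocal fluorescence and micro-CT grey values are not
comparable, but the reconstructed neuropil shapes are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelField, RegistrationFailedError, Volume
from .isa import AtlasModel
from .phantoms import ConfocalStack
from .registration import (
    AffineParams,
    NMIConfig,
    TransformChain,
    apply_transform,
    register_affine,
    register_bspline,
)

log = logging.getLogger(__name__)

__all__ = ["ConfocalStack", "NeuronRegistrationResult", "register_neuron_stack"]


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom) if denom else 0.0


def _blurred_mask_image(labels: np.ndarray, ids: list[int], sigma_vox: float, voxel_size) -> np.ndarray:
    """Distinct grey level per landmark, Gaussian-blurred (sigma in voxels of
    the smallest axis, scaled per axis for anisotropic grids)."""
    img = np.zeros(labels.shape, dtype=np.float64)
    for k, lid in enumerate(sorted(ids), start=1):
        img[labels == lid] = 255.0 * k / len(ids)
    v = np.asarray(voxel_size, dtype=np.float64)
    sig = sigma_vox * v.min() / v
    return ndimage.gaussian_filter(img, sig)


@dataclass
class NeuronRegistrationResult:
    """Neuron channel in atlas coordinates plus the chain and per-landmark Dice."""

    neuron: Volume
    atlas_labels_confocal: LabelField
    chain: TransformChain
    dice_affine: dict[str, float]
    dice_elastic: dict[str, float]


def register_neuron_stack(
    stack: ConfocalStack,
    atlas: AtlasModel,
    config: NMIConfig | None = None,
    blur_sigma_vox: float = 1.5,
    elastic_spacing_factor: float = 8.0,
    sample_stride: int = 2,
) -> NeuronRegistrationResult:
    """Register a confocal stack into the atlas and transfer its neuron channel.

    Steps: (1) 12-DOF affine of the stack's landmark masks onto the matching
    atlas labels; (2) atlas labels resampled to the confocal voxel grid;
    (3) B-spline elastic refinement on the masks; (4) chain applied to the
    neuron channel.  The output grid is the atlas domain sampled at confocal
    resolution, so coordinates remain atlas-physical.

    Raises ``ValueError`` for a stack landmark with no atlas counterpart and
    ``RegistrationFailedError`` if the affine stage finds no overlap.
    """
    if atlas.fused_labels is None:
        raise ValueError("atlas has no fused labels")
    config = config or NMIConfig()
    atlas_ids = set(np.unique(atlas.fused_labels.data).tolist()) - {0}
    stack_ids = sorted(set(np.unique(stack.landmarks.data).tolist()) - {0})
    missing = [lid for lid in stack_ids if lid not in atlas_ids]
    if missing:
        names = [stack.landmarks.catalog.get(m, str(m)) for m in missing]
        raise ValueError(f"stack landmarks {names} have no matching atlas label")

    atlas_voxel = atlas.fused_labels.voxel_size
    fixed_mask = Volume(
        _blurred_mask_image(atlas.fused_labels.data, stack_ids, blur_sigma_vox, atlas_voxel),
        atlas_voxel,
    )
    moving_mask = Volume(
        _blurred_mask_image(stack.landmarks.data, stack_ids, blur_sigma_vox, stack.landmarks.voxel_size),
        stack.landmarks.voxel_size,
    )
    affine, score = register_affine(fixed_mask, moving_mask, dof=12, config=config)
    if not np.isfinite(score):
        raise RegistrationFailedError("affine landmark registration found no overlap")
    log.info("neuron affine score=%.5f", score)
    chain = TransformChain(affine)

    # atlas domain resampled at confocal resolution
    conf_voxel = stack.landmarks.voxel_size
    extent = atlas.fused_labels.physical_extent() if hasattr(atlas.fused_labels, "physical_extent") else tuple(
        n * v for n, v in zip(atlas.fused_labels.shape, atlas_voxel)
    )
    out_shape = tuple(max(1, int(round(e / v))) for e, v in zip(extent, conf_voxel))
    atlas_conf = apply_transform(
        atlas.fused_labels, TransformChain.identity(), out_shape=out_shape, out_voxel=conf_voxel
    )
    fixed_conf = Volume(
        _blurred_mask_image(atlas_conf.data, stack_ids, blur_sigma_vox, conf_voxel), conf_voxel
    )

    def per_landmark_dice(ch: TransformChain) -> dict[str, float]:
        warped = apply_transform(stack.landmarks, ch, out_shape=out_shape, out_voxel=conf_voxel)
        return {
            stack.landmarks.catalog[lid]: _dice(warped.data == lid, atlas_conf.data == lid)
            for lid in stack_ids
        }

    # refine the affine against the confocal-resolution atlas masks: the
    # coarse atlas grid limits the first pass's accuracy under anisotropy
    affine, score = register_affine(
        fixed_conf, moving_mask, dof=12, init=affine, config=config, levels=(4, 2)
    )
    log.info("neuron affine refinement score=%.5f", score)
    chain = TransformChain(affine)
    dice_affine = per_landmark_dice(chain)
    spacing = tuple(max(e / elastic_spacing_factor, 4.0 * v) for e, v in zip(extent, conf_voxel))
    grid, el_score = register_bspline(
        fixed_conf, moving_mask, chain, spacing, config=config, sample_stride=sample_stride
    )
    chain = chain.with_grid(grid)
    log.info("neuron elastic spacing=%s score=%.5f", np.round(spacing, 1), el_score)
    dice_elastic = per_landmark_dice(chain)

    neuron_out = apply_transform(
        stack.neuron, chain, "linear", out_shape=out_shape, out_voxel=conf_voxel
    )
    return NeuronRegistrationResult(
        neuron=neuron_out,
        atlas_labels_confocal=atlas_conf,
        chain=chain,
        dice_affine=dice_affine,
        dice_elastic=dice_elastic,
    )
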