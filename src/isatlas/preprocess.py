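"""Per-specimen preparation before registration.

Mirrors the interactive brain-extraction workflow: a sparse scaffold of
2D outlines in the three orthogonal planes is turned into a watertight brain
mask; everything outside is set to 0; the remaining intensities are stretched
to the full 8-bit range; and neuropil outlines drawn on every 4th–6th XY
slice are completed into dense label fields by distance-map interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DimensionError, LabelField, Volume, require_same_grid
from .fusion import signed_distance_map


@dataclass
class SparseAnnotation:
    """Sparse per-plane 2D masks marking a structure's outline.

    ``xy[k]`` is a 2D array over (x, y) at slice z=k; ``xz[j]`` over (x, z) at
    y=j; ``yz[i]`` over (y, z) at x=i.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    xy: dict[int, np.ndarray] = field(default_factory=dict)
    xz: dict[int, np.ndarray] = field(default_factory=dict)
    yz: dict[int, np.ndarray] = field(default_factory=dict)

    def to_volume_mask(self) -> np.ndarray:
        """Union of all annotated voxels as a 3D boolean array."""
        nx, ny, nz = self.shape
        out = np.zeros(self.shape, dtype=bool)
        for k, m in self.xy.items():
            if not (0 <= k < nz) or m.shape != (nx, ny):
                raise DimensionError(f"XY annotation at z={k} does not fit grid {self.shape}")
            out[:, :, k] |= m.astype(bool)
        for j, m in self.xz.items():
            if not (0 <= j < ny) or m.shape != (nx, nz):
                raise DimensionError(f"XZ annotation at y={j} does not fit grid {self.shape}")
            out[:, j, :] |= m.astype(bool)
        for i, m in self.yz.items():
            if not (0 <= i < nx) or m.shape != (ny, nz):
                raise DimensionError(f"YZ annotation at x={i} does not fit grid {self.shape}")
            out[i, :, :] |= m.astype(bool)
        return out


def _ball(radius_vox: int) -> np.ndarray:
    if radius_vox <= 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius_vox)
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x * x + y * y + z * z <= r * r


def mask_from_scaffold(annotation: SparseAnnotation, closing_radius_um: float) -> Volume:
    """Shrink-wrap a sparse outline scaffold into a watertight brain mask.

    Union of annotated voxels → morphological closing with a ball of the
    given radius → hole filling → largest connected component (re-united with
    any annotated voxels that fell outside it, so the mask always contains
    the scaffold).
    """
    seed = annotation.to_volume_mask()
    if not seed.any():
        raise ValueError("empty annotation: no voxels marked in any plane")
    r_vox = int(round(closing_radius_um / annotation.voxel_size))
    if r_vox > 0:
        ball = _ball(r_vox)
        padded = np.pad(seed, r_vox + 1)
        closed = ndimage.binary_closing(padded, structure=ball)
        sl = (slice(r_vox + 1, -(r_vox + 1)),) * 3
        closed = closed[sl]
    else:
        closed = seed.copy()
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        filled = labels == (int(np.argmax(sizes)) + 1)
    mask = filled | seed
    return Volume(mask.astype(np.uint8) * np.uint8(1), annotation.voxel_size)


def apply_mask(volume: Volume, mask: Volume) -> Volume:
    """Zero out all voxels outside the mask (the arithmetic cropping step)."""
    require_same_grid(volume, mask, "volume and mask")
    out = np.where(mask.data > 0, volume.data, 0)
    return Volume(out.astype(volume.data.dtype), volume.voxel_size)


def normalize_intensity(volume: Volume, percentile_clip: float | None = None) -> Volume:
    """Stretch nonzero intensities linearly to [0, 255] (uint8, half-up rounding).

    Statistics are computed over nonzero voxels only so that the forced-zero
    background from masking does not pin the minimum.  ``percentile_clip``
    optionally clips the stretch range to the (p, 100-p) percentiles first
    (off by default).
    """
    data = volume.data.astype(np.float64)
    nz = data != 0
    vals = data[nz]
    if vals.size == 0:
        raise ValueError("cannot normalize: volume has no nonzero voxels")
    if percentile_clip is not None:
        lo = float(np.percentile(vals, percentile_clip))
        hi = float(np.percentile(vals, 100.0 - percentile_clip))
    else:
        lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise ValueError(
            f"cannot normalize: nonzero region is constant (value {lo}); "
            "a degenerate input has no dynamic range to stretch"
        )
    out = np.zeros_like(data)
    stretched = (np.clip(data[nz], lo, hi) - lo) / (hi - lo) * 255.0
    out[nz] = np.floor(stretched + 0.5)
    return Volume(out.astype(np.uint8), volume.voxel_size)


def interpolate_labels(sparse: LabelField, annotated_slices: list[int]) -> LabelField:
    """Complete a label field annotated on a subset of XY slices.

    For each label, consecutive annotated slices are bridged by linearly
    interpolating their 2D signed Euclidean distance maps and thresholding at
    0; overlapping claims go to the label with the smallest interpolated
    distance.  Annotated slices are preserved verbatim.  A label present on
    only one end of an interval claims only the half of the interval nearer
    to it (nearest-slice copy), with a warning if it appears on a single
    annotated slice overall.
    """
    annotated = sorted(set(int(k) for k in annotated_slices))
    nz = sparse.shape[2]
    if not annotated or annotated[0] < 0 or annotated[-1] >= nz:
        raise ValueError(f"annotated slice indices {annotated} outside grid with nz={nz}")
    out = np.zeros(sparse.shape, dtype=np.int32)
    for k in annotated:
        out[:, :, k] = sparse.data[:, :, k]

    label_ids = sorted(sparse.catalog)
    slice_counts = {
        lid: sum(1 for k in annotated if (sparse.data[:, :, k] == lid).any()) for lid in label_ids
    }
    for lid, cnt in slice_counts.items():
        if cnt == 1:
            warnings.warn(
                f"label {lid} ({sparse.catalog[lid]}) appears on a single annotated slice; "
                "using nearest-slice copy", stacklevel=2,
            )

    big = float(max(sparse.shape)) * max(sparse.voxel_size)  # "very far outside" stand-in
    vs2d = (sparse.voxel_size[0], sparse.voxel_size[1])

    def sdm2d(mask: np.ndarray) -> np.ndarray | None:
        if not mask.any() or mask.all():
            return None
        return signed_distance_map(mask, vs2d)

    for z0, z1 in zip(annotated[:-1], annotated[1:]):
        gap = z1 - z0
        if gap <= 1:
            continue
        best = np.full((sparse.shape[0], sparse.shape[1], gap - 1), np.inf)
        chosen = np.zeros_like(best, dtype=np.int32)
        for lid in label_ids:
            d0 = sdm2d(sparse.data[:, :, z0] == lid)
            d1 = sdm2d(sparse.data[:, :, z1] == lid)
            if d0 is None and d1 is None:
                continue
            for j, z in enumerate(range(z0 + 1, z1)):
                t = (z - z0) / gap
                if d0 is not None and d1 is not None:
                    d = (1 - t) * d0 + t * d1
                elif d0 is not None:
                    d = d0 if t < 0.5 else np.full_like(d0, big)
                else:
                    d = d1 if t >= 0.5 else np.full_like(d1, big)
                take = (d < 0) & (d < best[:, :, j])
                chosen[:, :, j][take] = lid
                best[:, :, j][take] = d[take]
        out[:, :, z0 + 1 : z1] = chosen
    return LabelField(out, sparse.voxel_size, dict(sparse.catalog))
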