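"""Reading and writing volumes, label fields and tables.

Two on-disk representations are supported:

* 8-bit greyscale image series (BMP/PNG/TIFF), one file per z-slice, sorted
  lexicographically — the export format of the micro-CT reconstruction step.
* NRRD single-file volumes with voxel spacing in the header; label fields get
  a JSON sidecar (``<stem>.labels.json``) holding the id → name catalog.

The in-memory axis convention is ``(x, y, z)`` (see :mod:`isatlas.core`); a
2D slice file stores rows = y, columns = x, so slices are transposed on the
way in and out.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import DimensionError, LabelField, Volume

_SERIES_EXTS = {".bmp", ".png", ".tif", ".tiff"}


def read_image_series(directory: str | os.PathLike, pattern: str = "*", voxel_size_um: float = 3.9) -> Volume:
    """Stack a lexicographically sorted 2D image series into a uint8 volume.

    Slice ``k`` of the sorted series becomes plane ``z = k``.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.glob(pattern) if p.suffix.lower() in _SERIES_EXTS)
    if not files:
        raise FileNotFoundError(f"no image slices matching {pattern!r} in {directory}")
    slices = []
    for p in files:
        img = np.asarray(iio.imread(p))
        if img.ndim == 3:  # greyscale saved with redundant channels
            img = img[..., 0]
        if img.dtype != np.uint8:
            raise ValueError(f"{p.name}: expected 8-bit greyscale, got dtype {img.dtype}")
        slices.append(img)
    shape0 = slices[0].shape
    for p, s in zip(files, slices):
        if s.shape != shape0:
            raise DimensionError(f"slice {p.name} has shape {s.shape}, expected {shape0}")
    # slice array is (rows=y, cols=x); volume is (x, y, z)
    data = np.stack([s.T for s in slices], axis=2)
    return Volume(np.ascontiguousarray(data), voxel_size_um)


def write_image_series(volume: Volume, directory: str | os.PathLike, prefix: str = "slice", ext: str = ".png") -> list[Path]:
    """Write a uint8 volume as one 2D image per z-slice (PNG by default)."""
    if volume.data.dtype != np.uint8:
        raise ValueError("image series output requires a uint8 volume")
    if ext.lower() not in _SERIES_EXTS:
        raise ValueError(f"unsupported series extension {ext!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(volume.shape[2] - 1)))
    paths = []
    for k in range(volume.shape[2]):
        p = directory / f"{prefix}{k:0{width}d}{ext}"
        iio.imwrite(p, np.ascontiguousarray(volume.data[:, :, k].T))
        paths.append(p)
    return paths


def _catalog_sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".labels.json")


def write_nrrd(path: str | os.PathLike, obj: Volume | LabelField) -> None:
    """Write a volume or label field as NRRD; label catalogs go to a JSON sidecar."""
    path = Path(path)
    data = obj.data
    if isinstance(obj, LabelField):
        data = data.astype(np.int32, copy=False)
    # SimpleITK images index (x, y, z) via GetPixel but store arrays as (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(v) for v in obj.voxel_size))
    sitk.WriteImage(img, str(path), useCompression=False)
    if isinstance(obj, LabelField):
        with open(_catalog_sidecar(path), "w") as fh:
            json.dump({str(k): v for k, v in obj.catalog.items()}, fh, indent=1, sort_keys=True)


def read_nrrd(path: str | os.PathLike, allow_anisotropic: bool = False) -> Volume | LabelField:
    """Read an NRRD file written by :func:`write_nrrd`.

    Integer-typed files with a catalog sidecar come back as
    :class:`LabelField`; everything else as :class:`Volume`.  Anisotropic
    spacing is rejected unless ``allow_anisotropic`` is set, because the
    averaging pipeline assumes isotropic micro-CT grids (confocal-like inputs
    are the exception).
    """
    path = Path(path)
    img = sitk.ReadImage(str(path))
    spacing = tuple(float(v) for v in img.GetSpacing())
    if not allow_anisotropic and (abs(spacing[0] - spacing[1]) > 1e-9 or abs(spacing[0] - spacing[2]) > 1e-9):
        raise ValueError(
            f"{path.name}: anisotropic spacing {spacing} — the pipeline requires isotropic voxels; "
            "pass allow_anisotropic=True for confocal-like inputs"
        )
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    sidecar = _catalog_sidecar(path)
    if np.issubdtype(data.dtype, np.integer) and data.dtype != np.uint8 and sidecar.exists():
        with open(sidecar) as fh:
            catalog = {int(k): v for k, v in json.load(fh).items()}
        return LabelField(data, spacing, catalog)
    return Volume(np.ascontiguousarray(data), spacing)


def resample_isotropic(volume: Volume, target_voxel_um: float, interpolation: str = "linear") -> Volume:
    """Resample to a new isotropic voxel size, preserving physical extent.

    ``nearest`` must be used for label-like data so no new values are
    invented; ``linear`` is the intensity default.
    """
    if target_voxel_um <= 0:
        raise ValueError(f"target voxel size must be positive, got {target_voxel_um}")
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"interpolation must be 'nearest' or 'linear', got {interpolation!r}")
    if volume.is_isotropic and abs(volume.voxel_size[0] - target_voxel_um) < 1e-12:
        return volume.copy()
    new_shape = tuple(
        max(1, int(round(n * v / target_voxel_um))) for n, v in zip(volume.shape, volume.voxel_size)
    )
    # voxel-centred sampling of the input grid at the output grid's positions
    coords = np.meshgrid(
        *[np.arange(m) * target_voxel_um / v for m, v in zip(new_shape, volume.voxel_size)],
        indexing="ij",
    )
    order = 0 if interpolation == "nearest" else 1
    src = volume.data.astype(np.float64, copy=False)
    out = ndimage.map_coordinates(src, np.stack(coords), order=order, mode="nearest")
    if volume.data.dtype == np.uint8:
        out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return Volume(out, target_voxel_um)


def write_catalog(path: str | os.PathLike, catalog: dict[int, str]) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): v for k, v in catalog.items()}, fh, indent=1, sort_keys=True)


def read_catalog(path: str | os.PathLike) -> dict[int, str]:
    with open(path) as fh:
        return {int(k): v for k, v in json.load(fh).items()}
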