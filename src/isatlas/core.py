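"""Core containers for the atlas pipeline.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(x, y, z)`` where ``z`` is the slice index of an
  exported 2D image series ("virtual frontal" slices stacked along z).
* Coordinates are voxel-centred and 0-based; the physical position of voxel
  ``(i, j, k)`` is ``(i * dx, j * dy, k * dz)`` in micrometres.
* Label 0 is reserved for background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class DimensionError(ValueError):
    """Array shapes or grids do not match the operation's contract."""


class OverlapError(RuntimeError):
    """No fixed-image voxel maps inside the moving image domain."""


class RegistrationFailedError(RuntimeError):
    """Registration could not produce a transform (e.g. no overlap at any level)."""


class SpecError(ValueError):
    """A synthetic phantom specification is internally inconsistent."""


def _as_spacing(voxel_size: float | Sequence[float]) -> tuple[float, float, float]:
    if np.isscalar(voxel_size):
        v = float(voxel_size)  # type: ignore[arg-type]
        spacing = (v, v, v)
    else:
        spacing = tuple(float(v) for v in voxel_size)  # type: ignore[union-attr]
        if len(spacing) != 3:
            raise ValueError(f"voxel_size must be a scalar or length-3, got {voxel_size!r}")
    if any(v <= 0 for v in spacing):
        raise ValueError(f"voxel size must be positive, got {spacing}")
    return spacing  # type: ignore[return-value]


@dataclass
class Volume:
    """A 3D scalar grid with voxel size in µm.

    ``data`` has shape ``(nx, ny, nz)``.  ``voxel_size`` may be given as a
    scalar (isotropic, the micro-CT case) or a per-axis triple (needed for
    confocal stacks); it is stored as a triple.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __init__(self, data: np.ndarray, voxel_size: float | Sequence[float]):
        data = np.asarray(data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise DimensionError(f"volume data must be 3D and nonempty, got shape {data.shape}")
        self.data = data
        self.voxel_size = _as_spacing(voxel_size)
        if data.dtype == np.uint8:
            pass  # uint8 is always in [0, 255]
        elif np.issubdtype(data.dtype, np.integer):
            self.data = data.astype(np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        dx, dy, dz = self.voxel_size
        return abs(dx - dy) < 1e-9 and abs(dx - dz) < 1e-9

    @property
    def isotropic_voxel(self) -> float:
        if not self.is_isotropic:
            raise ValueError(f"volume is anisotropic: {self.voxel_size}")
        return self.voxel_size[0]

    @property
    def dtype_tag(self) -> str:
        return "uint8" if self.data.dtype == np.uint8 else "float"

    def physical_extent(self) -> tuple[float, float, float]:
        """Extent in µm spanned by voxel centres plus one voxel per axis."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size)


@dataclass
class LabelField:
    """Integer compartment map over a :class:`Volume` grid.

    ``catalog`` maps each nonzero label id to a structure name (e.g. ``LA-l``,
    ``ME-r``, ``CX``, ``RN``).  Label 0 is background and never catalogued.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    catalog: dict[int, str]

    def __init__(
        self,
        data: np.ndarray,
        voxel_size: float | Sequence[float],
        catalog: Mapping[int, str],
    ):
        data = np.asarray(data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise DimensionError(f"label data must be 3D and nonempty, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"label data must be integer, got dtype {data.dtype}")
        self.data = data.astype(np.int32, copy=False)
        self.voxel_size = _as_spacing(voxel_size)
        self.catalog = {int(k): str(v) for k, v in catalog.items()}
        if 0 in self.catalog:
            raise ValueError("label 0 is reserved for background and cannot be catalogued")
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.catalog)
        if missing:
            raise ValueError(f"label ids {sorted(missing)} present in data but absent from catalog")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def isotropic_voxel(self) -> float:
        dx, dy, dz = self.voxel_size
        if abs(dx - dy) > 1e-9 or abs(dx - dz) > 1e-9:
            raise ValueError(f"label field is anisotropic: {self.voxel_size}")
        return dx

    def mask(self, label_id: int) -> np.ndarray:
        return self.data == label_id

    def ids_by_name(self) -> dict[str, int]:
        return {v: k for k, v in self.catalog.items()}

    def copy(self) -> "LabelField":
        return LabelField(self.data.copy(), self.voxel_size, dict(self.catalog))


@dataclass
class SpecimenSet:
    """An ordered cohort of (intensity, labels) specimen pairs on one voxel size."""

    volumes: list[Volume]
    labels: list[LabelField | None]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.volumes) < 2:
            raise ValueError(f"a specimen set needs >= 2 specimens, got {len(self.volumes)}")
        if len(self.labels) != len(self.volumes):
            raise ValueError("one label field slot per volume required (may be None)")
        if not self.ids:
            self.ids = [f"specimen{i:02d}" for i in range(len(self.volumes))]
        v0 = self.volumes[0].voxel_size
        for v in self.volumes:
            if not np.allclose(v.voxel_size, v0):
                raise ValueError("all specimens must share one voxel size")
        for lab in self.labels:
            if lab is not None and not np.allclose(lab.voxel_size, v0):
                raise ValueError("label fields must share the cohort voxel size")

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.volumes[0].voxel_size


def require_same_grid(a, b, what: str = "operands") -> None:
    if a.shape != b.shape:
        raise DimensionError(f"{what} have different shapes: {a.shape} vs {b.shape}")


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer with .5 always rounding up (platform-stable)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)
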