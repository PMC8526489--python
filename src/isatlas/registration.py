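"""Intensity-based 3D registration: NMI metric, affine and B-spline FFD.

Transforms map *fixed-space physical coordinates to moving-space physical
coordinates* (pull-back resampling): to resample a moving image onto the
fixed grid, every fixed voxel centre is pushed through the chain and the
moving image is interpolated there.

The similarity metric is normalized mutual information in the
Studholme form ``NMI = (H(A) + H(B)) / H(A, B)`` with Shannon entropies
(natural log) of a joint intensity histogram; it ranges over [1, 2] and is
maximal for a deterministic intensity relationship.  Optimization is
derivative-free coordinate descent with halving step schedules — robust
without analytic NMI gradients and fully deterministic.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import (
    LabelField,
    OverlapError,
    RegistrationFailedError,
    Volume,
)

# --------------------------------------------------------------------------
# transform parameterizations
# --------------------------------------------------------------------------

_PARAM_NAMES = ("tx", "ty", "tz", "rx", "ry", "rz", "sx", "sy", "sz", "hxy", "hxz", "hyz")


@dataclass
class AffineParams:
    """12-parameter affine transform with 6/9/12-DOF subsets.

    Order of application to a centred point q = p - center:
    scale, shear, rotation (intrinsic Z-Y-X Euler), then translation:
    ``A(p) = R @ H @ S @ (p - center) + center + t``.
    Translations and the rotation center are in µm.
    """

    t: tuple[float, float, float] = (0.0, 0.0, 0.0)
    r: tuple[float, float, float] = (0.0, 0.0, 0.0)
    s: tuple[float, float, float] = (1.0, 1.0, 1.0)
    h: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dof: int = 6
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.dof not in (6, 9, 12):
            raise ValueError(f"dof must be 6, 9 or 12, got {self.dof}")
        if any(v <= 0 for v in self.s):
            raise ValueError(f"scales must be positive, got {self.s}")
        if self.dof == 6 and (self.s != (1.0, 1.0, 1.0) or self.h != (0.0, 0.0, 0.0)):
            raise ValueError("dof=6 requires unit scale and zero shear")
        if self.dof == 9 and self.h != (0.0, 0.0, 0.0):
            raise ValueError("dof=9 requires zero shear")

    # -- matrix form -------------------------------------------------------
    def linear(self) -> np.ndarray:
        rx, ry, rz = self.r
        cx, sx = math.cos(rx), math.sin(rx)
        cy, sy = math.cos(ry), math.sin(ry)
        cz, sz = math.cos(rz), math.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        S = np.diag(self.s)
        H = np.array([[1.0, self.h[0], self.h[1]], [0, 1.0, self.h[2]], [0, 0, 1.0]])
        return Rz @ Ry @ Rx @ H @ S

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix mapping fixed physical µm to moving physical µm."""
        L = self.linear()
        c = np.asarray(self.center, dtype=np.float64)
        t = np.asarray(self.t, dtype=np.float64)
        M = np.eye(4)
        M[:3, :3] = L
        M[:3, 3] = c + t - L @ c
        return M

    # -- optimizer packing -------------------------------------------------
    def to_vector(self) -> np.ndarray:
        full = np.array([*self.t, *self.r, *self.s, *self.h], dtype=np.float64)
        return full[: self.dof]

    def with_vector(self, v: np.ndarray) -> "AffineParams":
        full = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=np.float64)
        full[: self.dof] = v
        return AffineParams(
            t=tuple(full[0:3]), r=tuple(full[3:6]), s=tuple(full[6:9]), h=tuple(full[9:12]),
            dof=self.dof, center=self.center,
        )

    @staticmethod
    def identity(dof: int = 6, center=(0.0, 0.0, 0.0)) -> "AffineParams":
        return AffineParams(dof=dof, center=tuple(float(c) for c in center))

    def promoted(self, dof: int) -> "AffineParams":
        """Re-tag with a higher DOF count (parameters unchanged)."""
        if dof < self.dof:
            raise ValueError("cannot demote an affine transform")
        return replace(self, dof=dof)

    def to_dict(self) -> dict:
        return {
            "type": "affine", "dof": self.dof,
            "t": list(self.t), "r": list(self.r), "s": list(self.s), "h": list(self.h),
            "center": list(self.center),
        }

    @staticmethod
    def from_dict(d: dict) -> "AffineParams":
        return AffineParams(
            t=tuple(d["t"]), r=tuple(d["r"]), s=tuple(d["s"]), h=tuple(d["h"]),
            dof=int(d["dof"]), center=tuple(d["center"]),
        )


class BSplineGrid:
    """Cubic B-spline free-form deformation over the fixed image domain.

    Control points sit on a lattice with per-axis spacing (µm); point ``i``
    lies at physical position ``(i - 1) * spacing`` so the lattice covers the
    domain plus a one-cell margin on each side.  ``coeffs`` holds one µm
    displacement 3-vector per control point, shape ``(ncx, ncy, ncz, 3)``.
    """

    def __init__(self, spacing, coeffs: np.ndarray):
        self.spacing = tuple(float(v) for v in (spacing if np.iterable(spacing) else (spacing,) * 3))
        coeffs = np.asarray(coeffs, dtype=np.float64)
        if coeffs.ndim != 4 or coeffs.shape[3] != 3:
            raise ValueError(f"coeffs must have shape (ncx, ncy, ncz, 3), got {coeffs.shape}")
        self.coeffs = coeffs

    @staticmethod
    def for_domain(extent_um, spacing, voxel_size) -> "BSplineGrid":
        spacing = tuple(float(v) for v in (spacing if np.iterable(spacing) else (spacing,) * 3))
        for sp, v in zip(spacing, voxel_size):
            if sp < 4 * v - 1e-9:
                raise ValueError(f"control spacing {sp} µm < 4 voxels ({4 * v} µm)")
        nctrl = tuple(int(math.ceil(e / sp)) + 3 for e, sp in zip(extent_um, spacing))
        return BSplineGrid(spacing, np.zeros(nctrl + (3,)))

    def lattice_coords(self, phys: np.ndarray) -> np.ndarray:
        """Physical µm positions (3, ...) to lattice coordinates (control index space)."""
        out = np.empty_like(phys, dtype=np.float64)
        for a in range(3):
            out[a] = phys[a] / self.spacing[a] + 1.0
        return out

    def displacement(self, phys: np.ndarray) -> np.ndarray:
        """Evaluate the FFD displacement (µm) at physical positions (3, ...)."""
        u = self.lattice_coords(np.asarray(phys, dtype=np.float64))
        out = np.empty_like(u)
        for a in range(3):
            out[a] = ndimage.map_coordinates(
                self.coeffs[..., a], u, order=3, prefilter=False, mode="nearest"
            )
        return out

    def to_dict(self) -> dict:
        return {
            "type": "bspline", "spacing": list(self.spacing),
            "shape": list(self.coeffs.shape[:3]),
            "coeffs": [round(float(c), 9) for c in self.coeffs.ravel()],
        }

    @staticmethod
    def from_dict(d: dict) -> "BSplineGrid":
        coeffs = np.array(d["coeffs"], dtype=np.float64).reshape(tuple(d["shape"]) + (3,))
        return BSplineGrid(tuple(d["spacing"]), coeffs)


@dataclass
class TransformChain:
    """One affine followed by zero or more B-spline refinements.

    Total map ``x -> A(x) + sum_g d_g(x)`` with every ``d_g`` evaluated at the
    fixed-space position ``x``.
    """

    affine: AffineParams
    grids: list[BSplineGrid] = field(default_factory=list)

    def map_points(self, phys: np.ndarray) -> np.ndarray:
        """Map fixed-space physical positions (3, ...) to moving space."""
        phys = np.asarray(phys, dtype=np.float64)
        M = self.affine.matrix()
        flat = phys.reshape(3, -1)
        out = M[:3, :3] @ flat + M[:3, 3:4]
        out = out.reshape(phys.shape)
        for g in self.grids:
            out = out + g.displacement(phys)
        return out

    def with_grid(self, grid: BSplineGrid) -> "TransformChain":
        return TransformChain(self.affine, self.grids + [grid])

    def to_dict(self) -> dict:
        return {"version": 1, "affine": self.affine.to_dict(), "grids": [g.to_dict() for g in self.grids]}

    @staticmethod
    def from_dict(d: dict) -> "TransformChain":
        return TransformChain(
            AffineParams.from_dict(d["affine"]),
            [BSplineGrid.from_dict(g) for g in d.get("grids", [])],
        )

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @staticmethod
    def load(path: str | os.PathLike) -> "TransformChain":
        with open(path) as fh:
            return TransformChain.from_dict(json.load(fh))

    @staticmethod
    def identity(center=(0.0, 0.0, 0.0), dof: int = 6) -> "TransformChain":
        return TransformChain(AffineParams.identity(dof, center))


# --------------------------------------------------------------------------
# NMI metric
# --------------------------------------------------------------------------

@dataclass
class NMIConfig:
    """Histogram settings for the NMI metric.

    ``exclude_zero_pairs`` drops voxel pairs where both intensities are
    exactly 0 — after brain extraction the background is forced to 0 and
    would otherwise dominate the joint histogram.
    """

    bins: int = 64
    exclude_zero_pairs: bool = True
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError(f"bins must be >= 2, got {self.bins}")
        if self.interpolation not in ("nearest", "linear"):
            raise ValueError(f"interpolation must be 'nearest' or 'linear', got {self.interpolation}")


def _intensity_range(data: np.ndarray) -> tuple[float, float]:
    if data.dtype == np.uint8:
        return 0.0, 255.0
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def _bin_values(values: np.ndarray, lo: float, hi: float, bins: int) -> np.ndarray:
    idx = np.floor((values.astype(np.float64) - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def _fixed_phys_grid(volume: Volume) -> np.ndarray:
    ax = [np.arange(n, dtype=np.float64) * v for n, v in zip(volume.shape, volume.voxel_size)]
    return np.stack(np.meshgrid(*ax, indexing="ij"))


def _sample_moving(moving: Volume, phys: np.ndarray, interpolation: str):
    """Sample moving intensities at moving-space physical positions.

    Returns (values, in_domain) where out-of-domain positions carry
    nearest-edge values but are flagged invalid.
    """
    idx = np.empty_like(phys)
    for a in range(3):
        idx[a] = phys[a] / moving.voxel_size[a]
    valid = np.ones(phys.shape[1:], dtype=bool)
    for a in range(3):
        valid &= (idx[a] >= 0) & (idx[a] <= moving.shape[a] - 1)
    order = 0 if interpolation == "nearest" else 1
    vals = ndimage.map_coordinates(
        moving.data.astype(np.float64, copy=False), idx, order=order, mode="nearest"
    )
    return vals, valid


def joint_histogram(
    fixed: Volume, moving: Volume, chain: TransformChain, config: NMIConfig | None = None
) -> np.ndarray:
    """Joint intensity histogram (bins × bins) of fixed vs transformed moving.

    Counts run over fixed-grid voxels whose mapped position lands inside the
    moving domain; both-zero pairs are dropped when configured.
    """
    config = config or NMIConfig()
    phys = _fixed_phys_grid(fixed)
    mapped = chain.map_points(phys)
    mvals, valid = _sample_moving(moving, mapped, config.interpolation)
    fvals = fixed.data.astype(np.float64, copy=False)
    keep = valid
    if config.exclude_zero_pairs:
        keep = keep & ~((fvals == 0) & (mvals == 0))
    if not keep.any():
        raise OverlapError("no overlapping voxel pairs between fixed and transformed moving image")
    flo, fhi = _intensity_range(fixed.data)
    mlo, mhi = _intensity_range(moving.data)
    fb = _bin_values(fvals[keep], flo, fhi, config.bins)
    mb = _bin_values(mvals[keep], mlo, mhi, config.bins)
    hist = np.bincount(fb * config.bins + mb, minlength=config.bins * config.bins)
    return hist.reshape(config.bins, config.bins).astype(np.float64)


def _nmi_from_hist(hist: np.ndarray) -> float:
    n = hist.sum()
    if n == 0:
        raise OverlapError("empty joint histogram")
    p = hist / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h_ab = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
        pa = p.sum(axis=1)
        pb = p.sum(axis=0)
        h_a = float(-np.sum(np.where(pa > 0, pa * np.log(pa), 0.0)))
        h_b = float(-np.sum(np.where(pb > 0, pb * np.log(pb), 0.0)))
    if h_ab <= 1e-15:
        return 2.0  # single occupied cell: perfect (degenerate) dependence
    return (h_a + h_b) / h_ab


def nmi(fixed: Volume, moving: Volume, chain: TransformChain | None = None, config: NMIConfig | None = None) -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B) in [1, 2]."""
    chain = chain or TransformChain.identity()
    return _nmi_from_hist(joint_histogram(fixed, moving, chain, config))


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def apply_transform(
    obj: Volume | LabelField,
    chain: TransformChain,
    interpolation: str | None = None,
    out_shape: tuple[int, int, int] | None = None,
    out_voxel=None,
):
    """Resample a volume or label field onto the fixed grid through a chain.

    The output grid defaults to the input's own grid (the cohort case where
    all specimens share one grid).  Labels are always sampled with nearest
    interpolation and out-of-domain voxels become 0/background.
    """
    is_labels = isinstance(obj, LabelField)
    if is_labels:
        if interpolation not in (None, "nearest"):
            raise ValueError("label fields must be resampled with nearest interpolation")
        interpolation = "nearest"
    else:
        interpolation = interpolation or "linear"
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    out_shape = out_shape or obj.shape
    out_voxel = tuple(float(v) for v in (out_voxel if out_voxel is not None else obj.voxel_size))
    ax = [np.arange(n, dtype=np.float64) * v for n, v in zip(out_shape, out_voxel)]
    phys = np.stack(np.meshgrid(*ax, indexing="ij"))
    mapped = chain.map_points(phys)
    idx = np.empty_like(mapped)
    for a in range(3):
        idx[a] = mapped[a] / obj.voxel_size[a]
    order = 0 if interpolation == "nearest" else 1
    if is_labels:
        out = ndimage.map_coordinates(obj.data, idx, order=0, mode="constant", cval=0)
        return LabelField(out.astype(np.int32), out_voxel, dict(obj.catalog))
    out = ndimage.map_coordinates(
        obj.data.astype(np.float64, copy=False), idx, order=order, mode="constant", cval=0.0
    )
    if obj.data.dtype == np.uint8:
        out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return Volume(out, out_voxel)


def _downsample(volume: Volume, factor: int) -> Volume:
    if factor == 1:
        return volume  # keep dtype: the histogram range depends on it
    sm = ndimage.gaussian_filter(volume.data.astype(np.float64), sigma=factor / 2.0)
    data = sm[::factor, ::factor, ::factor]
    return Volume(data, tuple(v * factor for v in volume.voxel_size))


# --------------------------------------------------------------------------
# affine registration
# --------------------------------------------------------------------------

class _AffineObjective:
    """NMI of fixed vs moving under a parameter vector, on one pyramid level.

    Guards against the small-overlap pathology of NMI (the score rises as the
    images are pushed apart and the joint histogram degenerates): candidates
    keeping fewer than a quarter of the pairs kept by the starting transform
    — or collapsing the histogram to a single cell — score -inf.
    """

    def __init__(self, fixed: Volume, moving: Volume, config: NMIConfig):
        self.moving = moving
        self.config = config
        self.phys = _fixed_phys_grid(fixed).reshape(3, -1)
        fvals = fixed.data.reshape(-1).astype(np.float64)
        flo, fhi = _intensity_range(fixed.data)
        self.fb = _bin_values(fvals, flo, fhi, config.bins)
        self.fzero = fvals == 0
        self.mlo, self.mhi = _intensity_range(moving.data)
        self.min_keep: int | None = None

    def __call__(self, params: AffineParams) -> float:
        M = params.matrix()
        mapped = M[:3, :3] @ self.phys + M[:3, 3:4]
        mvals, valid = _sample_moving(self.moving, mapped, self.config.interpolation)
        keep = valid
        if self.config.exclude_zero_pairs:
            keep = keep & ~(self.fzero & (mvals == 0))
        n_keep = int(keep.sum())
        if n_keep == 0:
            return -np.inf
        if self.min_keep is None:  # first call is the starting transform
            self.min_keep = max(8, n_keep // 4)
        elif n_keep < self.min_keep:
            return -np.inf
        mb = _bin_values(mvals[keep], self.mlo, self.mhi, self.config.bins)
        bins = self.config.bins
        hist = np.bincount(self.fb[keep] * bins + mb, minlength=bins * bins).reshape(bins, bins)
        if np.count_nonzero(hist) == 1:
            return -np.inf  # degenerate single-cell histogram
        return _nmi_from_hist(hist.astype(np.float64))


def _intensity_com(volume: Volume) -> np.ndarray:
    """Intensity-weighted centre of mass in physical µm."""
    w = volume.data.astype(np.float64)
    total = w.sum()
    if total <= 0:
        return np.array([(n - 1) * v / 2.0 for n, v in zip(volume.shape, volume.voxel_size)])
    com_idx = np.array(ndimage.center_of_mass(w))
    return com_idx * np.asarray(volume.voxel_size)


def register_affine(
    fixed: Volume,
    moving: Volume,
    dof: int = 6,
    init: AffineParams | None = None,
    config: NMIConfig | None = None,
    levels: tuple[int, ...] = (4, 2, 1),
    max_sweeps: int = 8,
) -> tuple[AffineParams, float]:
    """Maximize NMI over a 6/9/12-DOF affine via multiresolution coordinate descent.

    Rotation/scale/shear act about the fixed-image physical centre.  The
    search is greedy (±step per parameter, halving schedule), keeps the
    incumbent on exact ties and is fully deterministic; the returned score is
    never below the score of ``init`` minus 1e-9.
    """
    config = config or NMIConfig()
    center = tuple((n - 1) * v / 2.0 for n, v in zip(fixed.shape, fixed.voxel_size))
    if init is None:
        # centre-of-mass translation start: avoids decoy optima from the
        # brain's rough mirror symmetry (e.g. one optic lobe onto the other)
        t0 = tuple(
            float(cm - cf)
            for cm, cf in zip(_intensity_com(moving), _intensity_com(fixed))
        )
        init = replace(AffineParams.identity(dof, center), t=t0)
    else:
        if init.dof != dof:
            init = replace(init.promoted(dof) if init.dof < dof else init, dof=dof)
        init = replace(init, center=init.center if any(init.center) else center)
    fine_voxel = min(fixed.voxel_size)
    extent = max(fixed.physical_extent())
    incumbent = init
    any_level_ok = False
    for f in levels:
        # levels below ~12 voxels per axis carry too little structure and
        # can walk into decoy optima (mirror-symmetric anatomy)
        if min(fixed.shape) // f < 12 and f != 1:
            continue
        obj = _AffineObjective(_downsample(fixed, f), _downsample(moving, f), config)
        score = obj(incumbent)
        if not np.isfinite(score):
            continue
        any_level_ok = True
        level_voxel = fine_voxel * f
        t_step = 2.0 * level_voxel
        while t_step >= 0.25 * fine_voxel - 1e-12:
            ang_step = t_step / (extent / 2.0)
            steps = np.array(
                [t_step] * 3 + [ang_step] * 3 + [ang_step] * 3 + [ang_step] * 3, dtype=np.float64
            )[:dof]
            for _ in range(max_sweeps):
                improved = False
                vec = incumbent.to_vector()
                for i in range(dof):
                    best_v, best_s = vec[i], score
                    for sgn in (+1.0, -1.0):
                        trial = vec.copy()
                        trial[i] = vec[i] + sgn * steps[i]
                        if 6 <= i < 9 and trial[i] <= 0.05:
                            continue
                        cand = incumbent.with_vector(trial)
                        s = obj(cand)
                        if s > best_s:
                            best_v, best_s = trial[i], s
                    if best_s > score:
                        vec[i] = best_v
                        score = best_s
                        incumbent = incumbent.with_vector(vec)
                        improved = True
                if not improved:
                    break
            t_step /= 2.0
    if not any_level_ok:
        raise RegistrationFailedError("no image overlap at any pyramid level")
    # final score on the full-resolution objective; never regress below init
    obj = _AffineObjective(fixed, moving, config)
    final = obj(incumbent)
    init_score = obj(init)
    if np.isfinite(init_score) and init_score > final:
        incumbent, final = init, init_score
    return incumbent, float(final)


# --------------------------------------------------------------------------
# B-spline FFD registration
# --------------------------------------------------------------------------

def _bspline3(t: np.ndarray) -> np.ndarray:
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at < 1
    m2 = (at >= 1) & (at < 2)
    out[m1] = (4 - 6 * at[m1] ** 2 + 3 * at[m1] ** 3) / 6.0
    out[m2] = (2 - at[m2]) ** 3 / 6.0
    return out


def _xlogx(n: np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=np.float64)
    return np.where(n > 0, n * np.log(np.maximum(n, 1e-300)), 0.0)


class _HistState:
    """Joint histogram with incremental entropy bookkeeping.

    Tracks sum(n_ij log n_ij) for joint and marginal counts so NMI updates
    after a local change cost O(changed bins) instead of O(bins^2).
    """

    def __init__(self, bins: int):
        self.bins = bins
        self.joint = np.zeros(bins * bins, dtype=np.float64)
        self.ma = np.zeros(bins, dtype=np.float64)
        self.mb = np.zeros(bins, dtype=np.float64)
        self.s_ab = 0.0
        self.s_a = 0.0
        self.s_b = 0.0
        self.n = 0.0

    def add_pairs(self, fb: np.ndarray, mb: np.ndarray) -> None:
        self.apply_delta(*self.delta(fb, mb, np.empty(0, np.int64), np.empty(0, np.int64)))

    def delta(self, fb_add, mb_add, fb_rem, mb_rem):
        bins = self.bins
        d_joint = np.bincount(fb_add * bins + mb_add, minlength=bins * bins).astype(np.float64)
        if fb_rem.size:
            d_joint -= np.bincount(fb_rem * bins + mb_rem, minlength=bins * bins)
        d_a = np.bincount(fb_add, minlength=bins).astype(np.float64)
        d_b = np.bincount(mb_add, minlength=bins).astype(np.float64)
        if fb_rem.size:
            d_a -= np.bincount(fb_rem, minlength=bins)
            d_b -= np.bincount(mb_rem, minlength=bins)
        return d_joint, d_a, d_b, float(fb_add.size - fb_rem.size)

    def peek_nmi(self, d_joint, d_a, d_b, d_n) -> float:
        cells = np.nonzero(d_joint)[0]
        s_ab = self.s_ab + float(np.sum(_xlogx(self.joint[cells] + d_joint[cells]) - _xlogx(self.joint[cells])))
        ca = np.nonzero(d_a)[0]
        s_a = self.s_a + float(np.sum(_xlogx(self.ma[ca] + d_a[ca]) - _xlogx(self.ma[ca])))
        cb = np.nonzero(d_b)[0]
        s_b = self.s_b + float(np.sum(_xlogx(self.mb[cb] + d_b[cb]) - _xlogx(self.mb[cb])))
        n = self.n + d_n
        if n <= 0:
            return -np.inf
        logn = math.log(n)
        h_ab = logn - s_ab / n
        if h_ab <= 1e-15:
            return 2.0
        h_a = logn - s_a / n
        h_b = logn - s_b / n
        return (h_a + h_b) / h_ab

    def apply_delta(self, d_joint, d_a, d_b, d_n) -> None:
        cells = np.nonzero(d_joint)[0]
        self.s_ab += float(np.sum(_xlogx(self.joint[cells] + d_joint[cells]) - _xlogx(self.joint[cells])))
        self.joint[cells] += d_joint[cells]
        ca = np.nonzero(d_a)[0]
        self.s_a += float(np.sum(_xlogx(self.ma[ca] + d_a[ca]) - _xlogx(self.ma[ca])))
        self.ma[ca] += d_a[ca]
        cb = np.nonzero(d_b)[0]
        self.s_b += float(np.sum(_xlogx(self.mb[cb] + d_b[cb]) - _xlogx(self.mb[cb])))
        self.mb[cb] += d_b[cb]
        self.n += d_n

    def nmi(self) -> float:
        z = np.zeros(0)
        return self.peek_nmi(np.zeros(self.bins * self.bins), z, z, 0.0)


def register_bspline(
    fixed: Volume,
    moving: Volume,
    init_chain: TransformChain,
    grid_spacing,
    config: NMIConfig | None = None,
    sample_stride: int = 2,
    step_schedule_voxels: tuple[float, ...] = (2.0, 1.0, 0.5, 0.25),
    bending_weight: float = 0.0,
    max_displacement_factor: float = 0.4,
) -> tuple[BSplineGrid, float]:
    """Append an optimized FFD grid to ``init_chain`` by maximizing NMI.

    Control-point displacements are optimized one at a time with exact
    incremental joint-histogram updates over each point's support region,
    evaluated on a strided voxel lattice (``sample_stride``).  Displacement
    magnitudes are capped at ``max_displacement_factor × spacing`` per axis as
    a folding guard.  ``bending_weight`` subtracts a discrete bending-energy
    penalty (squared second differences of the coefficient lattice) from the
    objective.  The result is deterministic and its objective never falls
    below the value at the zero-displacement start.

    Returns the new grid and the objective value on the sampling lattice.
    """
    config = config or NMIConfig()
    grid = BSplineGrid.for_domain(fixed.physical_extent(), grid_spacing, fixed.voxel_size)
    st = max(1, int(sample_stride))
    bins = config.bins

    # strided fixed lattice
    sidx = [np.arange(0, n, st) for n in fixed.shape]
    fsub = fixed.data[::st, ::st, ::st].astype(np.float64)
    flo, fhi = _intensity_range(fixed.data)
    fb = _bin_values(fsub, flo, fhi, bins)
    fzero = fsub == 0
    mlo, mhi = _intensity_range(moving.data)
    mdata = moving.data.astype(np.float64, copy=False)

    phys = np.stack(
        np.meshgrid(*[si * v for si, v in zip(sidx, fixed.voxel_size)], indexing="ij")
    )
    base = init_chain.map_points(phys)  # moving-space µm before the new grid
    disp = np.zeros_like(base)  # current new-grid displacement at lattice points

    interp_order = 0 if config.interpolation == "nearest" else 1

    def sample(box, disp_box):
        pts = base[(slice(None),) + box] + disp_box
        idx = np.empty_like(pts)
        valid = np.ones(pts.shape[1:], dtype=bool)
        for a in range(3):
            idx[a] = pts[a] / moving.voxel_size[a]
            valid &= (idx[a] >= 0) & (idx[a] <= moving.shape[a] - 1)
        vals = ndimage.map_coordinates(mdata, idx, order=interp_order, mode="nearest")
        return vals, valid

    def pairs(box, vals, valid):
        keep = valid
        if config.exclude_zero_pairs:
            keep = keep & ~(fzero[box] & (vals == 0))
        return fb[box][keep], _bin_values(vals[keep], mlo, mhi, bins)

    full = (slice(None),) * 3
    vals0, valid0 = sample(full, disp)
    cur_vals, cur_valid = vals0, valid0
    state = _HistState(bins)
    fb0, mb0 = pairs(full, vals0, valid0)
    if fb0.size == 0:
        raise OverlapError("no overlapping voxel pairs at the start of elastic registration")
    state.add_pairs(fb0, mb0)

    # per-axis, per-control-point support on the strided lattice
    nctrl = grid.coeffs.shape[:3]
    support: list[list[tuple[slice, np.ndarray]]] = []
    for a in range(3):
        u = sidx[a] * fixed.voxel_size[a] / grid.spacing[a] + 1.0
        axis_list = []
        for c in range(nctrl[a]):
            inside = np.nonzero(np.abs(u - c) < 2.0)[0]
            if inside.size == 0:
                axis_list.append((slice(0, 0), np.zeros(0)))
            else:
                sl = slice(int(inside[0]), int(inside[-1]) + 1)
                axis_list.append((sl, _bspline3(u[sl] - c)))
        support.append(axis_list)

    cap = max_displacement_factor * min(grid.spacing)
    fine_voxel = min(fixed.voxel_size)

    def bending_energy_local(coeffs, c, a) -> float:
        if bending_weight == 0.0:
            return 0.0
        # squared second differences along each lattice axis touching point c
        e = 0.0
        for ax in range(3):
            arr = coeffs[..., a]
            n = arr.shape[ax]
            for off in (-1, 0, 1):
                j = c[ax] + off
                if 1 <= j <= n - 2:
                    sl = list(c)
                    sl[ax] = slice(j - 1, j + 2)
                    trip = arr[tuple(sl)]
                    e += float((trip[0] - 2 * trip[1] + trip[2]) ** 2)
        return e

    score = state.nmi()
    for step_vox in step_schedule_voxels:
        step = step_vox * fine_voxel
        for cx in range(nctrl[0]):
            slx, wx = support[0][cx]
            if wx.size == 0:
                continue
            for cy in range(nctrl[1]):
                sly, wy = support[1][cy]
                if wy.size == 0:
                    continue
                for cz in range(nctrl[2]):
                    slz, wz = support[2][cz]
                    if wz.size == 0:
                        continue
                    box = (slx, sly, slz)
                    fb_box = fb[box]
                    if not fb_box.any() and not cur_vals[box].any():
                        continue  # all-background region: no NMI information
                    patch = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
                    old_fb, old_mb = pairs(box, cur_vals[box], cur_valid[box])
                    for a in range(3):
                        c0 = grid.coeffs[cx, cy, cz, a]
                        best = None
                        for sgn in (+1.0, -1.0):
                            cand = c0 + sgn * step
                            if abs(cand) > cap:
                                continue
                            dbox = disp[(slice(None),) + box].copy()
                            dbox[a] += (cand - c0) * patch
                            vals, valid = sample(box, dbox)
                            nfb, nmb = pairs(box, vals, valid)
                            d = state.delta(nfb, nmb, old_fb, old_mb)
                            s = state.peek_nmi(*d)
                            if bending_weight:
                                coeffs_try = grid.coeffs.copy()
                                coeffs_try[cx, cy, cz, a] = cand
                                s -= bending_weight * (
                                    bending_energy_local(coeffs_try, (cx, cy, cz), a)
                                    - bending_energy_local(grid.coeffs, (cx, cy, cz), a)
                                )
                            # the 1e-9 margin rejects float-noise "improvements"
                            # that would otherwise drift a perfectly aligned pair
                            if s > score + 1e-9 and (best is None or s > best[0]):
                                best = (s, cand, d, vals, valid, dbox[a])
                        if best is not None:
                            s, cand, d, vals, valid, new_da = best
                            state.apply_delta(*d)
                            grid.coeffs[cx, cy, cz, a] = cand
                            disp[a][box] = new_da
                            cur_vals[box] = vals
                            cur_valid[box] = valid
                            score = s
                            old_fb, old_mb = pairs(box, vals, valid)
    return grid, float(score)


def elastic_objective_score(
    fixed: Volume, moving: Volume, chain: TransformChain,
    config: NMIConfig | None = None, sample_stride: int = 2,
) -> float:
    """NMI of fixed vs moving under ``chain`` on the strided optimizer lattice.

    This is the quantity :func:`register_bspline` maximizes; useful for
    before/after comparisons on identical footing.
    """
    config = config or NMIConfig()
    st = max(1, int(sample_stride))
    fsub = Volume(fixed.data[::st, ::st, ::st].astype(np.float64),
                  tuple(v * st for v in fixed.voxel_size))
    # keep original intensity range semantics
    phys = _fixed_phys_grid(fsub)
    mapped = chain.map_points(phys)
    mvals, valid = _sample_moving(moving, mapped, config.interpolation)
    fvals = fsub.data
    keep = valid
    if config.exclude_zero_pairs:
        keep = keep & ~((fvals == 0) & (mvals == 0))
    if not keep.any():
        raise OverlapError("no overlap")
    flo, fhi = _intensity_range(fixed.data)
    mlo, mhi = _intensity_range(moving.data)
    fbv = _bin_values(fvals[keep], flo, fhi, config.bins)
    mbv = _bin_values(mvals[keep], mlo, mhi, config.bins)
    hist = np.bincount(fbv * config.bins + mbv, minlength=config.bins**2)
    return _nmi_from_hist(hist.reshape(config.bins, config.bins).astype(np.float64))
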