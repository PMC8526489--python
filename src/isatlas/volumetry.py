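"""Neuropil volumetry: per-structure volumes, cohort statistics, relative
volumes with exclusion sets, and cross-atlas extent comparisons.

Composite structures (the central complex CX, optic lobes OL and mushroom
bodies MB) are reported as sums over a group-membership table; relative
volumes use the *top-level* denominator — base structures that belong to no
group, plus the group totals — so members are never double-counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import LabelField, round_half_up


def load_reference_brain() -> dict:
    """Published Bombus terrestris standard-brain volumes and group table."""
    with resources.files("isatlas").joinpath("data/bombus_standard_brain.json").open() as fh:
        return json.load(fh)


def load_reference_extents() -> list["AtlasExtent"]:
    """Voxel counts/sizes of the published hymenopteran standard brains."""
    with resources.files("isatlas").joinpath("data/hymenoptera_atlas_extents.json").open() as fh:
        doc = json.load(fh)
    return [
        AtlasExtent(a["name"], tuple(a["voxel_counts"]), tuple(a["voxel_size_um"]))
        for a in doc["atlases"]
    ]


def label_volumes(
    label_field: LabelField, groups: dict[str, list[str]] | None = None
) -> dict[str, float]:
    """Structure name → volume in µm³ (voxel count × voxel volume).

    Background is excluded; group structures are appended as sums of their
    members (missing members count 0).
    """
    if not label_field.catalog:
        counts = {}
    else:
        ids = np.array(sorted(label_field.catalog))
        raw = np.bincount(label_field.data.ravel(), minlength=int(ids.max()) + 1 if ids.size else 1)
        counts = {label_field.catalog[int(i)]: int(raw[int(i)]) for i in ids}
    vv = float(np.prod(label_field.voxel_size))
    out = {name: c * vv for name, c in counts.items() if c > 0}
    if groups:
        for gname, members in groups.items():
            out[gname] = sum(out.get(m, 0.0) for m in members)
    return out


def relative_volumes(
    volumes: dict[str, float],
    groups: dict[str, list[str]] | None = None,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> dict[str, float]:
    """Percentages of the summed top-level volume, optionally excluding structures.

    ``volumes`` holds base structures (groups, if already present, are
    recomputed from members).  Excluded structures leave both the numerator
    and the denominator; group totals shrink accordingly.  Every remaining
    base structure and group gets a percentage.
    """
    groups = groups or {}
    members = {m for g in groups.values() for m in g}
    base = {k: v for k, v in volumes.items() if k not in groups}
    unknown = set(exclude) - set(base)
    if unknown:
        raise ValueError(f"excluded structures not present: {sorted(unknown)}")
    base = {k: v for k, v in base.items() if k not in exclude}
    gsum = {g: sum(base.get(m, 0.0) for m in mem) for g, mem in groups.items()}
    denominator = sum(v for k, v in base.items() if k not in members) + sum(gsum.values())
    if denominator <= 0:
        raise ValueError("zero total volume: cannot form percentages")
    out = {k: 100.0 * v / denominator for k, v in base.items()}
    out.update({g: 100.0 * v / denominator for g, v in gsum.items()})
    return out


@dataclass
class VolumetryTable:
    """Cohort volumetry in the layout of a standard-brain volume table."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        rounded = self.frame.copy()
        for col in rounded.columns:
            if col.endswith("(%)"):
                rounded[col] = (round_half_up(rounded[col] * 10) / 10.0)
        rounded.to_csv(path, float_format="%.6g")


def cohort_stats(
    specimen_volumes: list[dict[str, float]],
    groups: dict[str, list[str]] | None = None,
    exclude: set[str] = frozenset(),
    standard_volumes: dict[str, float] | None = None,
) -> VolumetryTable:
    """Mean/SD of volumes and relative volumes over a cohort.

    Sample standard deviation (n−1).  Structures missing from a specimen are
    treated as volume 0.  ``standard_volumes`` (e.g. from the fused atlas)
    adds the standard-brain columns.  Rounding happens only at serialization.
    """
    if len(specimen_volumes) < 2:
        raise ValueError("cohort statistics need >= 2 specimens")
    groups = groups or {}
    names: list[str] = sorted({k for v in specimen_volumes for k in v if k not in groups})
    members = {m for g in groups.values() for m in g}
    rows = names + [g for g in groups if g not in names]

    def matrix(fn) -> dict[str, np.ndarray]:
        per = [fn(v) for v in specimen_volumes]
        return {r: np.array([p.get(r, 0.0) for p in per]) for r in rows}

    vols = matrix(lambda v: {**{k: v.get(k, 0.0) for k in names},
                             **{g: sum(v.get(m, 0.0) for m in mem) for g, mem in groups.items()}})
    rel_all = matrix(lambda v: relative_volumes({k: v.get(k, 0.0) for k in names}, groups))
    rel_exc = matrix(lambda v: relative_volumes({k: v.get(k, 0.0) for k in names}, groups, exclude))

    data = {
        "mean volume (µm³)": [vols[r].mean() for r in rows],
        "SD (µm³)": [vols[r].std(ddof=1) for r in rows],
        "relative volume (%)": [rel_all[r].mean() for r in rows],
        "SD rel (%)": [rel_all[r].std(ddof=1) for r in rows],
        "relative volume excl (%)": [
            np.nan if r in exclude else rel_exc[r].mean() for r in rows
        ],
        "SD rel excl (%)": [
            np.nan if r in exclude else rel_exc[r].std(ddof=1) for r in rows
        ],
    }
    if standard_volumes is not None:
        try:
            std_rel = relative_volumes(
                {k: standard_volumes.get(k, 0.0) for k in names}, groups
            )
        except ValueError:  # empty standard segmentation: volumes only
            std_rel = {}
        data["standard brain (µm³)"] = [
            standard_volumes.get(r, sum(standard_volumes.get(m, 0.0) for m in groups.get(r, [])))
            for r in rows
        ]
        data["standard brain (%)"] = [std_rel.get(r, np.nan) for r in rows]
    return VolumetryTable(pd.DataFrame(data, index=pd.Index(rows, name="structure")))


@dataclass
class AtlasExtent:
    """Voxel counts and sizes of one atlas, per axis (x, y, z)."""

    name: str
    voxel_counts: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.voxel_counts) or any(s <= 0 for s in self.voxel_size_um):
            raise ValueError(f"{self.name}: voxel counts and sizes must be positive")

    def physical_size_um(self) -> tuple[int, int, int]:
        """Physical extent per axis, rounded half-up to whole µm."""
        return tuple(
            int(round_half_up(c * s)) for c, s in zip(self.voxel_counts, self.voxel_size_um)
        )  # type: ignore[return-value]


def atlas_extent_stats(extents: list[AtlasExtent]) -> pd.DataFrame:
    """Physical sizes and pairwise voxel-count ratios (%) of a set of atlases.

    The ratio of atlas a to atlas b along an axis is
    ``100 × count_a / count_b``, rounded half-up to an integer percent.
    """
    if not extents:
        raise ValueError("need at least one atlas extent")
    rows = []
    for a in extents:
        phys = a.physical_size_um()
        row = {
            "atlas": a.name,
            **{f"voxels {ax}": c for ax, c in zip("xyz", a.voxel_counts)},
            **{f"size {ax} (µm)": p for ax, p in zip("xyz", phys)},
        }
        for b in extents:
            if b.name == a.name:
                continue
            for ax, ca, cb in zip("xyz", a.voxel_counts, b.voxel_counts):
                row[f"{ax} vs {b.name} (%)"] = int(round_half_up(100.0 * ca / cb))
        rows.append(row)
    return pd.DataFrame(rows).set_index("atlas")
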