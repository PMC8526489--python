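"""End-to-end pipeline with validated configuration and provenance.

``run_pipeline`` wires the stages together: load (or simulate) a cohort,
preprocess, iterative shape averaging, optional separate standardization of
small structures, label fusion and volumetry, writing every artifact plus a
machine-readable manifest into an atlas directory.  Reruns from the same
manifest are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import io as vio
from .core import SpecimenSet
from .isa import AtlasModel, ISAConfig, isa_run, standardize_substructure
from .phantoms import PHANTOM_GROUPS, PhantomSpec, make_cohort
from .preprocess import apply_mask, normalize_intensity
from .registration import NMIConfig
from .volumetry import cohort_stats, label_volumes

log = logging.getLogger(__name__)


class NMISettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bins: int = 64
    exclude_zero_pairs: bool = True
    interpolation: str = "linear"


class ISASettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    affine_dof_schedule: tuple[int, ...] = (6, 9)
    n_elastic_iters: int = 5
    grid_schedule_um: tuple[float, ...] = ()
    placement_dof: int = 6
    sample_stride: int = 2


class SimulateSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_specimens: int = 10
    grid_size: int = 96
    noise_sd: float = 5.0
    warp_sd_vox: float = 2.0
    max_translation_vox: float = 5.0
    max_rotation_deg: float = 10.0


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    cohort_dir: str | None = None
    simulate: SimulateSettings | None = None
    normalize: bool = True
    mask_suffix: str = "_mask"
    substructure_labels: list[int] = Field(default_factory=list)
    volumetry_exclude: list[str] = Field(default_factory=list)
    groups: dict[str, list[str]] = Field(default_factory=lambda: dict(PHANTOM_GROUPS))
    isa: ISASettings = Field(default_factory=ISASettings)
    nmi: NMISettings = Field(default_factory=NMISettings)
    seed: int = 0
    verbosity: str = "info"


def _load_cohort(cfg: PipelineConfig) -> SpecimenSet:
    if cfg.simulate is not None:
        sim = cfg.simulate
        spec = PhantomSpec(
            shape=(sim.grid_size,) * 3, noise_sd=sim.noise_sd, warp_sd_vox=sim.warp_sd_vox,
            max_translation_vox=sim.max_translation_vox, max_rotation_deg=sim.max_rotation_deg,
            seed=cfg.seed,
        )
        cohort, truth = make_cohort(spec, sim.n_specimens, cfg.seed)
        masked = [apply_mask(v, m) for v, m in zip(cohort.volumes, truth.specimen_masks)]
        return SpecimenSet(masked, cohort.labels, cohort.ids)
    if cfg.cohort_dir is None:
        raise ValueError("config must set either cohort_dir or simulate")
    root = Path(cfg.cohort_dir)
    vols, labs, ids = [], [], []
    for vol_path in sorted(root.glob("*_volume.nrrd")):
        stem = vol_path.name[: -len("_volume.nrrd")]
        vol = vio.read_nrrd(vol_path)
        lab_path = root / f"{stem}_labels.nrrd"
        lab = vio.read_nrrd(lab_path) if lab_path.exists() else None
        mask_path = root / f"{stem}{cfg.mask_suffix}.nrrd"
        if mask_path.exists():
            vol = apply_mask(vol, vio.read_nrrd(mask_path))
        vols.append(vol)
        labs.append(lab)
        ids.append(stem)
    if len(vols) < 2:
        raise ValueError(f"cohort directory {root} holds {len(vols)} specimens; >= 2 required")
    return SpecimenSet(vols, labs, ids)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> AtlasModel:
    """Execute preprocess → ISA → (substructure) → fusion → volumetry.

    Writes ``template.nrrd``, ``labels.nrrd``, ``chains/*.json``,
    ``volumetry.csv``, ``log.txt`` and ``manifest.json`` into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root_logger = logging.getLogger("isatlas")
    root_logger.addHandler(handler)
    root_logger.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    try:
        cohort = _load_cohort(config)
        if config.normalize:
            cohort = SpecimenSet(
                [normalize_intensity(v) for v in cohort.volumes], cohort.labels, cohort.ids
            )
        isa_cfg = ISAConfig(
            affine_dof_schedule=config.isa.affine_dof_schedule,
            n_elastic_iters=config.isa.n_elastic_iters,
            grid_schedule_um=config.isa.grid_schedule_um,
            placement_dof=config.isa.placement_dof,
            seed=config.seed,
            nmi_config=NMIConfig(**config.nmi.model_dump()),
            sample_stride=config.isa.sample_stride,
        )
        atlas = isa_run(cohort, isa_cfg)
        if config.substructure_labels:
            atlas = standardize_substructure(cohort, config.substructure_labels, atlas)

        # export
        template8 = np.clip(np.floor(atlas.template.data + 0.5), 0, 255).astype(np.uint8)
        from .core import Volume  # local import to avoid cycle noise

        vio.write_nrrd(out / "template.nrrd", Volume(template8, atlas.template.voxel_size))
        chains_dir = out / "chains"
        chains_dir.mkdir(exist_ok=True)
        for sid, chain in zip(atlas.specimen_ids, atlas.chains):
            chain.save(chains_dir / f"{sid}.json")
        if atlas.fused_labels is not None:
            vio.write_nrrd(out / "labels.nrrd", atlas.fused_labels)
            per_specimen = [
                label_volumes(lab, config.groups) for lab in cohort.labels if lab is not None
            ]
            table = cohort_stats(
                [{k: v for k, v in p.items() if k not in config.groups} for p in per_specimen],
                groups=config.groups,
                exclude=set(config.volumetry_exclude),
                standard_volumes=label_volumes(atlas.fused_labels),
            )
            table.to_csv(out / "volumetry.csv")
        manifest = {
            "config": json.loads(config.model_dump_json()),
            "seed": config.seed,
            "config_hash": hashlib.sha256(config.model_dump_json().encode()).hexdigest(),
            "specimens": atlas.specimen_ids,
            "reference_index": atlas.reference_index,
            "round_mean_nmi": atlas.round_mean_nmi,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return atlas
    finally:
        root_logger.removeHandler(handler)
        handler.close()
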