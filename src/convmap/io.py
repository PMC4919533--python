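"""Formats (NIfTI, TSV, JSON, YAML) and the end-to-end pipeline runner."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from convmap import groupstats, network, overlap, rsa
from convmap.synth import SyntheticConfig, generate_dataset
from convmap.types import BetaImageSet, ConditionLabel, StatMap

logger = logging.getLogger(__name__)

LABEL_COLUMNS = ["index", "association_id", "cue_category", "associate_category",
                 "order_index", "phase", "instance_index", "run_id"]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_nifti(path, data: np.ndarray, voxel_size_mm: float = 2.0,
               affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = _affine(voxel_size_mm)
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_labels(path, labels: list[ConditionLabel]) -> None:
    rows = [{"index": i, **dataclasses.asdict(lab)}
            for i, lab in enumerate(labels)]
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_labels(path) -> list[ConditionLabel]:
    df = pd.read_csv(path, sep="\t")
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    df = df.sort_values("index")
    return [ConditionLabel(
        association_id=int(r.association_id), cue_category=str(r.cue_category),
        associate_category=str(r.associate_category),
        order_index=int(r.order_index), phase=str(r.phase),
        instance_index=int(r.instance_index), run_id=int(r.run_id),
    ) for r in df.itertuples()]


def write_beta_set(betas: BetaImageSet, nifti_path, label_path,
                   mask_path=None) -> None:
    save_nifti(nifti_path, betas.data, betas.voxel_size_mm)
    write_labels(label_path, betas.labels)
    if mask_path is not None:
        save_nifti(mask_path, betas.mask.astype(np.uint8), betas.voxel_size_mm)


def read_beta_set(nifti_path, label_path, mask_path=None) -> BetaImageSet:
    data, affine = load_nifti(nifti_path)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D beta stack, got shape {data.shape}")
    labels = read_labels(label_path)
    if len(labels) != data.shape[3]:
        raise ValueError(
            f"label table has {len(labels)} rows for {data.shape[3]} volumes")
    if mask_path is not None:
        mask = load_nifti(mask_path)[0] > 0
    else:
        mask = np.any(data != 0, axis=3)
    vox = float(np.abs(affine[0, 0])) or 2.0
    return BetaImageSet(data=data, labels=labels, mask=mask, voxel_size_mm=vox)


def write_region_names(path, region_names: list[str],
                       region_to_module: dict[int, int]) -> None:
    df = pd.DataFrame({
        "region_id": np.arange(1, len(region_names) + 1),
        "name": region_names,
        "module": [region_to_module[r] for r in range(1, len(region_names) + 1)],
    })
    df.to_csv(path, sep="\t", index=False)


def save_statmap(path, statmap: StatMap, voxel_size_mm: float = 2.0) -> None:
    save_nifti(path, statmap.values, voxel_size_mm)


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline end to end."""

    output_dir: str = "convmap_out"
    # input paths (ignored when `synthetic` is set)
    beta_paths: list[str] = field(default_factory=list)
    label_paths: list[str] = field(default_factory=list)
    atlas_path: str | None = None
    mask_path: str | None = None
    synthetic: SyntheticConfig | None = None
    # RSA
    radius_voxels: int = 4
    min_voxels: int = 30
    # network
    subsample_factor: int = 4
    fdr_alpha: float = 0.05
    metric: str = "pc"
    # group
    n_perm_group: int = 10000
    side: str = "greater"
    alpha: float = 0.05
    # overlap
    target_region_ids: list[int] = field(default_factory=list)
    n_perm_overlap: int = 10000
    n_draw: int = 2
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
            d["synthetic"]["grid_shape"] = list(self.synthetic.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        cfg = cls(**d)
        if syn is not None:
            syn = dict(syn)
            syn["grid_shape"] = tuple(syn["grid_shape"])
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def run_all(config: PipelineConfig) -> dict:
    """RSA -> network -> group -> overlap, writing all artefacts.

    Returns the manifest dict (also written as ``manifest.json``). Fully
    deterministic given the config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    if config.synthetic is not None:
        subjects, gt = generate_dataset(config.synthetic)
        atlas = gt.atlas
        targets = config.target_region_ids or [gt.planted_region_id]
        save_nifti(out / "atlas.nii", atlas.astype(np.int16))
        write_region_names(out / "regions.tsv", gt.region_names,
                           gt.region_to_module)
        manifest["stages"]["simulate"] = {
            "n_subjects": len(subjects),
            "planted_region_id": gt.planted_region_id,
            "visual_region_ids": gt.visual_region_ids,
        }
    else:
        if config.atlas_path is None or not config.beta_paths:
            raise RuntimeError("[input] need beta_paths and atlas_path "
                               "when no synthetic config is given")
        subjects = [read_beta_set(b, l, config.mask_path)
                    for b, l in zip(config.beta_paths, config.label_paths)]
        atlas = load_nifti(config.atlas_path)[0].astype(np.int64)
        targets = config.target_region_ids
        if not targets:
            raise RuntimeError("[input] target_region_ids required")

    grid = subjects[0].mask.shape
    try:
        contrast = rsa.build_contrast_matrix(subjects[0].phase_labels("retrieval"))
        spheres = rsa.searchlight_spheres(subjects[0].mask,
                                          config.radius_voxels,
                                          config.min_voxels)
        conj_maps, hub_contrasts = [], []
        for s, betas in enumerate(subjects):
            cmap = rsa.conjunctiveness_map(betas, contrast, spheres)
            conj_maps.append(cmap)
            save_statmap(out / f"sub-{s:02d}_conjunctiveness.nii", cmap)
            hub = network.subject_hubness(
                betas, atlas, subsample_factor=config.subsample_factor,
                fdr_alpha=config.fdr_alpha, metric=config.metric,
                seed=config.seed)
            up = network.upsample_map(hub["contrast"], config.subsample_factor,
                                      grid)
            hub_contrasts.append(up)
            save_statmap(out / f"sub-{s:02d}_hubness_contrast.nii", up)
        manifest["stages"]["subject_maps"] = {
            "n_spheres": len(spheres),
            "radius_voxels": config.radius_voxels,
            "min_voxels": config.min_voxels,
            "subsample_factor": config.subsample_factor,
            "metric": config.metric,
        }
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        raise RuntimeError(f"[subject-maps] {exc}") from exc

    try:
        results = {}
        for name, maps in (("conjunctiveness", conj_maps),
                           ("hubness", hub_contrasts)):
            g = groupstats.signflip_permutation_test(
                maps, n_perm=config.n_perm_group, side=config.side,
                seed=config.seed)
            save_statmap(out / f"group_{name}_t.nii", g.t)
            save_statmap(out / f"group_{name}_p.nii", g.p)
            mask = groupstats.binarize_map(g.p, config.alpha)
            save_nifti(out / f"group_{name}_mask.nii", mask.astype(np.uint8))
            results[name] = (g, mask)
        manifest["stages"]["group"] = {
            "n_perm": config.n_perm_group, "side": config.side,
            "alpha": config.alpha, "seed": config.seed,
            "exhaustive": results["conjunctiveness"][0].exhaustive,
            "suprathreshold_voxels": {
                name: int(mask.sum()) for name, (g, mask) in results.items()},
        }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[group] {exc}") from exc

    try:
        conj_mask = results["conjunctiveness"][1]
        hub_mask = results["hubness"][1]
        ov = overlap.spatial_resampling_test(
            conj_mask, hub_mask, atlas, targets,
            n_perm=config.n_perm_overlap, n_draw=config.n_draw,
            seed=config.seed)
        with open(out / "overlap.json", "w") as fh:
            json.dump(ov.to_dict(), fh, indent=2)
        roi = np.isin(atlas, targets)
        corr = None
        overlap_roi = conj_mask & hub_mask & roi
        if overlap_roi.sum() >= 5:
            corr = overlap.metric_correlation(conj_maps, hub_contrasts,
                                              overlap_roi)
        manifest["stages"]["overlap"] = {
            "dice": ov.dice, "relative_overlap": ov.relative_overlap,
            "p_dice": ov.p_dice, "p_relative": ov.p_relative,
            "n_perm": ov.n_permutations, "n_draw": ov.n_regions_drawn,
            "target_region_ids": targets,
            "metric_correlation": corr,
        }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[overlap] {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
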