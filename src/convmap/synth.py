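"""Synthetic multi-subject beta-image sets with planted effects.

The generator emulates a paired-associate retrieval design: balanced
associations over face/house/body category pairs, two cue-associate orders,
equal retrieval and inter-trial-interval (ITI) regressor counts. Planted
structure covers the three downstream statistics:

- a *conjunctive* term: association-specific, order-invariant patterns in a
  designated planted region;
- a *perceptual* term: category patterns in "visual" regions, dependent on
  cue/associate order (cue weighted 1.0, associate 0.5);
- a *connectivity* term: every voxel loads on its module's latent instance
  series; planted-region voxels additionally load on all other modules'
  series during retrieval only (hub effect).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np

from convmap.types import BetaImageSet, ConditionLabel

_PAIR_TYPES = (("face", "house"), ("face", "body"), ("house", "body"))


@dataclass
class SyntheticConfig:
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_regions: int = 8
    n_modules: int = 2
    n_subjects: int = 12
    n_associations: int = 12
    instances_per_condition: int = 2
    runs: int = 2
    conjunctive_effect: float = 0.0
    perceptual_effect: float = 0.0
    hub_effect: float = 0.0
    module_coupling: float = 1.0
    noise_sd: float = 1.0
    planted_region_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be a 3-tuple")
        if self.n_regions < 4:
            raise ValueError("need at least 4 regions")
        if self.n_modules < 1 or self.n_modules > self.n_regions:
            raise ValueError("n_modules must be in [1, n_regions]")
        for name in ("conjunctive_effect", "perceptual_effect", "hub_effect",
                     "module_coupling"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (1 <= self.planted_region_id <= self.n_regions):
            raise ValueError(
                f"planted_region_id {self.planted_region_id} outside "
                f"1..{self.n_regions}"
            )


@dataclass
class GroundTruth:
    """Planted structure needed to score recovery downstream."""

    atlas: np.ndarray
    region_names: list[str]
    region_to_module: dict[int, int]
    planted_region_id: int
    planted_mask: np.ndarray
    visual_region_ids: list[int]
    visual_mask: np.ndarray
    association_patterns: list[dict[int, np.ndarray]] = field(default_factory=list)
    category_patterns: list[dict[str, np.ndarray]] = field(default_factory=list)


def make_design(n_associations: int = 12, instances_per_condition: int = 2,
                runs: int = 2) -> list[ConditionLabel]:
    """Balanced retrieval + ITI condition labels.

    Associations are assigned to the three category-pair types in equal
    thirds; each association contributes both cue-associate orders. The
    default arguments yield 96 retrieval and 96 ITI labels.
    """
    if n_associations % 3 != 0:
        raise ValueError(
            "n_associations must be divisible by 3 so the three category-pair "
            f"types (face-house, face-body, house-body) balance; got {n_associations}"
        )
    if min(n_associations, instances_per_condition, runs) < 1:
        raise ValueError("all design arguments must be >= 1")
    labels: list[ConditionLabel] = []
    for phase in ("retrieval", "iti"):
        for aid in range(1, n_associations + 1):
            c1, c2 = _PAIR_TYPES[(aid - 1) % 3]
            for order in (0, 1):
                cue, assoc = (c1, c2) if order == 0 else (c2, c1)
                for run in range(1, runs + 1):
                    for inst in range(instances_per_condition):
                        labels.append(ConditionLabel(
                            association_id=aid, cue_category=cue,
                            associate_category=assoc, order_index=order,
                            phase=phase, instance_index=inst, run_id=run,
                        ))
    return labels


def generate_atlas(grid_shape: tuple[int, int, int], n_regions: int,
                   seed: int, n_modules: int = 2):
    """Tile the full grid into compact contiguous regions by balanced growth.

    Regions are grown from random seed voxels by round-robin breadth-first
    expansion, which keeps voxel counts close to equal. Region codes are
    1..n_regions; module assignment is round-robin over regions.

    Returns (atlas volume, region_names, region_to_module).
    """
    shape = tuple(int(s) for s in grid_shape)
    n_vox = int(np.prod(shape))
    if n_regions > n_vox:
        raise ValueError(f"{n_regions} regions exceed {n_vox} voxels")
    rng = np.random.default_rng(seed)
    atlas = np.zeros(shape, dtype=np.int32)
    flat_seeds = rng.choice(n_vox, size=n_regions, replace=False)
    queues = []
    for rid, fs in enumerate(flat_seeds, start=1):
        coord = np.unravel_index(fs, shape)
        queues.append(collections.deque([coord]))
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    remaining = n_vox
    while remaining > 0:
        for rid, queue in enumerate(queues, start=1):
            while queue:
                x, y, z = queue.popleft()
                if atlas[x, y, z] == 0:
                    atlas[x, y, z] = rid
                    remaining -= 1
                    for dx, dy, dz in offsets:
                        nx, ny, nz = x + dx, y + dy, z + dz
                        if (0 <= nx < shape[0] and 0 <= ny < shape[1]
                                and 0 <= nz < shape[2] and atlas[nx, ny, nz] == 0):
                            queue.append((nx, ny, nz))
                    break
    region_names = [f"region_{rid:03d}" for rid in range(1, n_regions + 1)]
    region_to_module = {rid: (rid - 1) % n_modules for rid in range(1, n_regions + 1)}
    return atlas, region_names, region_to_module


def _visual_regions(region_to_module: dict[int, int], planted_region_id: int
                    ) -> list[int]:
    """Non-planted regions of one designated module (the lowest module id
    differing from the planted region's, falling back to the planted module
    when there is only one)."""
    planted_module = region_to_module[planted_region_id]
    modules = sorted(set(region_to_module.values()))
    others = [m for m in modules if m != planted_module]
    visual_module = others[0] if others else planted_module
    return sorted(r for r, m in region_to_module.items()
                  if m == visual_module and r != planted_region_id)


def generate_dataset(config: SyntheticConfig
                     ) -> tuple[list[BetaImageSet], GroundTruth]:
    """Generate per-subject beta-image sets plus ground truth.

    Deterministic given ``config.seed``; latent patterns are drawn once per
    subject (the analysis is within-subject) and module latent series are
    i.i.d. standard normal per instance and phase.
    """
    atlas, region_names, region_to_module = generate_atlas(
        config.grid_shape, config.n_regions, config.seed, config.n_modules)
    mask = atlas > 0
    planted_mask = atlas == config.planted_region_id
    visual_ids = _visual_regions(region_to_module, config.planted_region_id)
    visual_mask = np.isin(atlas, visual_ids)

    gt = GroundTruth(
        atlas=atlas, region_names=region_names,
        region_to_module=region_to_module,
        planted_region_id=config.planted_region_id,
        planted_mask=planted_mask, visual_region_ids=visual_ids,
        visual_mask=visual_mask,
    )

    # per-voxel module (flat over mask, C order)
    region_flat = atlas[mask]
    module_flat = np.array([region_to_module[r] for r in region_flat])
    planted_flat = planted_mask[mask]
    visual_flat = visual_mask[mask]
    n_maskvox = int(mask.sum())

    labels = make_design(config.n_associations, config.instances_per_condition,
                         config.runs)
    ret_idx = [i for i, lab in enumerate(labels) if lab.phase == "retrieval"]
    iti_idx = [i for i, lab in enumerate(labels) if lab.phase == "iti"]

    subject_seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    subjects: list[BetaImageSet] = []
    for ss in subject_seeds:
        rng = np.random.default_rng(ss)
        assoc_pat = {aid: rng.standard_normal(int(planted_flat.sum()))
                     for aid in range(1, config.n_associations + 1)}
        cat_pat = {cat: rng.standard_normal(int(visual_flat.sum()))
                   for cat in ("face", "house", "body")}
        series = {phase: rng.standard_normal((config.n_modules, len(idx)))
                  for phase, idx in (("retrieval", ret_idx), ("iti", iti_idx))}

        flat = np.zeros((n_maskvox, len(labels)))
        for phase, idx in (("retrieval", ret_idx), ("iti", iti_idx)):
            S = series[phase]  # (n_modules, n_phase_instances)
            flat[:, idx] += config.module_coupling * S[module_flat, :]
            if phase == "retrieval" and config.hub_effect > 0:
                other = S.sum(axis=0)[None, :] - S[module_flat[planted_flat], :]
                flat[np.ix_(planted_flat, idx)] += config.hub_effect * other
        for jj, i in enumerate(ret_idx):
            lab = labels[i]
            if config.conjunctive_effect > 0:
                flat[planted_flat, i] += (config.conjunctive_effect
                                          * assoc_pat[lab.association_id])
            if config.perceptual_effect > 0:
                flat[visual_flat, i] += config.perceptual_effect * (
                    cat_pat[lab.cue_category] + 0.5 * cat_pat[lab.associate_category])
        if config.noise_sd > 0:
            flat += rng.normal(0.0, config.noise_sd, size=flat.shape)

        data = np.zeros(config.grid_shape + (len(labels),))
        data[mask] = flat
        subjects.append(BetaImageSet(data=data, labels=list(labels), mask=mask))
        gt.association_patterns.append(assoc_pat)
        gt.category_patterns.append(cat_pat)
    return subjects, gt
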