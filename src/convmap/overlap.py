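"""Spatial overlap of binarized conjunctiveness and hubness masks.

Observed Dice and relative overlap are computed on a target-region union and
compared against a null built by re-drawing the same number of atlas regions
uniformly at random (with the target redrawable — the null permutes region
labels, it does not exclude the hypothesis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr, wilcoxon

from convmap.types import StatMap

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    dice: float
    relative_overlap: float
    p_dice: float
    p_relative: float
    n_permutations: int
    n_regions_drawn: int
    seed: int
    target_region_ids: list[int] = field(default_factory=list)
    null_dice: np.ndarray = field(default_factory=lambda: np.array([]))
    null_relative: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "relative_overlap": self.relative_overlap,
            "p_dice": self.p_dice,
            "p_relative": self.p_relative,
            "n_permutations": self.n_permutations,
            "n_regions_drawn": self.n_regions_drawn,
            "seed": self.seed,
            "target_region_ids": list(self.target_region_ids),
            "null_dice": self.null_dice.tolist(),
            "null_relative": self.null_relative.tolist(),
        }


def dice_coefficient(h: np.ndarray, c: np.ndarray) -> float:
    """2|H and C| / (|H| + |C|); 0 when both masks are empty."""
    h = np.asarray(h, dtype=bool).ravel()
    c = np.asarray(c, dtype=bool).ravel()
    if h.size != c.size:
        raise ValueError(f"length mismatch: {h.size} vs {c.size}")
    denom = int(h.sum()) + int(c.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((h & c).sum()) / denom


def relative_overlap(h: np.ndarray, c: np.ndarray, n: int) -> float:
    """|H and C| / n, the overlap extent relative to ROI size."""
    h = np.asarray(h, dtype=bool).ravel()
    c = np.asarray(c, dtype=bool).ravel()
    if h.size != c.size:
        raise ValueError(f"length mismatch: {h.size} vs {c.size}")
    if n <= 0:
        raise ValueError("ROI size n must be positive")
    return int((h & c).sum()) / n


def spatial_resampling_test(conj_mask: np.ndarray, hub_mask: np.ndarray,
                            atlas: np.ndarray, target_region_ids,
                            n_perm: int = 10000, n_draw: int = 2,
                            seed: int = 0) -> OverlapResult:
    """Overlap in the target regions against a random-region null.

    Each permutation draws ``n_draw`` distinct atlas regions uniformly and
    scores the same two statistics on their union; p-values use the add-one
    estimator with ties counting against the hypothesis.
    """
    atlas = np.asarray(atlas)
    conj_mask = np.asarray(conj_mask, dtype=bool)
    hub_mask = np.asarray(hub_mask, dtype=bool)
    if conj_mask.shape != atlas.shape or hub_mask.shape != atlas.shape:
        raise ValueError("masks and atlas must share one grid")
    region_ids = [int(r) for r in np.unique(atlas[atlas > 0])]
    targets = [int(t) for t in target_region_ids]
    missing = set(targets) - set(region_ids)
    if missing:
        raise ValueError(f"target regions {sorted(missing)} absent from atlas")
    if len(region_ids) <= n_draw:
        raise ValueError(
            f"atlas has {len(region_ids)} regions; need more than n_draw={n_draw}")

    def score(roi: np.ndarray) -> tuple[float, float]:
        h = hub_mask[roi]
        c = conj_mask[roi]
        return dice_coefficient(h, c), relative_overlap(h, c, int(roi.sum()))

    obs_roi = np.isin(atlas, targets)
    obs_dice, obs_rel = score(obs_roi)
    rng = np.random.default_rng(seed)
    null_dice = np.empty(n_perm)
    null_rel = np.empty(n_perm)
    ids = np.array(region_ids)
    for k in range(n_perm):
        drawn = rng.choice(ids, size=n_draw, replace=False)
        null_dice[k], null_rel[k] = score(np.isin(atlas, drawn))
    p_dice = (1.0 + np.sum(null_dice >= obs_dice)) / (n_perm + 1.0)
    p_rel = (1.0 + np.sum(null_rel >= obs_rel)) / (n_perm + 1.0)
    return OverlapResult(dice=obs_dice, relative_overlap=obs_rel,
                         p_dice=float(p_dice), p_relative=float(p_rel),
                         n_permutations=n_perm, n_regions_drawn=n_draw,
                         seed=seed, target_region_ids=targets,
                         null_dice=null_dice, null_relative=null_rel)


def metric_correlation(conj_maps: list[StatMap], hub_maps: list[StatMap],
                       roi_mask: np.ndarray) -> dict:
    """Across-voxel Spearman rho per subject plus a group signed-rank test.

    Subjects with a constant map inside the ROI (rho undefined) are excluded
    with a warning. The Wilcoxon test is two-tailed against rho = 0.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() < 5:
        raise ValueError("ROI must contain at least 5 voxels")
    if len(conj_maps) != len(hub_maps):
        raise ValueError("subject count mismatch between map lists")
    rhos = []
    for s, (cm, hm) in enumerate(zip(conj_maps, hub_maps)):
        roi = roi_mask & cm.mask & hm.mask
        c = cm.values[roi]
        h = hm.values[roi]
        if c.size < 5 or np.all(c == c[0]) or np.all(h == h[0]):
            logger.warning("subject %d: constant map in ROI, rho excluded", s)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearmanr(c, h).statistic
        if np.isfinite(rho):
            rhos.append(float(rho))
    if len(rhos) < 2:
        raise ValueError("fewer than 2 subjects with defined rho")
    res = wilcoxon(rhos, alternative="two-sided")
    return {"rho": rhos, "wilcoxon_statistic": float(res.statistic),
            "p": float(res.pvalue), "n": len(rhos)}
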