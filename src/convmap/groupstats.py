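"""Group-level nonparametric inference on subject maps.

The one-sample test flips each subject's map by a random sign to build the
null of the voxel-wise t statistic. When 2^n_subjects fits in the
permutation budget the full flip set is enumerated (exact p); otherwise
Monte-Carlo flips with the add-one estimator are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from convmap.types import BetaImageSet, StatMap

logger = logging.getLogger(__name__)

_SIDES = ("greater", "less", "two-sided")


@dataclass
class GroupResult:
    t: StatMap
    p: StatMap
    n_permutations: int
    seed: int
    exhaustive: bool
    undefined: np.ndarray  # zero-variance zero-mean voxels, p forced to 1


def _t_from_moments(mean: np.ndarray, ssq: np.ndarray, n: int) -> np.ndarray:
    """t statistics from per-voxel means and sums of squares.

    sd == 0 with nonzero mean maps to +/-inf (a constant nonzero map is
    maximal evidence under sign flips); sd == 0 with zero mean maps to 0.
    """
    var = (ssq - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    zero_sd = var == 0
    t[zero_sd & (mean > 0)] = np.inf
    t[zero_sd & (mean < 0)] = -np.inf
    t[zero_sd & (mean == 0)] = 0.0
    return t


def _sign_matrix(n_subjects: int, n_perm: int, seed: int
                 ) -> tuple[np.ndarray, bool]:
    if 2 ** n_subjects <= n_perm:
        codes = np.arange(2 ** n_subjects)
        bits = (codes[:, None] >> np.arange(n_subjects)[None, :]) & 1
        return 1 - 2 * bits.astype(np.float64), True
    rng = np.random.default_rng(seed)
    return rng.choice([-1.0, 1.0], size=(n_perm, n_subjects)), False


def signflip_permutation_test(subject_maps: list[StatMap], n_perm: int = 10000,
                              side: str = "greater", seed: int = 0
                              ) -> GroupResult:
    """Voxel-wise one-sample t-test with a sign-flip permutation null."""
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}")
    if len(subject_maps) < 3:
        raise ValueError("need at least 3 subjects")
    mask = np.logical_and.reduce([m.mask for m in subject_maps])
    if not mask.any():
        raise ValueError("no voxel is in every subject's mask")
    X = np.stack([m.values[mask] for m in subject_maps])  # (S, V)
    n, n_vox = X.shape
    ssq = (X ** 2).sum(axis=0)
    obs_t = _t_from_moments(X.mean(axis=0), ssq, n)
    undefined_flat = (X.std(axis=0) == 0) & (X.mean(axis=0) == 0)

    signs, exhaustive = _sign_matrix(n, n_perm, seed)
    n_draws = signs.shape[0]
    if side == "greater":
        obs_cmp = obs_t
    elif side == "less":
        obs_cmp = -obs_t
    else:
        obs_cmp = np.abs(obs_t)
    count = np.zeros(n_vox)
    chunk = max(1, int(2 ** 22 // max(n_vox, 1)))
    for start in range(0, n_draws, chunk):
        S = signs[start:start + chunk]
        mean_f = (S @ X) / n
        t_f = _t_from_moments(mean_f, np.broadcast_to(ssq, mean_f.shape).copy(), n)
        if side == "greater":
            count += (t_f >= obs_cmp).sum(axis=0)
        elif side == "less":
            count += (-t_f >= obs_cmp).sum(axis=0)
        else:
            count += (np.abs(t_f) >= obs_cmp).sum(axis=0)
    if exhaustive:
        p_flat = count / n_draws
    else:
        p_flat = (1.0 + count) / (n_draws + 1.0)
    p_flat[undefined_flat] = 1.0
    if undefined_flat.any():
        logger.warning("%d zero-variance zero-mean voxels: p set to 1",
                       int(undefined_flat.sum()))

    t_vol = np.zeros(mask.shape)
    p_vol = np.ones(mask.shape)
    t_finite = np.where(np.isfinite(obs_t), obs_t, np.sign(obs_t) * 1e12)
    t_vol[mask] = t_finite
    p_vol[mask] = p_flat
    undef_vol = np.zeros(mask.shape, dtype=bool)
    undef_vol[mask] = undefined_flat
    t_map = StatMap(values=t_vol, mask=mask, level="group", metric="t",
                    p=p_vol)
    p_map = StatMap(values=p_vol, mask=mask, level="group", metric="p")
    return GroupResult(t=t_map, p=p_map, n_permutations=n_draws, seed=seed,
                       exhaustive=exhaustive, undefined=undef_vol)


def binarize_map(p_map: StatMap, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of voxels with p < alpha (inside the map's mask)."""
    return (p_map.values < alpha) & p_map.mask


def posthoc_breakdown(betas: BetaImageSet, roi_mask: np.ndarray
                      ) -> dict[str, float]:
    """Demeaned mean ROI pattern similarity for the four comparison types.

    Types cross association identity (same/different) with cue-associate
    order (same/different); no perception-penalty exclusions are applied.
    The four means are demeaned within subject, so they sum to 0.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    roi = roi_mask & betas.mask
    if roi.sum() < 3:
        raise ValueError("ROI must contain at least 3 in-mask voxels")
    labels = betas.phase_labels("retrieval")
    idx = betas.phase_indices("retrieval")
    patterns = betas.data[roi][:, idx].T  # (n_instances, n_roi_voxels)
    ranked = rankdata(patterns, axis=1)
    sim = np.corrcoef(ranked)
    sums = {k: 0.0 for k in ("same_assoc_same_order", "same_assoc_diff_order",
                             "diff_assoc_same_order", "diff_assoc_diff_order")}
    counts = dict.fromkeys(sums, 0)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            key = ("same" if a.association_id == b.association_id else "diff")
            key += "_assoc_"
            key += "same" if a.order_index == b.order_index else "diff"
            key += "_order"
            sums[key] += sim[i, j]
            counts[key] += 1
    means = {k: sums[k] / counts[k] for k in sums if counts[k] > 0}
    if len(means) < 4:
        raise ValueError("design does not populate all four comparison types")
    grand = sum(means.values()) / 4.0
    return {k: v - grand for k, v in means.items()}
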