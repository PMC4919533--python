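"""Searchlight RSA: balanced associative contrast and conjunctiveness maps.

The contrast encodes the associative-similarity hypothesis with a perception
penalty: same-association cells are included only when the cue-associate
order differs between the two instances, and different-association cells only
when both cue and associate categories match. Everything else (notably
same-association/same-order and mixed-category cells) is excluded, so
category- or order-driven perceptual similarity cannot masquerade as
associative memory information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from convmap.types import BetaImageSet, ConditionLabel, StatMap


@dataclass
class ContrastMatrix:
    """Symmetric cell weights over retrieval condition-instances.

    ``include`` marks the cells entering the GLM; the mean weight over
    included cells is 0 by construction.
    """

    weights: np.ndarray
    include: np.ndarray
    labels: list[ConditionLabel]

    def included_mean(self) -> float:
        return float(self.weights[self.include].mean())


@dataclass
class SimilarityMatrix:
    """Pairwise Spearman correlation between instance patterns.

    Rows/columns of zero-variance patterns are NaN (excluded downstream).
    """

    values: np.ndarray
    labels: list[ConditionLabel]


def cell_rule(a: ConditionLabel, b: ConditionLabel) -> int:
    """Contrast role of one unordered instance pair.

    Returns +1 (same association, different order), -1 (different
    association, identical cue and associate categories), or 0 (excluded).
    """
    if a.association_id == b.association_id:
        return 1 if a.order_index != b.order_index else 0
    if (a.cue_category == b.cue_category
            and a.associate_category == b.associate_category):
        return -1
    return 0


def build_contrast_matrix(labels: list[ConditionLabel]) -> ContrastMatrix:
    """Build the balanced associative contrast for retrieval labels.

    Positive cells get +1/n_pos and negative cells -1/n_neg (counts over
    included upper-triangle cells), making the included-cell mean exactly 0.
    """
    if any(lab.phase != "retrieval" for lab in labels):
        raise ValueError("contrast is defined over retrieval-phase labels only")
    if len({lab.association_id for lab in labels}) < 2:
        raise ValueError("contrast undefined: need at least 2 associations")
    if len({lab.order_index for lab in labels}) < 2:
        raise ValueError("contrast undefined: need both cue-associate orders")
    n = len(labels)
    sign = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            sign[i, j] = sign[j, i] = cell_rule(labels[i], labels[j])
    iu = np.triu_indices(n, k=1)
    n_pos = int((sign[iu] == 1).sum())
    n_neg = int((sign[iu] == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "contrast undefined: design yields no "
            + ("positive (same-association, different-order) "
               if n_pos == 0 else
               "negative (different-association, matching-category) ")
            + "comparisons"
        )
    weights = np.where(sign == 1, 1.0 / n_pos, 0.0)
    weights += np.where(sign == -1, -1.0 / n_neg, 0.0)
    include = sign != 0
    return ContrastMatrix(weights=weights, include=include, labels=list(labels))


def sphere_offsets(radius_voxels: int) -> np.ndarray:
    """Integer offsets with Euclidean norm <= radius."""
    r = int(radius_voxels)
    grid = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1].reshape(3, -1).T
    return grid[(grid ** 2).sum(axis=1) <= r * r]


def searchlight_spheres(mask: np.ndarray, radius_voxels: int = 4,
                        min_voxels: int = 30):
    """Enumerate searchlight spheres over in-mask centres.

    Returns a list of ``(centre, member_indices)`` where member indices point
    into the masked flat ordering (C order of ``mask`` True voxels). Centres
    whose in-mask neighbourhood has fewer than ``min_voxels`` members are
    omitted.
    """
    if radius_voxels < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    offsets = sphere_offsets(radius_voxels)
    flat_index = np.full(mask.shape, -1, dtype=np.int64)
    flat_index[mask] = np.arange(int(mask.sum()))
    centres = np.argwhere(mask)
    shape = np.array(mask.shape)
    spheres = []
    for centre in centres:
        coords = centre[None, :] + offsets
        ok = np.all((coords >= 0) & (coords < shape[None, :]), axis=1)
        coords = coords[ok]
        members = flat_index[coords[:, 0], coords[:, 1], coords[:, 2]]
        members = members[members >= 0]
        if members.size >= min_voxels:
            spheres.append((tuple(int(c) for c in centre), members))
    return spheres


def pattern_similarity(patterns: np.ndarray,
                       labels: list[ConditionLabel] | None = None
                       ) -> SimilarityMatrix:
    """Spearman rank correlation between all instance pattern pairs."""
    patterns = np.asarray(patterns, dtype=np.float64)
    if patterns.shape[1] < 3:
        raise ValueError("need at least 3 voxels per pattern")
    ranked = rankdata(patterns, axis=1)
    sd = ranked.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore"):
        values = np.corrcoef(ranked)
    values[degenerate, :] = np.nan
    values[:, degenerate] = np.nan
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values=values, labels=list(labels or []))


def fit_contrast(sim: SimilarityMatrix | np.ndarray,
                 contrast: ContrastMatrix) -> tuple[float, float]:
    """OLS of included upper-triangle similarities on [intercept, weight].

    Returns (slope, t statistic of the slope).
    """
    values = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim)
    iu = np.triu_indices(values.shape[0], k=1)
    keep = contrast.include[iu]
    y = values[iu][keep]
    w = contrast.weights[iu][keep]
    finite = np.isfinite(y)
    y, w = y[finite], w[finite]
    if np.unique(w).size < 2:
        raise ValueError("degenerate design: fewer than 2 distinct weights")
    X = np.column_stack([np.ones_like(w), w])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = y.size - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)
    slope = float(coef[1])
    t = slope / float(np.sqrt(cov[1, 1])) if cov[1, 1] > 0 else np.nan
    return slope, t


def conjunctiveness_map(betas: BetaImageSet, contrast: ContrastMatrix,
                        spheres) -> StatMap:
    """Per-voxel associative-information slope via searchlight RSA.

    For each sphere: Spearman similarity of retrieval-instance patterns,
    fitted to the contrast; the slope lands on the centre voxel. Voxels with
    no surviving sphere are masked out.
    """
    ret_labels = betas.phase_labels("retrieval")
    if ret_labels != contrast.labels:
        raise ValueError("contrast labels do not match the retrieval labels")
    patterns = betas.phase_data("retrieval")  # (n_instances, n_mask_voxels)

    n = len(ret_labels)
    iu = np.triu_indices(n, k=1)
    keep = contrast.include[iu]
    w = contrast.weights[iu][keep]
    X = np.column_stack([np.ones_like(w), w])
    slope_proj = np.linalg.solve(X.T @ X, X.T)[1]  # fast path, no NaNs

    values = np.zeros(betas.mask.shape)
    out_mask = np.zeros(betas.mask.shape, dtype=bool)
    for centre, members in spheres:
        ranked = rankdata(patterns[:, members], axis=1)
        sd = ranked.std(axis=1)
        if np.all(sd > 0):
            sim = np.corrcoef(ranked)
            slope = float(slope_proj @ sim[iu][keep])
        else:
            sim = pattern_similarity(patterns[:, members])
            try:
                slope, _ = fit_contrast(sim, contrast)
            except ValueError:
                continue
        values[centre] = slope
        out_mask[centre] = True
    return StatMap(values=values, mask=out_mask, level="subject",
                   metric="conjunctiveness")
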