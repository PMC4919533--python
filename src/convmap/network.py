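"""Beta-series connectivity, Louvain modules, and voxel-wise hubness.

Connectivity is the Pearson correlation of voxel (or region-mean) beta
vectors within one phase; negative correlations are zeroed and positive
edges are kept only when their Benjamini-Hochberg-adjusted p-value passes
``fdr_alpha``. Hubness is the participation coefficient

    PC_i = 1 - sum_s (e_is / k_i)^2

with e_is the summed weight of node i's edges into module s and k_i its
total edge weight (binary mode counts edges instead). Eigenvector centrality
is provided as a control metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from scipy.stats import false_discovery_control

from convmap.types import BetaImageSet, StatMap

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityGraph:
    """Symmetric nonnegative weighted adjacency over subsampled voxel nodes."""

    adjacency: np.ndarray
    node_coords: np.ndarray  # (n_nodes, 3) voxel indices on the graph's grid
    grid_shape: tuple[int, int, int]
    phase: str

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=np.float64)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(A < 0):
            raise ValueError("adjacency must be nonnegative")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(A, 0.0)
        self.adjacency = A


@dataclass
class ModulePartition:
    """Region -> module assignment from Louvain modularity detection."""

    region_to_module: dict[int, int]

    @property
    def n_modules(self) -> int:
        return len(set(self.region_to_module.values()))

    def node_modules(self, node_regions: np.ndarray) -> np.ndarray:
        return np.array([self.region_to_module[int(r)] for r in node_regions])


def subsample_betas(betas: BetaImageSet, factor: int) -> BetaImageSet:
    """Average non-overlapping factor^3 blocks of in-mask voxels.

    Blocks without any in-mask voxel are dropped from the output mask;
    voxel size scales by ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    shape = betas.data.shape[:3]
    if factor > min(shape):
        raise ValueError(f"factor {factor} larger than grid dimension {min(shape)}")
    out_shape = tuple(-(-s // factor) for s in shape)
    n_vol = betas.data.shape[3]
    sums = np.zeros(out_shape + (n_vol,))
    counts = np.zeros(out_shape)
    coords = np.argwhere(betas.mask)
    blocks = coords // factor
    np.add.at(sums, (blocks[:, 0], blocks[:, 1], blocks[:, 2]),
              betas.data[betas.mask])
    np.add.at(counts, (blocks[:, 0], blocks[:, 1], blocks[:, 2]), 1)
    out_mask = counts > 0
    data = np.zeros_like(sums)
    data[out_mask] = sums[out_mask] / counts[out_mask][:, None]
    return BetaImageSet(data=data, labels=list(betas.labels), mask=out_mask,
                        voxel_size_mm=betas.voxel_size_mm * factor)


def block_majority_labels(atlas: np.ndarray, mask: np.ndarray,
                          factor: int, out_mask: np.ndarray) -> np.ndarray:
    """Most frequent in-mask atlas label per factor^3 block, for out_mask
    blocks, in C order of out_mask True voxels (ties -> smallest label)."""
    coords = np.argwhere(mask)
    blocks = coords // factor
    labels = atlas[mask]
    out_shape = out_mask.shape
    votes: dict[tuple[int, int, int], dict[int, int]] = {}
    for (bx, by, bz), lab in zip(map(tuple, blocks), labels):
        votes.setdefault((bx, by, bz), {}).setdefault(int(lab), 0)
        votes[(bx, by, bz)][int(lab)] += 1
    out = np.zeros(out_shape, dtype=np.int64)
    for key, counter in votes.items():
        best = max(sorted(counter), key=lambda k: counter[k])
        out[key] = best
    return out[out_mask]


def _correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform with n-2 df."""
    df = n - 2
    rc = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rc * np.sqrt(df / (1.0 - rc ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(rc) >= 1.0] = 0.0
    return p


def _threshold_edges(r: np.ndarray, n_obs: int, fdr_alpha: float) -> np.ndarray:
    """Zero negatives, keep positive edges passing BH FDR over positive pairs."""
    n = r.shape[0]
    A = np.where(r > 0, r, 0.0)
    np.fill_diagonal(A, 0.0)
    iu = np.triu_indices(n, k=1)
    pos = A[iu] > 0
    if pos.any():
        p = _correlation_pvalues(r[iu][pos], n_obs)
        padj = false_discovery_control(p, method="bh")
        keep = np.zeros(pos.size, dtype=bool)
        keep[pos] = padj < fdr_alpha
        W = np.zeros_like(A)
        vals = np.where(keep, A[iu], 0.0)
        W[iu] = vals
        W = W + W.T
    else:
        W = np.zeros_like(A)
    return W


def build_connectivity(betas: BetaImageSet, phase: str,
                       fdr_alpha: float = 0.05) -> ConnectivityGraph:
    """Voxel-by-voxel beta-series connectivity for one phase."""
    X = betas.phase_data(phase)  # (n_instances, n_nodes)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 instances for correlation p-values")
    sd = X.std(axis=0)
    dead = sd == 0
    if dead.any():
        logger.warning("%d zero-variance nodes: edges set to 0", int(dead.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[dead, :] = 0.0
    r[:, dead] = 0.0
    W = _threshold_edges(r, X.shape[0], fdr_alpha)
    return ConnectivityGraph(adjacency=W, node_coords=np.argwhere(betas.mask),
                             grid_shape=betas.mask.shape, phase=phase)


def region_graph(betas: BetaImageSet, atlas: np.ndarray, phase: str,
                 fdr_alpha: float = 0.05) -> tuple[list[int], np.ndarray]:
    """Region-by-region connectivity from region-averaged beta vectors."""
    atlas = np.asarray(atlas)
    if atlas.shape != betas.mask.shape:
        raise ValueError("atlas grid does not match beta grid")
    idx = betas.phase_indices(phase)
    region_ids, means = [], []
    for rid in np.unique(atlas[atlas > 0]):
        sel = (atlas == rid) & betas.mask
        if not sel.any():
            logger.warning("region %d empty, excluded from region graph", rid)
            continue
        region_ids.append(int(rid))
        means.append(betas.data[sel][:, idx].mean(axis=0))
    M = np.asarray(means)  # (n_regions, n_instances)
    sd = M.std(axis=1)
    dead = sd == 0
    if dead.any():
        logger.warning("%d zero-variance regions in region graph", int(dead.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(M)
    r = np.atleast_2d(r)
    r[dead, :] = 0.0
    r[:, dead] = 0.0
    W = _threshold_edges(r, idx.size, fdr_alpha)
    return region_ids, W


def louvain_partition(region_ids: list[int], adjacency: np.ndarray,
                      seed: int = 0) -> ModulePartition:
    """Louvain modularity partition of the region graph (seeded, one run)."""
    if len(region_ids) == 0:
        raise ValueError("empty region graph")
    if not np.any(adjacency > 0):
        logger.warning("region graph has no edges: one module per region")
        return ModulePartition({rid: i for i, rid in enumerate(region_ids)})
    G = nx.Graph()
    G.add_nodes_from(region_ids)
    n = len(region_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if adjacency[i, j] > 0:
                G.add_edge(region_ids[i], region_ids[j], weight=adjacency[i, j])
    communities = nx.community.louvain_communities(G, weight="weight", seed=seed)
    mapping = {}
    for mid, members in enumerate(sorted(communities, key=min)):
        for rid in members:
            mapping[int(rid)] = mid
    return ModulePartition(mapping)


def participation_coefficient(adjacency: np.ndarray, node_modules: np.ndarray,
                              weighted: bool = True) -> np.ndarray:
    """PC_i = 1 - sum_s (e_is / k_i)^2; isolated nodes get PC 0.

    ``weighted=False`` counts edges instead of summing weights.
    """
    A = np.asarray(adjacency, dtype=np.float64)
    if not weighted:
        A = (A > 0).astype(np.float64)
    modules = np.asarray(node_modules)
    uniq = np.unique(modules)
    onehot = (modules[:, None] == uniq[None, :]).astype(np.float64)
    E = A @ onehot  # (n_nodes, n_modules)
    k = A.sum(axis=1)
    pc = np.zeros_like(k)
    nz = k > 0
    pc[nz] = 1.0 - ((E[nz] / k[nz, None]) ** 2).sum(axis=1)
    return np.clip(pc, 0.0, 1.0)


def eigenvector_centrality(adjacency: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the adjacency, nonnegative, unit 2-norm."""
    A = np.asarray(adjacency, dtype=np.float64)
    if not np.any(A):
        logger.warning("all-zero graph: eigenvector centrality set to 0")
        return np.zeros(A.shape[0])
    vals, vecs = np.linalg.eigh(A)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    return v / np.linalg.norm(v)


def hubness_statmap(values: np.ndarray, graph: ConnectivityGraph,
                    metric: str) -> StatMap:
    vol = np.zeros(graph.grid_shape)
    mask = np.zeros(graph.grid_shape, dtype=bool)
    xs, ys, zs = graph.node_coords.T
    vol[xs, ys, zs] = values
    mask[xs, ys, zs] = True
    return StatMap(values=vol, mask=mask, level="subject",
                   metric=f"{metric}_{graph.phase}")


def hubness_contrast(retrieval: StatMap, iti: StatMap) -> StatMap:
    """Voxel-wise retrieval - ITI hubness difference."""
    if retrieval.values.shape != iti.values.shape:
        raise ValueError("hubness maps on different grids")
    base_r = retrieval.metric.rsplit("_", 1)[0]
    base_i = iti.metric.rsplit("_", 1)[0]
    if base_r != base_i:
        raise ValueError(f"metric mismatch: {retrieval.metric} vs {iti.metric}")
    mask = retrieval.mask & iti.mask
    values = np.zeros_like(retrieval.values)
    values[mask] = retrieval.values[mask] - iti.values[mask]
    return StatMap(values=values, mask=mask, level="subject",
                   metric=f"{base_r}_contrast")


def upsample_map(statmap: StatMap, factor: int,
                 target_shape: tuple[int, int, int]) -> StatMap:
    """Block-replicate a subsampled map back to the analysis grid."""
    values = np.repeat(np.repeat(np.repeat(statmap.values, factor, axis=0),
                                 factor, axis=1), factor, axis=2)
    mask = np.repeat(np.repeat(np.repeat(statmap.mask, factor, axis=0),
                               factor, axis=1), factor, axis=2)
    sl = tuple(slice(0, s) for s in target_shape)
    return StatMap(values=values[sl], mask=mask[sl], level=statmap.level,
                   metric=statmap.metric)


def subject_hubness(betas: BetaImageSet, atlas: np.ndarray,
                    subsample_factor: int = 4, fdr_alpha: float = 0.05,
                    metric: str = "pc", seed: int = 0,
                    share_partition: bool = False
                    ) -> dict[str, StatMap]:
    """Retrieval / ITI hubness maps and their contrast for one subject.

    Per phase: region graph from analysis-grid betas -> Louvain partition;
    voxel graph from subsampled betas; nodes inherit their block-majority
    region's module. With ``share_partition`` the retrieval partition is
    reused for the ITI phase.
    """
    if metric not in ("pc", "evc"):
        raise ValueError(f"metric must be pc|evc, got {metric!r}")
    sub = subsample_betas(betas, subsample_factor)
    node_regions = block_majority_labels(atlas, betas.mask, subsample_factor,
                                         sub.mask)
    maps: dict[str, StatMap] = {}
    partition = None
    for phase in ("retrieval", "iti"):
        graph = build_connectivity(sub, phase, fdr_alpha=fdr_alpha)
        if metric == "pc":
            if partition is None or not share_partition:
                rids, W = region_graph(betas, atlas, phase, fdr_alpha=fdr_alpha)
                partition = louvain_partition(rids, W, seed=seed)
            values = participation_coefficient(
                graph.adjacency, partition.node_modules(node_regions))
        else:
            values = eigenvector_centrality(graph.adjacency)
        maps[phase] = hubness_statmap(values, graph, metric)
    maps["contrast"] = hubness_contrast(maps["retrieval"], maps["iti"])
    return maps
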