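import itertools

import numpy as np
import pytest
from scipy.stats import pearsonr

from convmap import network
from convmap.synth import make_design
from convmap.types import BetaImageSet


def beta_set_from_matrix(X, grid=(3, 3, 2), labels=None, mask=None):
    """Wrap an (instances x voxels) matrix into a BetaImageSet."""
    if labels is None:
        labels = make_design(6, 2, 2)  # 48 retrieval + 48 iti
    if mask is None:
        mask = np.ones(grid, bool)
    data = np.zeros(grid + (len(labels),))
    data[mask] = X.T
    return BetaImageSet(data=data, labels=labels, mask=mask)


class TestSubsample:
    def test_voxel_size_scaling(self, tiny_dataset):
        _, subjects, _ = tiny_dataset
        sub = network.subsample_betas(subjects[0], 2)
        assert sub.voxel_size_mm == subjects[0].voxel_size_mm * 2
        assert sub.data.shape[:3] == (5, 5, 5)

    def test_constant_volume(self):
        labels = make_design(6, 1, 1)
        data = np.full((4, 4, 4, len(labels)), 7.0)
        betas = BetaImageSet(data=data, labels=labels,
                             mask=np.ones((4, 4, 4), bool))
        sub = network.subsample_betas(betas, 2)
        assert np.allclose(sub.data[sub.mask], 7.0)

    def test_block_mean_oracle(self, rng):
        # each output voxel equals the arithmetic mean of its in-mask sources
        labels = make_design(6, 1, 1)
        mask = rng.random((4, 4, 4)) > 0.3
        data = rng.normal(size=(4, 4, 4, len(labels)))
        betas = BetaImageSet(data=data, labels=labels, mask=mask)
        sub = network.subsample_betas(betas, 2)
        for bx, by, bz in itertools.product(range(2), repeat=3):
            block_mask = mask[2 * bx:2 * bx + 2, 2 * by:2 * by + 2,
                              2 * bz:2 * bz + 2]
            block = data[2 * bx:2 * bx + 2, 2 * by:2 * by + 2,
                         2 * bz:2 * bz + 2]
            if block_mask.any():
                assert sub.mask[bx, by, bz]
                np.testing.assert_allclose(sub.data[bx, by, bz],
                                           block[block_mask].mean(axis=0))
            else:
                assert not sub.mask[bx, by, bz]

    def test_factor_too_large(self, tiny_dataset):
        _, subjects, _ = tiny_dataset
        with pytest.raises(ValueError, match="factor"):
            network.subsample_betas(subjects[0], 11)


class TestBuildConnectivity:
    def test_identical_vectors_edge_one(self, rng):
        v = rng.normal(size=48)
        X = np.column_stack([v, v] + [rng.normal(size=48) for _ in range(16)])
        betas = beta_set_from_matrix(np.vstack([X, X]))
        g = network.build_connectivity(betas, "retrieval")
        assert g.adjacency[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_edge_zero(self, rng):
        v = rng.normal(size=48)
        X = np.column_stack([v, -v] + [rng.normal(size=48) for _ in range(16)])
        betas = beta_set_from_matrix(np.vstack([X, X]))
        g = network.build_connectivity(betas, "retrieval")
        assert g.adjacency[0, 1] == 0.0

    def test_bh_oracle(self, rng):
        # independent BH step-up on the positive pairs' pearsonr p-values
        X = rng.normal(size=(96, 18))
        labels = make_design(12, 2, 2)
        betas = beta_set_from_matrix(np.vstack([X, X[::-1]]), labels=labels)
        g = network.build_connectivity(betas, "retrieval", fdr_alpha=0.2)
        n = 18
        pairs, ps = [], []
        for i, j in itertools.combinations(range(n), 2):
            r, p = pearsonr(X[:, i], X[:, j])
            if r > 0:
                pairs.append((i, j, r))
                ps.append(p)
        order = np.argsort(ps)
        m = len(ps)
        thresh_rank = 0
        for rank, idx in enumerate(order, start=1):
            if ps[idx] <= rank / m * 0.2:
                thresh_rank = rank
        keep = set()
        for rank, idx in enumerate(order, start=1):
            if rank <= thresh_rank:
                keep.add(idx)
        expected = np.zeros((n, n))
        for idx in keep:
            i, j, r = pairs[idx]
            expected[i, j] = expected[j, i] = r
        np.testing.assert_allclose(g.adjacency, expected, atol=1e-10)

    def test_zero_variance_node(self, rng, caplog):
        X = rng.normal(size=(48, 18))
        X[:, 3] = 5.0
        betas = beta_set_from_matrix(np.vstack([X, X]))
        with caplog.at_level("WARNING"):
            g = network.build_connectivity(betas, "retrieval")
        assert np.all(g.adjacency[3] == 0)
        assert "zero-variance" in caplog.text

    def test_threshold_monotone_in_alpha(self, rng):
        X = rng.normal(size=(48, 18))
        betas = beta_set_from_matrix(np.vstack([X, X]))
        loose = network.build_connectivity(betas, "retrieval", fdr_alpha=0.5)
        tight = network.build_connectivity(betas, "retrieval", fdr_alpha=0.05)
        assert np.all((tight.adjacency > 0) <= (loose.adjacency > 0))

    def test_too_few_instances(self, rng):
        labels = make_design(3, 1, 1)[:3] + make_design(3, 1, 1)[6:9]
        data = rng.normal(size=(3, 3, 2, 6))
        betas = BetaImageSet(data=data, labels=labels,
                             mask=np.ones((3, 3, 2), bool))
        with pytest.raises(ValueError, match="4 instances"):
            network.build_connectivity(betas, "retrieval")


class TestRegionGraph:
    def test_four_region_toy_oracle(self, rng):
        atlas = np.zeros((4, 4, 1), dtype=int)
        atlas[:2, :2, 0], atlas[:2, 2:, 0] = 1, 2
        atlas[2:, :2, 0], atlas[2:, 2:, 0] = 3, 4
        labels = make_design(6, 2, 2)
        data = rng.normal(size=(4, 4, 1, len(labels)))
        betas = BetaImageSet(data=data, labels=labels,
                             mask=np.ones((4, 4, 1), bool))
        rids, W = network.region_graph(betas, atlas, "retrieval",
                                       fdr_alpha=0.9)
        assert rids == [1, 2, 3, 4]
        idx = betas.phase_indices("retrieval")
        means = [data[atlas == r][:, idx].mean(axis=0) for r in rids]
        for i, j in itertools.combinations(range(4), 2):
            r, p = pearsonr(means[i], means[j])
            if r <= 0:
                assert W[i, j] == 0.0
            elif W[i, j] > 0:
                assert W[i, j] == pytest.approx(r)

    def test_identical_region_means_edge_one(self):
        atlas = np.zeros((4, 2, 1), dtype=int)
        atlas[:2], atlas[2:] = 1, 2
        labels = make_design(6, 1, 1)
        v = np.sin(np.arange(len(labels)))
        data = np.tile(v, (4, 2, 1, 1))
        betas = BetaImageSet(data=data, labels=labels,
                             mask=np.ones((4, 2, 1), bool))
        _, W = network.region_graph(betas, atlas, "retrieval")
        assert W[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_region_means_zero(self):
        atlas = np.zeros((4, 2, 1), dtype=int)
        atlas[:2], atlas[2:] = 1, 2
        labels = make_design(6, 1, 1)
        v = np.sin(np.arange(len(labels)))
        data = np.empty((4, 2, 1, len(labels)))
        data[:2], data[2:] = v, -v
        betas = BetaImageSet(data=data, labels=labels,
                             mask=np.ones((4, 2, 1), bool))
        _, W = network.region_graph(betas, atlas, "retrieval")
        assert W[0, 1] == 0.0

    def test_empty_region_excluded(self, rng, caplog):
        atlas = np.ones((4, 2, 1), dtype=int)
        atlas[2:] = 3  # region 2 missing entirely
        labels = make_design(6, 1, 1)
        data = rng.normal(size=(4, 2, 1, len(labels)))
        mask = np.ones((4, 2, 1), bool)
        mask[atlas == 3] = False  # region 3 present but outside the mask
        betas = BetaImageSet(data=data, labels=labels, mask=mask)
        with caplog.at_level("WARNING"):
            rids, W = network.region_graph(betas, atlas, "retrieval")
        assert rids == [1]
        assert "excluded" in caplog.text


def modularity(adjacency, communities):
    """Independent Newman modularity for the Louvain oracle."""
    A = adjacency
    k = A.sum(axis=1)
    two_m = A.sum()
    q = 0.0
    for comm in communities:
        for i in comm:
            for j in comm:
                q += A[i, j] - k[i] * k[j] / two_m
    return q / two_m


class TestLouvain:
    def test_two_disconnected_cliques(self):
        n = 10
        A = np.zeros((n, n))
        for block in (range(5), range(5, 10)):
            for i, j in itertools.combinations(block, 2):
                A[i, j] = A[j, i] = 1.0
        part = network.louvain_partition(list(range(1, n + 1)), A, seed=0)
        assert part.n_modules == 2
        mods = [part.region_to_module[r] for r in range(1, n + 1)]
        assert len(set(mods[:5])) == 1 and len(set(mods[5:])) == 1
        assert mods[0] != mods[5]

    def test_single_region(self):
        part = network.louvain_partition([1], np.zeros((1, 1)), seed=0)
        assert part.n_modules == 1

    def test_no_edges_singletons(self, caplog):
        with caplog.at_level("WARNING"):
            part = network.louvain_partition([1, 2, 3], np.zeros((3, 3)), seed=0)
        assert part.n_modules == 3

    def test_planted_two_block_matches_exhaustive(self):
        # oracle: exhaustive 2-partition modularity maximization
        n = 8
        rng = np.random.default_rng(0)
        A = np.full((n, n), 0.05)
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                A[i, j] = A[j, i] = 1.0
        np.fill_diagonal(A, 0.0)
        best_q, best_split = -np.inf, None
        for bits in itertools.product([0, 1], repeat=n - 1):
            split = (0,) + bits
            comm = [[i for i in range(n) if split[i] == s] for s in (0, 1)]
            comm = [c for c in comm if c]
            q = modularity(A, comm)
            if q > best_q:
                best_q, best_split = q, split
        assert best_split == (0, 0, 0, 0, 1, 1, 1, 1)
        part = network.louvain_partition(list(range(1, n + 1)), A, seed=0)
        mods = [part.region_to_module[r] for r in range(1, n + 1)]
        assert len(set(mods[:4])) == 1 and len(set(mods[4:])) == 1
        assert mods[0] != mods[4]

    def test_deterministic(self, rng):
        n = 12
        A = rng.random((n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        p1 = network.louvain_partition(list(range(1, n + 1)), A, seed=5)
        p2 = network.louvain_partition(list(range(1, n + 1)), A, seed=5)
        assert p1.region_to_module == p2.region_to_module


def pc_oracle(A, modules, weighted=True):
    """Brute-force per-node, per-module double loop."""
    if not weighted:
        A = (A > 0).astype(float)
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = sum(A[i, j] for j in range(n))
        if k == 0:
            continue
        acc = 0.0
        for s in set(modules):
            e_is = sum(A[i, j] for j in range(n) if modules[j] == s)
            acc += (e_is / k) ** 2
        out[i] = 1.0 - acc
    return out


class TestParticipationCoefficient:
    def test_provincial_node_zero(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        pc = network.participation_coefficient(A, [0, 0, 1, 1])
        assert np.all(pc == 0.0)

    def test_even_two_module_split(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        A[0, 2] = A[2, 0] = 1.0
        pc = network.participation_coefficient(A, [0, 0, 1])
        assert pc[0] == pytest.approx(0.5)  # 1 - 2*(1/2)^2

    def test_even_spread_limit(self):
        # node spread evenly over NM modules -> 1 - 1/NM
        nm = 4
        A = np.zeros((nm + 1, nm + 1))
        A[0, 1:] = A[1:, 0] = 1.0
        modules = [0] + list(range(nm))
        pc = network.participation_coefficient(A, modules)
        assert pc[0] == pytest.approx(1 - 1 / nm)

    def test_random_graph_oracle(self, rng):
        n = 20
        A = rng.random((n, n)) * (rng.random((n, n)) > 0.5)
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        modules = rng.integers(0, 3, size=n).tolist()
        got = network.participation_coefficient(A, modules)
        np.testing.assert_allclose(got, pc_oracle(A, modules), atol=1e-12)

    def test_binary_equals_weighted_on_binary_graph(self, rng):
        n = 15
        A = (rng.random((n, n)) > 0.6).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        modules = rng.integers(0, 3, size=n).tolist()
        w = network.participation_coefficient(A, modules, weighted=True)
        b = network.participation_coefficient(A, modules, weighted=False)
        np.testing.assert_allclose(w, b)

    def test_isolated_node_zero(self):
        A = np.zeros((3, 3))
        pc = network.participation_coefficient(A, [0, 1, 2])
        assert np.all(pc == 0.0)

    def test_range(self, rng):
        for _ in range(10):
            n = rng.integers(5, 25)
            A = rng.random((n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0)
            modules = rng.integers(0, 4, size=n).tolist()
            pc = network.participation_coefficient(A, modules)
            assert np.all((pc >= 0) & (pc <= 1))


def power_iteration(A, tol=1e-14, max_iter=100000):
    v = np.ones(A.shape[0]) / np.sqrt(A.shape[0])
    for _ in range(max_iter):
        w = A @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return v * 0
        w /= nrm
        if np.linalg.norm(w - v) < tol:
            break
        v = w
    return w


class TestEigenvectorCentrality:
    def test_ring_all_equal(self):
        n = 6
        A = np.zeros((n, n))
        for i in range(n):
            A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1.0
        v = network.eigenvector_centrality(A)
        np.testing.assert_allclose(v, v[0])

    def test_star_centre_maximal(self):
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1.0
        v = network.eigenvector_centrality(A)
        assert v[0] > v[1:].max()

    def test_power_iteration_oracle(self, rng):
        n = 12
        A = rng.random((n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        got = network.eigenvector_centrality(A)
        expected = power_iteration(A)
        if expected.sum() < 0:
            expected = -expected
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_zero_graph(self, caplog):
        with caplog.at_level("WARNING"):
            v = network.eigenvector_centrality(np.zeros((4, 4)))
        assert np.all(v == 0)


class TestHubnessContrast:
    def test_identical_maps_zero(self, tiny_dataset):
        _, subjects, gt = tiny_dataset
        maps = network.subject_hubness(subjects[0], gt.atlas,
                                       subsample_factor=2, seed=0)
        same = network.hubness_contrast(maps["retrieval"], maps["retrieval"])
        assert np.all(same.values[same.mask] == 0)

    def test_antisymmetry(self, tiny_dataset):
        _, subjects, gt = tiny_dataset
        maps = network.subject_hubness(subjects[0], gt.atlas,
                                       subsample_factor=2, seed=0)
        a = network.hubness_contrast(maps["retrieval"], maps["iti"])
        b = network.hubness_contrast(maps["iti"], maps["retrieval"])
        np.testing.assert_allclose(a.values[a.mask], -b.values[b.mask])

    def test_planted_hub_recovered(self, tiny_dataset):
        # generative-model oracle: planted-region voxels load on all
        # modules during retrieval only, so their contrast must dominate
        _, subjects, gt = tiny_dataset
        inside, outside = [], []
        for betas in subjects:
            maps = network.subject_hubness(betas, gt.atlas,
                                           subsample_factor=2, seed=0)
            up = network.upsample_map(maps["contrast"], 2, betas.mask.shape)
            inside.append(up.values[gt.planted_mask & up.mask].mean())
            outside.append(up.values[~gt.planted_mask & up.mask].mean())
        assert np.mean(inside) > np.mean(outside)

    def test_grid_mismatch_error(self, tiny_dataset):
        _, subjects, gt = tiny_dataset
        maps = network.subject_hubness(subjects[0], gt.atlas,
                                       subsample_factor=2, seed=0)
        small = network.subject_hubness(subjects[0], gt.atlas,
                                        subsample_factor=5, seed=0)
        with pytest.raises(ValueError, match="grid"):
            network.hubness_contrast(maps["retrieval"], small["iti"])
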