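"""Clustering, partition-agreement statistics, and the consensus machinery."""

import itertools

import numpy as np
import pytest

from phenofuse import (ModularityModel, coassignment, consensus_partition,
                       modularity, modularity_pvalue, nmi,
                       permutation_threshold, select_stable, spectral_cluster,
                       stability_surface, zrand)
from phenofuse.datatypes import FusedNetwork, Partition

from conftest import block_affinity


def _net(W):
    return FusedNetwork(values=W, patients=[str(i) for i in range(len(W))])


def _parts(label_arrays):
    n = len(label_arrays[0])
    return [Partition(labels=np.asarray(a), patients=[str(i) for i in range(n)])
            for a in label_arrays]


class TestSpectralCluster:
    def test_disjoint_cliques_recovered_exactly(self):
        W = np.zeros((20, 20))
        W[:10, :10] = 1.0
        W[10:, 10:] = 1.0
        p = spectral_cluster(_net(W), k=2, seed=0)
        assert nmi(p.labels, np.repeat([0, 1], 10)) == pytest.approx(1.0)

    def test_planted_three_blocks(self, rng):
        W, labels = block_affinity((12, 10, 8), within=1.0, between=0.05,
                                   noise=0.02, rng=rng)
        p = spectral_cluster(_net(W), k=3, seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels, p.labels) == 1.0

    def test_seed_determinism(self, rng):
        W, _ = block_affinity((8, 8, 8), noise=0.1, rng=rng)
        p1 = spectral_cluster(_net(W), k=3, seed=42)
        p2 = spectral_cluster(_net(W), k=3, seed=42)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_too_many_components_reported(self):
        W = np.kron(np.eye(3), np.ones((4, 4)))
        with pytest.raises(ValueError, match="components"):
            spectral_cluster(_net(W), k=2, seed=0)


class TestZrand:
    def test_identical_partitions_positive(self):
        a = np.repeat([0, 1, 2], 10)
        assert zrand(a, a) > 0

    def test_label_relabeling_invariance(self):
        a = np.repeat([0, 1, 2], 5)
        b = np.array([2, 0, 1])[a]
        assert zrand(a, b) == pytest.approx(zrand(a, a), abs=1e-12)

    def test_exhaustive_permutation_moments_n8(self, rng):
        # z standardizes the co-pair count by its EXACT permutation-model
        # moments: verified by enumerating all 8! relabelings
        for _ in range(3):
            a = rng.integers(0, 3, size=8)
            b = rng.integers(0, 3, size=8)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            iu = np.triu_indices(8, 1)
            same_a = (a[:, None] == a[None, :])[iu]
            ws = []
            for perm in itertools.permutations(range(8)):
                bp = b[list(perm)]
                same_b = (bp[:, None] == bp[None, :])[iu]
                ws.append(int((same_a & same_b).sum()))
            ws = np.array(ws, dtype=float)
            w_obs = float((same_a & (b[:, None] == b[None, :])[iu]).sum())
            expect = (w_obs - ws.mean()) / ws.std()
            assert zrand(a, b) == pytest.approx(expect, abs=1e-6)

    def test_null_mean_zero(self, rng):
        zs = [zrand(rng.integers(0, 3, size=40), rng.integers(0, 3, size=40))
              for _ in range(1000)]
        assert abs(np.mean(zs)) < 3 / np.sqrt(1000)

    def test_degenerate_partitions_return_zero(self):
        a = np.zeros(10, dtype=int)
        b = np.arange(10)
        assert zrand(a, np.repeat([0, 1], 5)) == 0.0
        assert zrand(b, np.repeat([0, 1], 5)) == 0.0


class TestStabilitySurface:
    def test_constant_grid_constant_surface(self):
        base = np.repeat([0, 1, 2], 10)
        grid = np.empty((3, 3), dtype=object)
        for i in range(3):
            for j in range(3):
                grid[i, j] = Partition(labels=base,
                                       patients=[str(x) for x in range(30)])
        surf = stability_surface(grid)
        assert np.allclose(surf, surf[0, 0])
        assert surf[0, 0] == pytest.approx(zrand(base, base))

    def test_deviant_center_scores_lowest(self, rng):
        base = np.repeat([0, 1, 2], 10)
        grid = np.empty((3, 3), dtype=object)
        for i in range(3):
            for j in range(3):
                lab = base if (i, j) != (1, 1) else rng.permutation(base)
                grid[i, j] = Partition(labels=lab,
                                       patients=[str(x) for x in range(30)])
        surf = stability_surface(grid)
        assert surf[1, 1] < surf[0, 0]
        assert surf[1, 1] < surf[2, 2]

    def test_corner_cells_average_two_neighbors(self):
        # corner value equals mean of z-Rand with its 2 existing neighbors
        labs = [np.repeat([0, 1], 5), np.repeat([0, 1], 5),
                np.array([0, 0, 0, 1, 1, 1, 1, 0, 1, 0]),
                np.repeat([1, 0], 5)]
        grid = np.empty((2, 2), dtype=object)
        pts = [str(x) for x in range(10)]
        grid[0, 0] = Partition(labels=labs[0], patients=pts)
        grid[0, 1] = Partition(labels=labs[1], patients=pts)
        grid[1, 0] = Partition(labels=labs[2], patients=pts)
        grid[1, 1] = Partition(labels=labs[3], patients=pts)
        surf = stability_surface(grid)
        expect = np.mean([zrand(labs[0], labs[1]), zrand(labs[0], labs[2])])
        assert surf[0, 0] == pytest.approx(expect, abs=1e-12)


class TestSelectStable:
    def test_pct_zero_retains_all(self, rng):
        surfaces = {k: rng.normal(size=(5, 5)) for k in (2, 3, 4)}
        assert len(select_stable(surfaces, pct=0)) == 25

    def test_constant_surfaces_flagged_empty(self):
        surfaces = {k: np.ones((4, 4)) for k in (2, 3, 4)}
        with pytest.raises(ValueError, match="no grid cell"):
            select_stable(surfaces, pct=95)

    def test_crafted_five_of_hundred(self):
        # three surfaces pooled; exactly 5 cells exceed the pooled 95th
        # percentile, all in one surface
        s_low = np.zeros((10, 10))
        s_mid = np.full((10, 10), 0.5)
        s_hot = np.full((10, 10), 0.5)
        s_hot.flat[:5] = 10.0
        cells = select_stable({2: s_low, 3: s_mid, 4: s_hot}, pct=95)
        assert sorted(cells) == [(0, 0), (0, 1), (0, 2), (0, 3), (0, 4)]
        # each retained cell carries its partitions at all three k
        assert len(cells) * 3 == 15


class TestCoassignment:
    def test_single_partition_binary_blocks(self):
        lab = np.repeat([0, 1], 3)
        C = coassignment(_parts([lab]))
        np.testing.assert_array_equal(C, (lab[:, None] == lab[None, :]))

    def test_half_agreement(self):
        C = coassignment(_parts([[0, 0, 1], [0, 1, 1]]))
        assert C[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(C), 1.0)

    def test_matches_bruteforce(self, rng):
        labs = [rng.integers(0, 3, size=12) for _ in range(50)]
        C = coassignment(_parts(labs))
        for i in range(12):
            for j in range(12):
                expect = np.mean([lab[i] == lab[j] for lab in labs])
                assert C[i, j] == pytest.approx(expect, abs=1e-12)


class TestPermutationThreshold:
    def test_two_equal_clusters_chance_level(self):
        n = 40
        lab = np.repeat([0, 1], n // 2)
        parts = _parts([lab] * 10)
        thr = permutation_threshold(parts, n_perm=200, seed=0)
        chance = (n / 2 - 1) / (n - 1)
        assert thr == pytest.approx(chance, abs=0.01)

    def test_four_clusters_below_two(self):
        n = 40
        p2 = _parts([np.repeat([0, 1], n // 2)] * 5)
        p4 = _parts([np.repeat([0, 1, 2, 3], n // 4)] * 5)
        t2 = permutation_threshold(p2, n_perm=100, seed=0)
        t4 = permutation_threshold(p4, n_perm=100, seed=0)
        assert t4 < t2
        assert t4 == pytest.approx((n / 4 - 1) / (n - 1), abs=0.01)

    def test_seed_determinism(self):
        parts = _parts([np.repeat([0, 1, 2], 5)] * 3)
        assert permutation_threshold(parts, 50, seed=9) == \
            permutation_threshold(parts, 50, seed=9)


class TestConsensusPartition:
    def test_binary_blocks_recovered(self):
        lab = np.repeat([0, 1, 2], 8)
        C = (lab[:, None] == lab[None, :]).astype(float)
        p = consensus_partition(C, threshold=0.5, seed=0, n_restarts=10)
        assert nmi(p.labels, lab) == pytest.approx(1.0)
        assert p.n_clusters == 3

    def test_identity_consistent_pool(self):
        lab = np.repeat([0, 1], 10)
        C = coassignment(_parts([lab] * 7))
        p = consensus_partition(C, threshold=0.4, seed=1, n_restarts=10)
        assert nmi(p.labels, lab) == pytest.approx(1.0)

    def test_disconnected_matrix_reported(self):
        with pytest.raises(ValueError, match="disconnected"):
            consensus_partition(np.eye(6), threshold=0.5, seed=0)

    def test_emergent_cluster_count_not_prespecified(self, rng):
        lab = rng.integers(0, 4, size=40)
        C = (lab[:, None] == lab[None, :]).astype(float)
        p = consensus_partition(C, threshold=0.5, seed=0, n_restarts=10)
        assert p.n_clusters == len(np.unique(lab))
        assert p.source == "consensus"


class TestNmi:
    def test_identical_and_relabeled(self):
        a = np.repeat([0, 1, 2], 7)
        assert nmi(a, a) == pytest.approx(1.0)
        assert nmi(a, np.array([2, 0, 1])[a]) == pytest.approx(1.0)

    def test_hand_contingency_2x2(self):
        # n=10 contingency [[4,1],[2,3]]: entropy arithmetic done by hand
        a = np.array([0] * 5 + [1] * 5)
        b = np.array([0, 0, 0, 0, 1, 0, 0, 1, 1, 1])
        nij = np.array([[4.0, 1.0], [2.0, 3.0]])
        pij = nij / 10
        pa = pij.sum(1, keepdims=True)
        pb = pij.sum(0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            mi = np.nansum(pij * np.log(pij / (pa * pb)))
        ha = -np.sum(pa * np.log(pa))
        hb = -np.sum(pb * np.log(pb))
        assert nmi(a, b) == pytest.approx(mi / ((ha + hb) / 2), abs=1e-10)

    def test_zero_entropy_returns_zero(self):
        assert nmi(np.zeros(8, int), np.repeat([0, 1], 4)) == 0.0


class TestModularity:
    def test_single_cluster_exactly_zero(self, rng):
        W, _ = block_affinity((5, 5), noise=0.1, rng=rng)
        assert modularity(W, np.zeros(10, int)) == pytest.approx(0.0, abs=1e-14)

    def test_matches_bruteforce(self, rng):
        W, labels = block_affinity((4, 4), within=1.0, between=0.2,
                                   noise=0.05, rng=rng)
        model = ModularityModel.from_affinity(W)
        two_m = W.sum()
        deg = W.sum(axis=1)
        q = 0.0
        for i in range(8):
            for j in range(8):
                if labels[i] == labels[j]:
                    q += (W[i, j] - deg[i] * deg[j] / two_m) / two_m
        assert modularity(model, labels) == pytest.approx(q, abs=1e-12)

    def test_planted_beats_random(self, rng):
        W, labels = block_affinity((10, 10), within=1.0, between=0.05,
                                   noise=0.02, rng=rng)
        q_good = modularity(W, labels)
        q_bad = modularity(W, rng.permutation(labels))
        assert q_good > 0 > q_bad - q_good

    def test_null_model_rows_sum_zero(self, rng):
        W, _ = block_affinity((6, 6), noise=0.1, rng=rng)
        model = ModularityModel.from_affinity(W)
        np.testing.assert_allclose(model.B.sum(axis=1), 0.0, atol=1e-10)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="zero total weight"):
            ModularityModel.from_affinity(np.zeros((4, 4)))


class TestModularityPvalue:
    def test_planted_significant_random_not(self, rng):
        W, labels = block_affinity((12, 12), within=1.0, between=0.05,
                                   noise=0.05, rng=rng)
        _, p_good = modularity_pvalue(W, labels, n_perm=999, seed=0)
        _, p_bad = modularity_pvalue(W, rng.permutation(labels), n_perm=999,
                                     seed=0)
        assert p_good < 0.01
        assert p_bad > 0.05


def test_metrics_invariant_under_relabeling(rng):
    a = rng.integers(0, 3, size=30)
    b = rng.integers(0, 4, size=30)
    relab = np.array([2, 0, 1])[a]
    W, _ = block_affinity((15, 15), noise=0.1, rng=rng)
    assert nmi(a, b) == pytest.approx(nmi(relab, b), abs=1e-12)
    assert zrand(a, b) == pytest.approx(zrand(relab, b), abs=1e-12)
    assert modularity(W, a) == pytest.approx(modularity(W, relab), abs=1e-12)
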