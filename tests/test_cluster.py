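import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, davies_bouldin_score

from decoyreduce import (
    KneeCurve,
    USRScoreMatrix,
    davies_bouldin,
    find_knee,
    gmm_cluster,
    gmx_cluster_usr,
    hierarchical_cluster,
    kmeans_cluster,
    scatter_loss,
    sse,
)

from conftest import simplex_blobs


def brute_scatter_loss(X, labels):
    """Triple-loop transliteration of the within-cluster scatter."""
    total = 0.0
    for lab in set(labels):
        idx = [i for i, l in enumerate(labels) if l == lab]
        for i in idx:
            for j in idx:
                if i != j:
                    total += np.linalg.norm(X[i] - X[j])
    return total / 2.0


def brute_greedy_cutoff(S, cutoff):
    """Independent greedy neighbor-count clustering oracle."""
    n = len(S)
    remaining = set(range(n))
    labels = [None] * n
    cluster = 0
    while remaining:
        counts = {
            i: sum(1 for j in remaining if j != i and S[i][j] <= cutoff)
            for i in remaining
        }
        best = min(remaining, key=lambda i: (-counts[i], i))
        members = {best} | {j for j in remaining if j != best and S[best][j] <= cutoff}
        for m in members:
            labels[m] = cluster
        remaining -= members
        cluster += 1
    return labels


def random_score_matrix(rng, n):
    raw = rng.random((n, n))
    S = (raw + raw.T) / 2
    np.fill_diagonal(S, 0)
    if S.max() > 0:
        S = S / S.max()
    return S


class TestScatterLoss:
    def test_two_point_cluster(self):
        X = np.array([[0.0], [1.0]])
        assert scatter_loss(X, [0, 0]) == pytest.approx(1.0)

    def test_singletons_are_free(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        assert scatter_loss(X, np.arange(6)) == 0.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 12))
        labels = rng.integers(0, 2, size=10)
        assert scatter_loss(X, labels) == pytest.approx(brute_scatter_loss(X, labels))


class TestSSE:
    def test_zero_when_points_sit_on_centroids(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0]])
        assert sse(X, [0, 1], X.copy()) == 0.0

    def test_one_dimensional_example(self):
        X = np.array([[0.0], [2.0]])
        assert sse(X, [0, 0], np.array([[1.0]])) == pytest.approx(2.0)


class TestFindKnee:
    def test_hand_evaluated_chord_rule(self):
        # chord from (1,1000) to (6,105); perpendicular distance is maximal
        # at k=3 (hand check: vertical gaps 421, 492, 343, 174)
        curve = KneeCurve(np.arange(1, 7), [1000, 400, 150, 120, 110, 105])
        assert find_knee(curve) == 3

    def test_straight_curve_falls_back_to_smallest_interior_k(self, caplog):
        curve = KneeCurve(np.arange(1, 6), [100, 80, 60, 40, 20])
        assert find_knee(curve) == 2
        assert any("straight" in r.message for r in caplog.records)

    @pytest.mark.parametrize("bend_at", [3, 5, 7])
    def test_recovers_planted_bend(self, bend_at):
        ks = np.arange(1, 10)
        crit = np.where(ks <= bend_at, 1000.0 - 150.0 * (ks - 1), 0.0)
        crit = crit + np.maximum(0, bend_at - ks) * 0  # piecewise linear
        crit[ks > bend_at] = crit[ks == bend_at] - 1.0 * (ks[ks > bend_at] - bend_at)
        assert find_knee(KneeCurve(ks, crit)) == bend_at

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            find_knee(KneeCurve([1, 2], [2.0, 1.0]))


class TestKMeans:
    def test_recovers_two_planted_blobs(self):
        X, truth = simplex_blobs(G=2, n=120, seed=0)
        result = kmeans_cluster(X, (2, 8), seed=0)
        assert result.k == 2
        assert adjusted_rand_score(truth, result.labels) == 1.0

    def test_winning_restart_minimizes_scatter_loss(self):
        X, _ = simplex_blobs(G=3, n=90, seed=1, sep_factor=3.0)
        result = kmeans_cluster(X, (3, 3), restarts=10, seed=1)
        winner_loss = scatter_loss(X, result.labels)
        # rerun the same restart schedule independently: no restart beats it
        rng = np.random.default_rng(1)
        from sklearn.cluster import KMeans

        for _ in range(10):
            init = X[rng.choice(len(X), size=3, replace=False)]
            labels = KMeans(n_clusters=3, init=init, n_init=1).fit_predict(X)
            assert winner_loss <= scatter_loss(X, labels) + 1e-9

    def test_duplicate_points_do_not_crash(self):
        X = np.zeros((10, 12))
        X[5:] = 1.0
        result = kmeans_cluster(X, (2, 4), seed=0)
        assert result.cluster_sizes.min() >= 1
        assert len(result.labels) == 10

    def test_deterministic_under_seed(self):
        X, _ = simplex_blobs(G=3, n=90, seed=2)
        a = kmeans_cluster(X, (2, 6), seed=5)
        b = kmeans_cluster(X, (2, 6), seed=5)
        assert a.k == b.k
        assert np.array_equal(a.labels, b.labels)

    def test_sse_curve_non_increasing_on_blobs(self):
        X, _ = simplex_blobs(G=3, n=150, seed=3)
        result = kmeans_cluster(X, (2, 8), seed=3)
        assert (np.diff(result.diagnostics.criterion) <= 1e-6).all()


class TestGMM:
    def test_literal_bic_matches_printed_formula(self):
        # direct evaluation: ln(100)*3 - 2*(-50) = 113.8155...
        n, k, loglik = 100, 3, -50.0
        assert np.log(n) * k - 2 * loglik == pytest.approx(113.8155, abs=1e-4)
        # the literal penalty counts components, the standard one counts
        # free mixture parameters (full covariance in 12-d: 91k - 1);
        # their curves must differ by exactly ln(n) * (90k - 1)
        X, _ = simplex_blobs(G=2, n=100, seed=0)
        lit = gmm_cluster(X, (2, 4), seed=0, bic_mode="literal").diagnostics
        std = gmm_cluster(X, (2, 4), seed=0, bic_mode="standard").diagnostics
        for k, lo, hi in zip(lit.k_values, lit.criterion, std.criterion):
            assert hi - lo == pytest.approx(np.log(100) * (90 * k - 1), rel=1e-9)

    def test_recovers_two_planted_gaussians_across_seeds(self):
        hits = 0
        for seed in range(10):
            X, truth = simplex_blobs(G=2, n=500, seed=seed)
            res = gmm_cluster(X, (2, 6), seed=seed)
            hits += res.k == 2 and adjusted_rand_score(truth, res.labels) > 0.99
        assert hits >= 9

    def test_single_blob_still_returns_contract(self):
        X = np.random.default_rng(0).normal(size=(60, 12))
        res = gmm_cluster(X, (2, 5), seed=0)
        uniq = np.unique(res.labels)
        assert np.array_equal(uniq, np.arange(len(uniq)))
        assert len(res.diagnostics.k_values) == 4

    def test_deterministic_under_seed(self):
        X, _ = simplex_blobs(G=3, n=120, seed=4)
        a = gmm_cluster(X, (2, 5), seed=7)
        b = gmm_cluster(X, (2, 5), seed=7)
        assert np.array_equal(a.labels, b.labels)


class TestDaviesBouldin:
    def test_singleton_clusters_score_zero(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        assert davies_bouldin(X, [0, 1]) == 0.0

    def test_hand_evaluated_two_cluster_case(self):
        X = np.array([[0.0], [0.2], [1.0], [1.2]])
        assert davies_bouldin(X, [0, 0, 1, 1]) == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 4))
        labels = rng.integers(0, 3, size=20)
        if len(np.unique(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        assert davies_bouldin(X, labels) == pytest.approx(
            davies_bouldin_score(X, labels)
        )

    def test_identical_centroids_rejected(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [-5.0, -5.0]])
        with pytest.raises(ValueError, match="identical centroids"):
            davies_bouldin(X, [0, 0, 1, 1])


class TestHierarchical:
    def test_two_planted_blobs_minimize_db_at_two(self):
        X, truth = simplex_blobs(G=2, n=100, seed=0)
        res = hierarchical_cluster(X, list(range(2, 8)))
        assert res.k == 2
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_chain_merges_nearest_pair_first(self):
        # single linkage on a chain with one short gap: cutting at k=2
        # must split at the widest gap, keeping the tight pair together
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        res = hierarchical_cluster(X, [2])
        assert res.k == 2
        assert len({res.labels[0], res.labels[1], res.labels[2]}) == 1
        assert res.labels[3] == res.labels[4] != res.labels[0]

    def test_empty_candidates_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            hierarchical_cluster(X, [])

    def test_deterministic_and_seed_free(self):
        X, _ = simplex_blobs(G=3, n=90, seed=5)
        a = hierarchical_cluster(X, list(range(2, 8)))
        b = hierarchical_cluster(X, list(range(2, 8)))
        assert np.array_equal(a.labels, b.labels)


def _matrix(ids, S):
    return USRScoreMatrix(ids=ids, scores=np.asarray(S, float), raw_max=1.0)


class TestGmxClusterUSR:
    def test_all_far_apart_gives_singletons(self):
        n = 4
        S = np.ones((n, n)) * 0.9
        np.fill_diagonal(S, 0)
        res = gmx_cluster_usr(_matrix([f"s{i}" for i in range(n)], S), cutoff=0.1)
        assert res.k == n

    def test_all_within_cutoff_gives_one_cluster(self):
        n = 5
        S = np.full((n, n), 0.05)
        np.fill_diagonal(S, 0)
        res = gmx_cluster_usr(_matrix([f"s{i}" for i in range(n)], S), cutoff=0.1)
        assert res.k == 1

    def test_planted_two_group_instance(self):
        # A neighbors {B, C}; D neighbors {E}; nothing crosses groups
        far, near = 0.9, 0.05
        S = np.full((5, 5), far)
        for i, j in [(0, 1), (0, 2), (3, 4)]:
            S[i, j] = S[j, i] = near
        np.fill_diagonal(S, 0)
        res = gmx_cluster_usr(_matrix(list("ABCDE"), S), cutoff=0.1)
        assert res.k == 2
        assert res.labels[0] == res.labels[1] == res.labels[2] == 0
        assert res.labels[3] == res.labels[4] == 1

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(2, 31))
            S = random_score_matrix(rng, n)
            cutoff = float(rng.uniform(0.05, 0.8))
            res = gmx_cluster_usr(_matrix([f"s{i}" for i in range(n)], S), cutoff)
            oracle = brute_greedy_cutoff(S.tolist(), cutoff)
            assert list(res.labels) == oracle

    def test_invalid_cutoff(self):
        S = np.zeros((3, 3))
        with pytest.raises(ValueError):
            gmx_cluster_usr(_matrix(["a", "b", "c"], S), cutoff=0.0)


class TestPartitionInvariant:
    def test_all_methods_partition_the_data(self):
        X, _ = simplex_blobs(G=3, n=60, seed=6)
        results = [
            kmeans_cluster(X, (2, 6), seed=0),
            gmm_cluster(X, (2, 6), seed=0),
            hierarchical_cluster(X, list(range(2, 7))),
        ]
        from scipy.spatial.distance import pdist, squareform

        raw = squareform(pdist(X))
        S = raw / raw.max()
        results.append(
            gmx_cluster_usr(_matrix([f"s{i}" for i in range(60)], S), cutoff=0.1)
        )
        for res in results:
            assert len(res.labels) == 60
            assert res.cluster_sizes.min() >= 1
            assert res.cluster_sizes.sum() == 60
            assert res.k == len(np.unique(res.labels))
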