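from math import log

import numpy as np
import pytest

from cdsknn import (
    EmbeddingMatrix,
    KnnGraph,
    MixtureSpec,
    RunConfig,
    build_knn_graph,
    coefficient_of_variation,
    divide_regions,
    log_omega,
    log_omega_exact,
    louvain_cluster,
    mutual_information,
    nrmi,
    rmi,
    sample_representatives,
    simulate_mixture,
    stability_scan,
    update_centroids,
)
from conftest import random_partition


def embed(values):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = np.column_stack([values, np.zeros_like(values)])
    return EmbeddingMatrix(
        values=values, cell_ids=[f"c{i}" for i in range(len(values))]
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

class TestSampleRepresentatives:
    def setup_method(self):
        M, _ = simulate_mixture(MixtureSpec(n_cells=100, k=2, dims=2, separation=20, seed=0))
        self.M = M
        part = divide_regions(M, g=10, seed=0)
        self.part = update_centroids(M, part, alpha=0.01)

    def test_deterministic_given_seed_and_replicate(self):
        a = sample_representatives(self.M, self.part, replicate_id=3, seed=9)
        b = sample_representatives(self.M, self.part, replicate_id=3, seed=9)
        np.testing.assert_array_equal(a.source_index, b.source_index)

    def test_replicates_differ(self):
        draws = {
            tuple(sample_representatives(self.M, self.part, l, seed=9).source_index)
            for l in range(20)
        }
        assert len(draws) > 1

    def test_each_sample_is_an_eligible_member_of_its_region(self):
        s = sample_representatives(self.M, self.part, replicate_id=1, seed=4)
        for r, idx in enumerate(s.source_index):
            assert self.part.region_of[idx] == r
            assert not self.part.outlier_flag[idx]

    def test_uniform_over_eligible_cells(self):
        # a 2-cell region: each member drawn in ~50% of replicates
        M = embed([[0.0, 0.0], [0.1, 0.0], [50.0, 0.0], [50.1, 0.0]])
        part = divide_regions(M, g=2, seed=0)
        part = update_centroids(M, part, alpha=0.01)
        r0_cells = np.flatnonzero(part.region_of == 0)
        picks = np.array([
            sample_representatives(M, part, l, seed=11).source_index[0]
            for l in range(10000)
        ])
        frac = (picks == r0_cells[0]).mean()
        assert 0.48 <= frac <= 0.52


# ---------------------------------------------------------------------------
# KNN graph
# ---------------------------------------------------------------------------

def brute_force_knn_edges(values, k):
    n = len(values)
    edges = set()
    for i in range(n):
        dists = sorted(
            (float(np.linalg.norm(values[i] - values[j])), j)
            for j in range(n) if j != i
        )
        for _, j in dists[:k]:
            edges.add((min(i, j), max(i, j)))
    return sorted(edges)


class TestBuildKnnGraph:
    def test_hand_example_three_points(self):
        graph = build_knn_graph(np.array([[0.0], [1.0], [3.0]]), k=1)
        assert [tuple(e) for e in graph.edges] == [(0, 1), (1, 2)]

    def test_matches_brute_force_with_ties(self, rng):
        for trial in range(200):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(1, min(n - 1, 10) + 1))
            # integer lattice coordinates force plenty of distance ties
            values = rng.integers(0, 4, size=(n, 2)).astype(float)
            graph = build_knn_graph(values, k)
            assert [tuple(e) for e in graph.edges] == brute_force_knn_edges(values, k)

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError, match="smaller"):
            build_knn_graph(np.zeros((4, 2)), k=4)

    def test_unweighted(self, rng):
        graph = build_knn_graph(rng.normal(size=(20, 2)), k=3)
        assert np.all(graph.weights == 1.0)


# ---------------------------------------------------------------------------
# louvain
# ---------------------------------------------------------------------------

class TestLouvain:
    @staticmethod
    def two_cliques():
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i + 5, j + 5) for i, j in edges]
        return KnnGraph(
            n_vertices=10, k=4,
            edges=np.array(edges), weights=np.ones(len(edges)),
        )

    def test_disconnected_cliques_are_separate_communities(self):
        part = louvain_cluster(self.two_cliques(), resolution=1.0, seed=0)
        assert part.n_communities == 2
        assert len(set(part.labels[:5])) == 1 and len(set(part.labels[5:])) == 1

    def test_two_blobs_with_a_bridge(self, rng):
        # two dense 10-cliques joined by one bridge edge
        edges = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        edges += [(i + 10, j + 10) for i, j in edges]
        edges.append((0, 10))
        graph = KnnGraph(22 - 2, 9, np.array(edges), np.ones(len(edges)))
        part = louvain_cluster(graph, resolution=1.0, seed=1)
        assert part.n_communities == 2
        # exhaustive check: this 2-partition maximizes modularity over all
        # assignments splitting the vertices into the two blobs or not
        import igraph as ig
        g = ig.Graph(n=20, edges=[tuple(e) for e in edges])
        best = g.modularity(list(part.labels))
        blob_split = [0] * 10 + [1] * 10
        assert best == pytest.approx(g.modularity(blob_split))

    def test_beats_singleton_partition_modularity(self, rng):
        values = rng.normal(size=(40, 2))
        graph = build_knn_graph(values, k=4)
        part = louvain_cluster(graph, resolution=1.0, seed=2)
        import igraph as ig
        g = graph.to_igraph()
        assert g.modularity(list(part.labels)) >= g.modularity(list(range(40)))

    def test_deterministic_given_seed(self, rng):
        graph = build_knn_graph(rng.normal(size=(60, 3)), k=5)
        a = louvain_cluster(graph, resolution=1.0, seed=5)
        b = louvain_cluster(graph, resolution=1.0, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)


# ---------------------------------------------------------------------------
# mutual information, Omega, RMI, NRMI
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_identical_two_group_partition_gives_ln2(self):
        u = np.array([0, 0, 1, 1])
        assert mutual_information(u, u) == pytest.approx(log(2))

    def test_constant_partition_gives_zero(self):
        u = np.array([0, 1, 0, 1])
        v = np.zeros(4, dtype=int)
        assert mutual_information(u, v) == pytest.approx(0.0)

    def test_contingency_table_hand_computation(self):
        # table [[2,1],[1,2]], n=6: direct term-by-term summation
        u = np.array([0, 0, 0, 1, 1, 1])
        v = np.array([0, 0, 1, 0, 1, 1])
        expected = sum(
            nrs / 6 * log(6 * nrs / (3 * 3)) for nrs in [2, 1, 1, 2]
        )
        assert mutual_information(u, v) == pytest.approx(expected)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            mutual_information(np.array([0, 1]), np.array([0, 1, 0]))


def enumerate_omega(a, b):
    """Brute-force count of nonnegative integer matrices with margins (a, b)
    by recursion over rows (independent oracle for the DP)."""
    if sum(a) != sum(b):
        return 0
    if len(a) == 1:
        return 1  # the single remaining row is forced to equal b

    def comps(total_, bounds):
        if not bounds:
            if total_ == 0:
                yield ()
            return
        for x in range(min(total_, bounds[0]) + 1):
            for rest in comps(total_ - x, bounds[1:]):
                yield (x,) + rest

    return sum(
        enumerate_omega(a[1:], tuple(bi - xi for bi, xi in zip(b, row)))
        for row in comps(a[0], tuple(b))
    )


class TestLogOmega:
    @pytest.mark.parametrize(
        "a,b,count",
        [
            ([2], [2], 1),          # single row: matrix forced
            ([1, 1], [1, 1], 2),    # the two permutation matrices
            ([2, 2], [2, 2], 3),    # free entry x in {0,1,2}
        ],
    )
    def test_exact_small_counts(self, a, b, count):
        assert log_omega_exact(a, b) == pytest.approx(log(count))
        assert log_omega(a, b) == pytest.approx(log(count))

    def test_exact_dp_matches_brute_force_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            a = tuple(np.bincount(rng.integers(0, 3, n)))
            b = tuple(np.bincount(rng.integers(0, 3, n)))
            a = tuple(x for x in a if x)
            b = tuple(x for x in b if x)
            assert log_omega_exact(a, b) == pytest.approx(
                log(enumerate_omega(a, b))
            )

    def test_single_row_margin_is_zero_for_any_n(self):
        for n in [1, 5, 20, 1000]:
            assert log_omega((n,), (n,)) == 0.0
        assert log_omega((30,), (10, 10, 10)) == 0.0

    def test_swap_symmetry(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 60))
            a = tuple(np.bincount(rng.integers(0, 4, n)) + 0)
            b = tuple(np.bincount(rng.integers(0, 4, n)) + 0)
            a = tuple(x for x in a if x)
            b = tuple(x for x in b if x)
            assert log_omega(a, b) == pytest.approx(log_omega(b, a), abs=1e-12)

    def test_margin_sum_mismatch_errors(self):
        with pytest.raises(ValueError, match="margin"):
            log_omega((2, 2), (3,))

    def test_analytic_estimate_tracks_exact_dp_at_moderate_n(self, rng):
        # bypass the exact-DP crossover: totals 15..30 use the estimate
        from cdsknn.graph_stability import _log_omega_conditional
        for _ in range(40):
            n = int(rng.integers(15, 31))
            a = tuple(np.bincount(rng.integers(0, 4, n)))
            b = tuple(np.bincount(rng.integers(0, 4, n)))
            a = tuple(x for x in a if x)
            b = tuple(x for x in b if x)
            if len(a) < 2 or len(b) < 2:
                continue
            exact = log_omega_exact(a, b)
            est = 0.5 * (_log_omega_conditional(a, b) + _log_omega_conditional(b, a))
            assert est == pytest.approx(exact, rel=0.10)


class TestRmiNrmi:
    def test_identical_two_group_partition(self):
        # RMI = ln 2 - (1/4) ln Omega([2,2],[2,2]) = ln 2 - ln(3)/4
        u = np.array([0, 0, 1, 1])
        assert rmi(u, u) == pytest.approx(log(2) - log(3) / 4, abs=1e-12)

    def test_singletons_vs_two_groups(self):
        # Omega([1,1,1,1],[2,2]) = 4!/(2!2!) = 6 (multinomial count)
        u = np.arange(4)
        v = np.array([0, 0, 1, 1])
        assert rmi(u, v) == pytest.approx(log(2) - log(6) / 4, abs=1e-12)

    def test_degenerate_partition_rmi_zero(self):
        u = np.zeros(6, dtype=int)
        v = np.array([0, 0, 1, 1, 2, 2])
        assert rmi(u, v) == pytest.approx(0.0)

    def test_nrmi_self_is_one(self, rng):
        for _ in range(100):
            u = random_partition(rng, 30, 5)
            assert nrmi(u, u) == pytest.approx(1.0, abs=1e-12)

    def test_nrmi_symmetric(self, rng):
        for _ in range(100):
            u = random_partition(rng, 30, 4)
            v = random_partition(rng, 30, 6)
            assert nrmi(u, v) == pytest.approx(nrmi(v, u), abs=1e-12)

    def test_nrmi_mixed_partition_from_enumeration(self):
        # all three RMI terms via exact Omega counts (n = 4)
        u = np.array([0, 0, 1, 1])
        v = np.arange(4)
        r_uv = log(2) - log(6) / 4
        r_uu = log(2) - log(3) / 4
        # I(v;v) = ln 4; Omega([1,1,1,1],[1,1,1,1]) = 4! = 24
        r_vv = log(4) - log(24) / 4
        assert nrmi(u, v) == pytest.approx(r_uv / (0.5 * (r_uu + r_vv)), abs=1e-12)

    def test_both_degenerate_is_zero(self):
        u = np.zeros(5, dtype=int)
        assert nrmi(u, u) == 0.0


class TestCoefficientOfVariation:
    def test_constant_offdiagonal_is_zero(self):
        s = np.full((4, 4), 0.7)
        np.fill_diagonal(s, 1.0)
        assert coefficient_of_variation(s) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        # off-diagonal {1, 2, 3}: mean 2, sample sd 1, CV 0.5
        s = np.array([[1.0, 1.0, 2.0], [1.0, 1.0, 3.0], [2.0, 3.0, 1.0]])
        assert coefficient_of_variation(s) == pytest.approx(0.5)

    def test_scale_invariant(self, rng):
        s = rng.uniform(0.5, 1.0, size=(5, 5))
        s = (s + s.T) / 2
        assert coefficient_of_variation(3.7 * s) == pytest.approx(
            coefficient_of_variation(s)
        )

    def test_zero_mean_gives_infinity(self):
        assert coefficient_of_variation(np.eye(3)) == float("inf")


# ---------------------------------------------------------------------------
# the stability scan
# ---------------------------------------------------------------------------

class TestStabilityScan:
    def test_two_blob_scan_properties(self, two_blob_embedding):
        M, labels = two_blob_embedding
        config = RunConfig(g=50, k_min=3, k_max=6, L=4, seed=0)
        part = divide_regions(M, g=50, seed=0)
        part = update_centroids(M, part, alpha=0.01)
        stab = stability_scan(M, part, config)
        assert stab.k_grid == [3, 4, 5, 6]
        assert stab.k_star in stab.k_grid
        for k in stab.k_grid:
            s = stab.similarity[k]
            np.testing.assert_allclose(np.diag(s), 1.0)
            np.testing.assert_allclose(s, s.T)
        assert stab.cv[stab.k_star] == min(stab.cv.values())

    def test_tie_break_to_smaller_k(self):
        # selection rule on a constructed cv map
        cvs = {3: 0.10, 5: 0.05, 7: 0.05}
        k_star = min(cvs, key=lambda k: (cvs[k], k))
        assert k_star == 5
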