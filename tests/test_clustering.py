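import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import net_from, random_graph
from oracles import set_partitions
from pcnkit.clustering import (
    Partition,
    community_detect,
    embed,
    embedded_clustering,
    generate_planted_partition,
    laplacian_spectrum,
    modularity,
    spectral_clustering,
)
from pcnkit.errors import ParameterError


class TestLaplacianSpectrum:
    def test_path3_unnormalized_closed_form(self):
        net = net_from([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert np.allclose(laplacian_spectrum(net, "unnormalized"), [0, 1, 3])

    def test_k2_unnormalized(self):
        net = net_from([[0, 1], [1, 0]])
        assert np.allclose(laplacian_spectrum(net, "unnormalized"), [0, 2])

    @pytest.mark.parametrize("variant", ["unnormalized", "sym", "rw"])
    def test_zero_multiplicity_counts_components(self, variant, two_triangles_net):
        vals = laplacian_spectrum(two_triangles_net, variant)
        assert np.sum(np.abs(vals) < 1e-9) == 2

    def test_isolated_node_contributes_zero_eigenvalue(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[1, 0] = 1
        vals = laplacian_spectrum(net_from(A), "sym")
        assert np.sum(np.abs(vals) < 1e-9) == 2  # K2 component + isolated node


class TestSpectralClustering:
    @pytest.mark.parametrize("variant", ["unnormalized", "sym", "rw"])
    def test_disconnected_components_recovered_exactly(self, variant,
                                                       two_triangles_net):
        part = spectral_clustering(two_triangles_net, 2, variant=variant, seed=0)
        assert part.labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_k_equals_n_gives_singletons(self, k3_net):
        part = spectral_clustering(k3_net, 3, seed=0)
        assert sorted(part.labels.tolist()) == [0, 1, 2]

    def test_k_out_of_range(self, k3_net):
        with pytest.raises(ParameterError):
            spectral_clustering(k3_net, 4)

    def test_planted_partition_recovery(self):
        net, truth = generate_planted_partition(4, 15, 0.9, 0.05, seed=1)
        part = spectral_clustering(net, 4, variant="sym", seed=0)
        assert adjusted_rand_score(truth, part.labels) >= 0.95

    def test_seeded_determinism(self, helix30_net):
        a = spectral_clustering(helix30_net, 3, seed=5)
        b = spectral_clustering(helix30_net, 3, seed=5)
        assert a.labels.tolist() == b.labels.tolist()


class TestEmbedding:
    def test_hope_katz_matrix_oracle_k2(self):
        # hand-inverted 2x2 Katz matrix for K2, beta = 0.1
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        beta = 0.1
        S = np.linalg.solve(np.eye(2) - beta * A, beta * A)
        assert np.allclose(S, [[0.0101, 0.1010], [0.1010, 0.0101]], atol=1e-3)
        emb = embed(net_from(A.astype(int)), "hope_katz", d=2, beta=beta)
        # singular values of S are |beta*lam/(1-beta*lam)| for lam = +-1
        sv = np.linalg.norm(emb.vectors, axis=0) ** 2
        assert np.allclose(sorted(sv, reverse=True), [1 / 9, 1 / 11], atol=1e-9)

    def test_laplacian_eigenmap_fiedler_separates_components(self,
                                                             two_triangles_net):
        emb = embed(two_triangles_net, "laplacian_eigenmap", d=1)
        v = emb.vectors[:, 0]
        assert np.allclose(v[:3], v[0], atol=1e-8)
        assert np.allclose(v[3:], v[3], atol=1e-8)
        assert np.sign(v[0]) == -np.sign(v[3])

    def test_full_rank_hope_on_k3(self, k3_net):
        emb = embed(k3_net, "hope_katz", d=3)
        assert emb.vectors.shape == (3, 3)
        assert np.isfinite(emb.vectors).all()

    def test_katz_divergence_rejected(self):
        net = net_from([[0, 1], [1, 0]])  # spectral radius 1
        with pytest.raises(ParameterError, match="diverges"):
            embed(net, "hope_katz", d=1, beta=1.0)


class TestEmbeddedClustering:
    def test_components_recovered_in_one_dimension(self, two_triangles_net):
        part = embedded_clustering(two_triangles_net, "laplacian_eigenmap",
                                   d=1, k=2, seed=0)
        assert part.labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_hope_recovers_planted_partition(self):
        net, truth = generate_planted_partition(4, 15, 0.9, 0.05, seed=1)
        part = embedded_clustering(net, "hope_katz", d=8, k=4, seed=0)
        assert adjusted_rand_score(truth, part.labels) >= 0.9

    def test_same_seed_identical_labels(self, helix30_net):
        a = embedded_clustering(helix30_net, "hope_katz", d=4, k=3, seed=2)
        b = embedded_clustering(helix30_net, "hope_katz", d=4, k=3, seed=2)
        assert a.labels.tolist() == b.labels.tolist()


class TestCommunities:
    def test_girvan_newman_cuts_the_bridge(self, barbell_net):
        part = community_detect(barbell_net, "girvan_newman", k=2)
        assert part.labels.tolist() == [0, 0, 0, 1, 1, 1]
        # the bridge is the unique maximum: 3x3 cross pairs all route over it
        G = nx.from_numpy_array(barbell_net.A)
        eb = nx.edge_betweenness_centrality(G, normalized=False)
        assert eb[(2, 3)] == pytest.approx(9.0)
        assert all(v < 9.0 for e, v in eb.items() if e != (2, 3))

    def test_label_propagation_on_disconnected_graph(self, two_triangles_net):
        part = community_detect(two_triangles_net, "label_propagation", seed=0)
        assert part.labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_greedy_modularity_maximizes_q_on_barbell(self, barbell_net):
        part = community_detect(barbell_net, "greedy_modularity")
        assert part.labels.tolist() == [0, 0, 0, 1, 1, 1]
        # exhaustive check over all 203 partitions of 6 nodes
        best = max(
            modularity(barbell_net, _as_partition(p))
            for p in set_partitions(range(6))
        )
        assert modularity(barbell_net, part) == pytest.approx(best)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ParameterError):
            community_detect(net_from(np.zeros((3, 3), dtype=int)), "louvain")

    @pytest.mark.parametrize("method", ["louvain", "greedy_modularity",
                                        "label_propagation", "girvan_newman"])
    def test_seeded_determinism(self, method, helix30_net):
        a = community_detect(helix30_net, method, seed=9, k=3)
        b = community_detect(helix30_net, method, seed=9, k=3)
        assert a.labels.tolist() == b.labels.tolist()


def _as_partition(groups):
    labels = np.empty(sum(len(g) for g in groups), dtype=int)
    for cid, members in enumerate(groups):
        for node in members:
            labels[node] = cid
    from pcnkit.clustering import canonical_labels

    labels = canonical_labels(labels)
    return Partition(labels=labels, k=int(labels.max()) + 1, method="enum")


class TestModularity:
    def test_barbell_triangle_partition(self, barbell_net):
        part = _as_partition([[0, 1, 2], [3, 4, 5]])
        assert modularity(barbell_net, part) == pytest.approx(5 / 14)

    def test_single_cluster_is_zero(self, barbell_net):
        part = _as_partition([[0, 1, 2, 3, 4, 5]])
        assert modularity(barbell_net, part) == pytest.approx(0.0)

    def test_k3_singletons(self, k3_net):
        part = _as_partition([[0], [1], [2]])
        assert modularity(k3_net, part) == pytest.approx(-1 / 3)

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            A = random_graph(rng, 10, 0.4)
            if A.sum() == 0:
                continue
            net = net_from(A)
            part = community_detect(net, "louvain", seed=int(rng.integers(100)))
            comms = [set(np.nonzero(part.labels == s)[0]) for s in range(part.k)]
            expected = nx.community.modularity(nx.from_numpy_array(A), comms)
            assert modularity(net, part) == pytest.approx(expected, abs=1e-12)


class TestPlantedPartition:
    def test_degenerate_probabilities_give_disjoint_cliques(self):
        net, truth = generate_planted_partition(2, 3, 1.0, 0.0, seed=0)
        expected = np.zeros((6, 6), dtype=int)
        expected[:3, :3] = 1 - np.eye(3)
        expected[3:, 3:] = 1 - np.eye(3)
        assert np.array_equal(net.A, expected)
        assert truth.tolist() == [0, 0, 0, 1, 1, 1]

    def test_fixed_seed_reproducible(self):
        a, _ = generate_planted_partition(3, 5, 0.8, 0.1, seed=42)
        b, _ = generate_planted_partition(3, 5, 0.8, 0.1, seed=42)
        assert np.array_equal(a.A, b.A)

    def test_within_block_edge_count_matches_binomial_mean(self):
        blocks, size, p_in = 2, 6, 0.6
        trials = 100
        per_block_pairs = size * (size - 1) // 2
        n_pairs = blocks * per_block_pairs * trials
        count = 0
        for seed in range(trials):
            net, truth = generate_planted_partition(blocks, size, p_in, 0.1,
                                                    seed=seed)
            same = truth[:, None] == truth[None, :]
            count += int(net.A[np.triu(same, k=1)].sum())
        mean = n_pairs * p_in
        sigma = np.sqrt(n_pairs * p_in * (1 - p_in))
        assert abs(count - mean) <= 3 * sigma

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            generate_planted_partition(2, 3, 0.2, 0.5, seed=0)
        with pytest.raises(ParameterError):
            generate_planted_partition(2, 3, 1.2, 0.1, seed=0)


class TestPartitionInvariants:
    def test_zero_eigenvalue_multiplicity_equals_components(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            A = random_graph(rng, int(rng.integers(3, 12)),
                             float(rng.uniform(0.1, 0.6)))
            net = net_from(A)
            vals = laplacian_spectrum(net, "unnormalized")
            ncomp = nx.number_connected_components(nx.from_numpy_array(A))
            assert np.sum(vals < 1e-8) == ncomp

    def test_community_q_beats_trivial_partition(self, barbell_net, helix30_net):
        for net in (barbell_net, helix30_net):
            trivial = _as_partition([list(range(net.n_nodes))])
            for method in ("louvain", "greedy_modularity"):
                part = community_detect(net, method, seed=0)
                assert modularity(net, part) >= modularity(net, trivial)
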