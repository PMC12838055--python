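"""Network estimation, centralities, communities and stability machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats

from semlink.network import (
    CommunityPartition,
    NetworkModel,
    case_drop_cs,
    centralities,
    ebic_glasso,
    edge_bootstrap,
    estimate_network,
    global_metrics,
    louvain,
    nearest_pd,
    spearman_matrix,
    structure_recovery_frequency,
)
from semlink.synthetic import exact_corr_data, sample_from_precision


def net_from_W(W, n=100):
    p = len(W)
    return NetworkModel([f"n{i}" for i in range(p)], np.asarray(W, float),
                        0.1, 0.5, np.eye(p), n)


def chain_precision(p=10, partial=0.3):
    Theta = np.eye(p)
    for i in range(p - 1):
        Theta[i, i + 1] = Theta[i + 1, i] = -partial
    return Theta


class TestSpearman:
    def test_monotone_invariance(self, rng):
        x = rng.standard_normal(50)
        R = spearman_matrix(np.column_stack([x, np.exp(x)]))
        assert R[0, 1] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self, rng):
        x = rng.standard_normal(30)
        R = spearman_matrix(np.column_stack([x, -x]))
        assert R[0, 1] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        X = rng.integers(0, 3, size=(5, 4)).astype(float)
        X[:, 0] += np.arange(5) * 1e-9  # keep one column varied
        R = spearman_matrix(X)
        ranked = np.column_stack([stats.rankdata(X[:, j]) for j in range(4)])
        expected = np.corrcoef(ranked, rowvar=False)
        np.testing.assert_allclose(R, expected, atol=1e-12)

    def test_zero_variance_column_flagged_missing(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 2.0
        R = spearman_matrix(X)
        assert np.isnan(R[0, 1]) and np.isnan(R[1, 2])
        assert R[1, 1] == 1.0


class TestNearestPD:
    def test_identity_passthrough(self):
        np.testing.assert_array_equal(nearest_pd(np.eye(4)), np.eye(4))

    def test_pd_input_unchanged(self):
        R = np.array([[1, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(nearest_pd(R), R, atol=1e-12)

    def test_indefinite_repaired(self):
        R = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(R).min() < 0
        A = nearest_pd(R)
        assert np.linalg.eigvalsh(A).min() >= 1e-6 - 1e-12
        np.testing.assert_allclose(np.diag(A), 1.0, atol=1e-12)


class TestEbicGlasso:
    def test_identity_gives_empty_network(self):
        net = ebic_glasso(np.eye(5), n=100)
        assert np.count_nonzero(net.W) == 0

    def test_lambda_to_zero_matches_analytic_partials(self):
        R = np.array([[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1.0]])
        net = ebic_glasso(R, n=1000, n_lambda=30, lambda_min_ratio=1e-8,
                          select="min_lambda", tol=1e-10, max_iter=2000)
        Theta = np.linalg.inv(R)
        d = np.sqrt(np.diag(Theta))
        W = -Theta / np.outer(d, d)
        np.fill_diagonal(W, 0.0)
        np.testing.assert_allclose(net.W, W, atol=1e-6)

    def test_chain_support_recovery(self):
        Theta = chain_precision()
        X = sample_from_precision(Theta, 800, seed=1)
        net = estimate_network(X)
        iu = np.triu_indices(10, k=1)
        truth = Theta[iu] != 0
        est = net.W[iu] != 0
        sens = (truth & est).sum() / truth.sum()
        fpr = (est & ~truth).sum() / (~truth).sum()
        assert sens >= 0.9
        assert fpr <= 0.15  # single-draw check; the tighter bound is averaged

    def test_sparsity_monotone_along_path(self):
        R = nearest_pd(spearman_matrix(sample_from_precision(chain_precision(6), 300, seed=2)))
        from sklearn.covariance import graphical_lasso
        edges = []
        for lam in np.geomspace(0.6, 0.01, 12):
            _, Th = graphical_lasso(R, alpha=lam, max_iter=200)
            W = -Th / np.outer(np.sqrt(np.diag(Th)), np.sqrt(np.diag(Th)))
            np.fill_diagonal(W, 0.0)
            edges.append(int(np.count_nonzero(np.abs(W) > 1e-10) // 2))
        assert all(a <= b for a, b in zip(edges, edges[1:]))

    def test_gamma_zero_no_sparser_than_gamma_one(self):
        X = sample_from_precision(chain_precision(8, 0.25), 300, seed=3)
        R = nearest_pd(spearman_matrix(X))
        e0 = np.count_nonzero(ebic_glasso(R, n=300, gamma=0.0).W)
        e1 = np.count_nonzero(ebic_glasso(R, n=300, gamma=1.0).W)
        assert e0 >= e1


class TestCentralities:
    def test_three_node_line_hand_values(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        c = centralities(net_from_W(W))
        assert c["n1"]["strength"] == pytest.approx(1.0)
        assert c["n0"]["strength"] == pytest.approx(0.5)
        assert c["n1"]["betweenness"] == pytest.approx(1.0)
        assert c["n0"]["betweenness"] == pytest.approx(0.0)

    def test_complete_equal_graph_ties(self):
        p = 5
        W = np.full((p, p), 0.3)
        np.fill_diagonal(W, 0.0)
        c = centralities(net_from_W(W))
        for key in ("strength", "betweenness", "closeness"):
            vals = {round(c[v][key], 12) for v in c}
            assert len(vals) == 1

    def test_betweenness_matches_brute_force(self, rng):
        """Brute-force all-pairs shortest-path enumeration on 6 nodes."""
        p = 6
        W = np.zeros((p, p))
        for i, j in itertools.combinations(range(p), 2):
            if rng.uniform() < 0.6:
                W[i, j] = W[j, i] = rng.uniform(0.1, 0.9)
        net = net_from_W(W)
        c = centralities(net)

        # enumerate all simple paths per pair, find shortest by 1/|w| lengths
        def simple_paths(s, t):
            out = []
            stack = [(s, [s])]
            while stack:
                v, path = stack.pop()
                if v == t:
                    out.append(path)
                    continue
                for u in range(p):
                    if W[v, u] > 0 and u not in path:
                        stack.append((u, path + [u]))
            return out

        between = np.zeros(p)
        for s, t in itertools.combinations(range(p), 2):
            paths = simple_paths(s, t)
            if not paths:
                continue
            lengths = [sum(1.0 / W[a, b] for a, b in zip(q, q[1:])) for q in paths]
            dmin = min(lengths)
            shortest = [q for q, l in zip(paths, lengths) if abs(l - dmin) < 1e-12]
            for q in shortest:
                for v in q[1:-1]:
                    between[v] += 1.0 / len(shortest)
        norm = (p - 1) * (p - 2) / 2
        for i in range(p):
            assert c[f"n{i}"]["betweenness"] == pytest.approx(between[i] / norm, abs=1e-9)

    def test_empty_network_all_zero(self):
        c = centralities(net_from_W(np.zeros((4, 4))))
        assert all(v == {"strength": 0.0, "betweenness": 0.0, "closeness": 0.0}
                   for v in c.values())


class TestLouvain:
    def test_two_cliques_closed_form(self):
        p = 10
        W = np.zeros((p, p))
        for a, b in itertools.combinations(range(5), 2):
            W[a, b] = W[b, a] = 0.2
        for a, b in itertools.combinations(range(5, 10), 2):
            W[a, b] = W[b, a] = 0.2
        part = louvain(net_from_W(W), seed=1)
        assert part.n_communities == 2
        assert part.Q == pytest.approx(0.5, abs=1e-12)

    def test_complete_graph_single_community(self):
        W = np.full((6, 6), 0.4)
        np.fill_diagonal(W, 0.0)
        part = louvain(net_from_W(W), seed=2)
        assert part.n_communities == 1

    def test_empty_network_singletons(self):
        part = louvain(net_from_W(np.zeros((4, 4))), seed=3)
        assert part.n_communities == 4
        assert part.Q == 0.0

    def test_seed_determinism(self, rng):
        W = np.abs(rng.standard_normal((12, 12))) * (rng.uniform(size=(12, 12)) < 0.3)
        W = np.triu(W, 1)
        W = W + W.T
        p1 = louvain(net_from_W(W), seed=9)
        p2 = louvain(net_from_W(W), seed=9)
        assert p1.labels == p2.labels and p1.Q == p2.Q


class TestGlobalMetrics:
    def test_empty(self):
        m = global_metrics(net_from_W(np.zeros((5, 5))))
        assert m == {"global_strength": 0.0, "density": 0.0}

    def test_complete_four_node(self):
        W = np.full((4, 4), 0.2)
        np.fill_diagonal(W, 0.0)
        m = global_metrics(net_from_W(W))
        assert m["global_strength"] == pytest.approx(1.2)
        assert m["density"] == 1.0


class TestStability:
    def test_case_drop_deterministic(self):
        X = sample_from_precision(chain_precision(5, 0.4), 150, seed=4)
        cs1 = case_drop_cs(X, "strength", n_boot=30, seed=11, n_lambda=10)
        cs2 = case_drop_cs(X, "strength", n_boot=30, seed=11, n_lambda=10)
        assert cs1 == cs2

    def test_unknown_index_rejected(self, rng):
        with pytest.raises(ValueError):
            case_drop_cs(rng.standard_normal((50, 4)), "eigenvector", n_boot=10, seed=0)

    def test_noise_has_zero_strength_stability(self, rng):
        X = np.random.default_rng(3).standard_normal((100, 8))
        assert case_drop_cs(X, "strength", n_boot=100, seed=1, n_lambda=10) == 0.0

    def test_edge_bootstrap_empty_network_missing(self, rng):
        X = rng.standard_normal((120, 5))
        out = edge_bootstrap(X, n_boot=20, seed=2, n_lambda=10)
        assert out["edge_mean_retention"] is None

    def test_edge_bootstrap_deterministic_strong_signal(self):
        Theta = np.eye(4)
        Theta[0, 1] = Theta[1, 0] = -0.5
        S = np.linalg.inv(Theta)
        d = np.sqrt(np.diag(S))
        X = exact_corr_data(S / np.outer(d, d), 400, seed=5)
        o1 = edge_bootstrap(X, n_boot=30, seed=3, n_lambda=10)
        o2 = edge_bootstrap(X, n_boot=30, seed=3, n_lambda=10)
        assert o1["edge_mean_retention"] == o2["edge_mean_retention"] == 1.0
        assert o1["edge_median_weight_corr"] == o2["edge_median_weight_corr"]

    def test_recovery_frequency_strong_vs_noise(self):
        # strong two-block structure
        p = 6
        C = np.eye(p)
        C[:3, :3] = 0.7
        C[3:, 3:] = 0.7
        np.fill_diagonal(C, 1.0)
        X = exact_corr_data(C, 300, seed=6)
        net = estimate_network(X, n_lambda=15)
        ref = louvain(net, seed=1)
        freq = structure_recovery_frequency(X, ref, n_boot=25, seed=7, n_lambda=10)
        assert freq >= 0.9
        # determinism
        freq2 = structure_recovery_frequency(X, ref, n_boot=25, seed=7, n_lambda=10)
        assert freq == freq2
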