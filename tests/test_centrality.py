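"""Centrality panel vs closed forms and independent oracles."""

import math

import numpy as np
import pytest

from conftest import (
    complete_graph,
    cycle_graph,
    path_graph,
    random_graph,
    star_graph,
    to_networkx,
)

from coexnet import (
    Network,
    betweenness,
    centrality_report,
    closeness,
    degree_centrality,
    eigenvector_centrality,
    pagerank,
)
from coexnet.errors import ConfigError, UndefinedResultError


def brute_betweenness(net: Network) -> dict[str, float]:
    """Exhaustive shortest-path enumeration (only viable on tiny graphs)."""
    from coexnet import bfs_levels

    nodes = net.nodes()
    score = {node: 0.0 for node in nodes}
    for i, s in enumerate(nodes):
        dist = bfs_levels(net, s)
        for t in nodes[i + 1:]:
            if dist[t] == math.inf:
                continue
            paths: list[tuple[str, ...]] = []

            def extend(path):
                head = path[-1]
                if head == t:
                    paths.append(tuple(path))
                    return
                for nxt in net.neighbors(head):
                    if dist[nxt] == dist[head] + 1 and dist[nxt] <= dist[t]:
                        extend(path + [nxt])

            extend([s])
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    return score


class TestBetweenness:
    def test_path_middle_node(self):
        scores = betweenness(path_graph(3))
        assert scores["n01"] == pytest.approx(1.0)
        assert scores["n00"] == scores["n02"] == 0.0

    @pytest.mark.parametrize("n", [3, 4, 6])
    def test_star_center_closed_form(self, n):
        """The hub of a star carries every leaf pair: C(n, 2)."""
        scores = betweenness(star_graph(n))
        assert scores["center"] == pytest.approx(n * (n - 1) / 2)
        assert all(scores[f"leaf{i:02d}"] == 0.0 for i in range(n))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_path_enumeration_oracle(self, seed):
        net = random_graph(9, 0.3, seed=seed)
        expected = brute_betweenness(net)
        got = betweenness(net)
        for node in net.nodes():
            assert got[node] == pytest.approx(expected[node], abs=1e-9)

    def test_leaves_always_score_zero(self):
        net = random_graph(15, 0.15, seed=4)
        scores = betweenness(net)
        for node in net.nodes():
            if net.degree(node) == 1:
                assert scores[node] == 0.0


class TestEigenvector:
    def test_complete_graph_symmetry(self):
        scores = eigenvector_centrality(complete_graph(4))
        assert all(s == pytest.approx(1.0) for s in scores.values())

    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_star_leaves_closed_form(self, n):
        """For K_{1,n} the principal eigenvector is center 1, leaf 1/sqrt(n)."""
        scores = eigenvector_centrality(star_graph(n))
        assert scores["center"] == pytest.approx(1.0)
        for i in range(n):
            assert scores[f"leaf{i:02d}"] == pytest.approx(1 / math.sqrt(n), abs=1e-8)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dense_eigendecomposition(self, seed):
        net = random_graph(12, 0.4, seed=seed)
        nodes = net.nodes()
        index = {node: i for i, node in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for u, v, _ in net.edges():
            A[index[u], index[v]] = A[index[v], index[u]] = 1.0
        lam, vecs = np.linalg.eigh(A)
        principal = np.abs(vecs[:, -1])
        principal /= principal.max()
        got = eigenvector_centrality(net)
        vec = np.array([got[node] for node in nodes])
        # eigen-residual check is robust to degenerate spectra
        assert np.max(np.abs(A @ vec - lam[-1] * vec)) < 1e-6 * max(lam[-1], 1.0)
        if lam[-1] - lam[-2] > 1e-6:
            np.testing.assert_allclose(vec, principal, atol=1e-6)

    def test_edgeless_graph_rejected(self):
        net = Network()
        net.add_node("a")
        with pytest.raises(UndefinedResultError):
            eigenvector_centrality(net)


class TestCloseness:
    @pytest.mark.parametrize("n", [3, 5])
    def test_complete_graph_all_one(self, n):
        assert all(
            s == pytest.approx(1.0) for s in closeness(complete_graph(n)).values()
        )

    def test_three_path_closed_form(self):
        scores = closeness(path_graph(3))
        assert scores["n01"] == pytest.approx(1.0)
        assert scores["n00"] == pytest.approx(2.0 / 3.0)
        assert scores["n02"] == pytest.approx(2.0 / 3.0)

    def test_isolated_node_scores_zero(self):
        net = path_graph(3)
        net.add_node("lonely")
        assert closeness(net)["lonely"] == 0.0

    def test_two_component_graph_matches_direct_formula(self):
        from test_graph_core import fw_distances

        net = random_graph(12, 0.25, seed=2)
        net.add_edge("zz1", "zz2", 0.9)
        nodes, index, D = fw_distances(net)
        n = len(nodes)
        got = closeness(net)
        for node in nodes:
            row = D[index[node]]
            reach = np.isfinite(row) & (row > 0)
            expected = (
                reach.sum() ** 2 / ((n - 1) * row[reach].sum()) if reach.any() else 0.0
            )
            assert got[node] == pytest.approx(expected, abs=1e-12)

    def test_scores_within_unit_interval(self):
        scores = closeness(random_graph(20, 0.2, seed=3))
        assert all(0.0 <= s <= 1.0 for s in scores.values())


class TestPagerank:
    @pytest.mark.parametrize("n", [4, 5, 7])
    def test_cycle_is_uniform(self, n):
        """A k-regular graph's PageRank fixed point is exactly uniform."""
        scores = pagerank(cycle_graph(n))
        assert all(s == pytest.approx(1.0 / n, abs=1e-10) for s in scores.values())

    def test_three_path_matches_linear_solve(self):
        """Solve the 3x3 stationarity system exactly and compare."""
        d = 0.85
        # column-stochastic walk matrix M[u, v] = 1/deg(v) for the path a-b-c
        M = np.array([
            [0.0, 0.5, 0.0],
            [1.0, 0.0, 1.0],
            [0.0, 0.5, 0.0],
        ])
        A = np.eye(3) - d * M
        b = np.full(3, (1 - d) / 3)
        expected = np.linalg.solve(A, b)
        expected /= expected.sum()
        net = path_graph(3)
        got = pagerank(net, damping=d)
        for node, value in zip(["n00", "n01", "n02"], expected):
            assert got[node] == pytest.approx(value, abs=1e-10)

    def test_conservation_and_nonnegativity(self):
        for seed in range(5):
            net = random_graph(15, 0.15, seed=seed)
            net.add_node("dangling")
            scores = pagerank(net)
            assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(s >= 0 for s in scores.values())

    def test_matches_networkx(self):
        import networkx as nx

        net = random_graph(20, 0.2, seed=10)
        expected = nx.pagerank(to_networkx(net), alpha=0.85, weight=None, tol=1e-12, max_iter=2000)
        got = pagerank(net)
        for node in net.nodes():
            assert got[node] == pytest.approx(expected[node], abs=1e-8)


class TestCentralityReport:
    def test_star_degree_top_is_center(self):
        reports = centrality_report(star_graph(5), measures=("degree",), top_k=1)
        assert reports["degree"].ranking == [("center", 5.0)]

    def test_unknown_measure_rejected(self):
        with pytest.raises(ConfigError):
            centrality_report(star_graph(3), measures=("katz",))

    def test_tied_scores_rank_lexically(self):
        net = cycle_graph(5)  # all degrees equal
        reports = centrality_report(net, measures=("degree",), top_k=5)
        assert [node for node, _ in reports["degree"].ranking] == net.nodes()

    def test_node_filter_excludes_traits_from_ranking_not_computation(self):
        net = star_graph(4)
        net.add_node("center", "trait")  # re-class the hub as a trait
        reports = centrality_report(
            net, measures=("degree", "pagerank"), top_k=10, node_filter="transcript"
        )
        names = [node for node, _ in reports["degree"].ranking]
        assert "center" not in names and len(names) == 4
        # the trait still holds its PageRank mass: leaf scores reflect it
        assert sum(reports["pagerank"].scores.values()) == pytest.approx(1.0)

    def test_planted_hub_ranks_first_on_most_measures(self):
        """A transcript loading on every module becomes the top hub."""
        from coexnet import (
            SyntheticSpec,
            align_strains,
            expected_correlation,
            generate_dataset,
            submatrix,
            threshold_network,
        )

        wins = 0
        trials = 3
        for seed in range(trials):
            spec = SyntheticSpec(
                n_strains=60, n_transcripts=70, module_sizes=(20, 20, 20),
                loading=2.0, noise_sd=1.0, phenotyped_fraction=1.0,
                planted_hub=True, rng_seed=100 + seed,
            )
            expr, pheno, truth = generate_dataset(spec)
            data = align_strains(expr, pheno)
            corr = submatrix(data, data.transcript_ids)
            # hub-to-module r has closed form ~0.496; threshold below it
            hub_r = 2 * 2 / math.sqrt((3 * 4 + 1) * (4 + 1))
            assert expected_correlation(2.0, 2.0, 1.0) == pytest.approx(0.8)
            net = threshold_network(corr, round(hub_r - 0.05, 2))
            reports = centrality_report(net, top_k=1)
            firsts = [rep.ranking[0][0] for rep in reports.values()]
            if sum(name == truth.hub_id for name in firsts) >= 4:
                wins += 1
        assert wins == trials


class TestRelabelInvariance:
    def test_all_measures_invariant_under_node_relabeling(self):
        net = random_graph(12, 0.3, seed=21)
        mapping = {node: f"x{ord(node[0])}{node[::-1]}" for node in net.nodes()}
        relabeled = Network()
        for node in net.nodes():
            relabeled.add_node(mapping[node])
        for u, v, w in net.edges():
            relabeled.add_edge(mapping[u], mapping[v], w)
        for fn in (degree_centrality, betweenness, closeness, pagerank,
                   eigenvector_centrality):
            base = fn(net)
            moved = fn(relabeled)
            for node in net.nodes():
                assert moved[mapping[node]] == pytest.approx(base[node], abs=1e-8)
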