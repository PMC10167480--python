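import itertools

import numpy as np
import pytest

from progulons import (
    ClusterOneParams,
    ModuleSpec,
    OpticsParams,
    clusterone_clusters,
    derive_seeds,
    fit_surrogate_trees,
    optics_clusters,
    simulate_proteomehd,
    top_edges,
    treeclust_dissimilarity,
)
from progulons.data_io import ProgulonError
from progulons.dissimilarity import CoregulationNetwork, DissimilarityMatrix
from progulons.seed_discovery import cohesiveness, optics_reachability


def dist_matrix(d: np.ndarray) -> DissimilarityMatrix:
    ids = [f"p{i:02d}" for i in range(len(d))]
    return DissimilarityMatrix(protein_ids=ids, d=d, n_trees_used=1)


def make_net(nodes, edges, weights=None) -> CoregulationNetwork:
    es = {frozenset(e) for e in edges}
    w = {frozenset(e): (weights or {}).get(tuple(sorted(e)), 1.0) for e in edges}
    return CoregulationNetwork(nodes=list(nodes), edges=es, weights=w)


class TestOptics:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        n = 10
        d = np.full((2 * n, 2 * n), 0.9)
        within = rng.uniform(0.01, 0.1, size=(2 * n, 2 * n))
        within = (within + within.T) / 2
        d[:n, :n] = within[:n, :n]
        d[n:, n:] = within[n:, n:]
        np.fill_diagonal(d, 0.0)
        clusters = optics_clusters(dist_matrix(d), OpticsParams(xi=0.05))
        assert len(clusters) == 2
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [n, n]
        blob_a = {f"p{i:02d}" for i in range(n)}
        assert {frozenset(c) for c in clusters} == {
            frozenset(blob_a),
            frozenset(f"p{i:02d}" for i in range(n, 2 * n)),
        }

    def test_uniform_distances_yield_no_clusters(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.4, 0.6, size=(20, 20))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        clusters = optics_clusters(dist_matrix(d), OpticsParams(xi=0.05))
        # no dense structure: nothing or noise-dominated fragments only
        assert sum(len(c) for c in clusters) <= 10

    def test_fewer_points_than_min_pts(self):
        d = np.zeros((3, 3))
        with pytest.raises(ProgulonError):
            optics_clusters(dist_matrix(d), OpticsParams(min_pts=5))

    def test_reachability_matches_hand_stepped_walk(self):
        """Reachability profile equals a textbook OPTICS walk on a 12-point
        one-dimensional fixture (core distance = distance to the
        min_pts-th nearest point, the point itself included)."""
        pts = np.array([0.0, 0.1, 0.2, 0.3, 0.35, 0.4,
                        2.0, 2.05, 2.1, 2.2, 2.3, 5.0])
        d = np.abs(pts[:, None] - pts[None, :]) / 10.0
        min_pts = 3

        core = np.sort(d, axis=1)[:, min_pts - 1]
        n = len(d)
        reach = np.full(n, np.inf)
        processed = np.zeros(n, bool)
        order = []
        seeds: dict[int, float] = {}
        while len(order) < n:
            if seeds:
                i = min(seeds, key=lambda k: (seeds[k], k))
                del seeds[i]
            else:
                i = int(np.flatnonzero(~processed)[0])
            processed[i] = True
            order.append(i)
            for j in np.flatnonzero(~processed):
                nd = max(core[i], d[i, j])
                if nd < reach[j]:
                    reach[j] = nd
                    seeds[j] = nd

        got_ids, got_reach = optics_reachability(
            dist_matrix(d), OpticsParams(xi=0.05, min_pts=min_pts))
        assert [int(x[1:]) for x in got_ids] == order
        np.testing.assert_allclose(got_reach[1:], [reach[i] for i in order][1:])
        assert np.isinf(got_reach[0])


def brute_force_best_cluster(g_nodes, edges, weights, contains, penalty):
    """Exhaustive search: the connected vertex subset with maximal
    cohesiveness among all subsets containing ``contains``."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(g_nodes)
    for e in edges:
        a, b = tuple(e)
        g.add_edge(a, b, weight=weights.get(frozenset(e), 1.0))
    best, best_f = None, -1.0
    nodes = list(g_nodes)
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            s = set(sub)
            if contains not in s:
                continue
            if not nx.is_connected(g.subgraph(s)):
                continue
            f = cohesiveness(g, s, penalty)
            if f > best_f:
                best, best_f = s, f
    return best, best_f


class TestClusterOne:
    def test_isolated_four_clique(self):
        nodes = list("abcdxy")
        edges = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"),
                 ("b", "d"), ("c", "d"), ("x", "y")]
        clusters = clusterone_clusters(make_net(nodes, edges))
        assert frozenset("abcd") in clusters
        # the isolated pair is below min_size
        assert all(len(c) >= 4 for c in clusters)

    def test_three_clique_below_min_size(self):
        nodes = list("abc")
        edges = [("a", "b"), ("a", "c"), ("b", "c")]
        assert clusterone_clusters(make_net(nodes, edges)) == []

    def test_empty_graph_raises(self):
        with pytest.raises(ProgulonError):
            clusterone_clusters(make_net(["a"], []))

    def test_matches_exhaustive_cohesiveness_search(self):
        """On two disjoint 4-cliques (8 nodes) the emitted clusters equal
        the subsets that exhaustive search over all connected vertex
        subsets proves globally optimal."""
        nodes = list("abcdefgh")
        edges = list(itertools.combinations("abcd", 2)) + \
            list(itertools.combinations("efgh", 2))
        params = ClusterOneParams(penalty=2.0, min_size=4,
                                  density_threshold=0.4)
        clusters = clusterone_clusters(make_net(nodes, edges), params)
        assert set(clusters) == {frozenset("abcd"), frozenset("efgh")}
        for c in clusters:
            best, best_f = brute_force_best_cluster(
                nodes, [frozenset(e) for e in edges], {}, min(c), 2.0)
            assert set(c) == best

    def test_clusters_are_local_cohesiveness_maxima(self):
        """With a bridge between the cliques, each emitted cluster is a
        local maximum of cohesiveness: no single vertex addition or
        removal improves it (checked exhaustively)."""
        import networkx as nx
        nodes = list("abcdefg")
        edges = list(itertools.combinations("abcd", 2)) + \
            list(itertools.combinations("defg", 2))
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        clusters = clusterone_clusters(make_net(nodes, edges))
        assert clusters
        for c in clusters:
            f = cohesiveness(g, set(c), 2.0)
            for v in nodes:
                moved = set(c) - {v} if v in c else set(c) | {v}
                if len(moved) >= 1:
                    assert cohesiveness(g, moved, 2.0) <= f + 1e-12

    def test_density_filter(self):
        # a path of 5 nodes is connected but sparse (density 0.4 exactly
        # for 5 nodes/4 edges); a stricter threshold drops it
        nodes = list("abcde")
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        loose = clusterone_clusters(
            make_net(nodes, edges),
            ClusterOneParams(density_threshold=0.0, min_size=4))
        strict = clusterone_clusters(
            make_net(nodes, edges),
            ClusterOneParams(density_threshold=0.9, min_size=4))
        assert strict == []
        assert all(len(c) >= 4 for c in loose)


def cohesiveness_of(nodes, edges, subset):
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return cohesiveness(g, set(subset), 2.0)


class TestDeriveSeeds:
    def test_intersection_rule(self):
        optics = [frozenset("ABCDE")]
        c1 = [frozenset("ABCDF")]
        seeds = derive_seeds(optics, c1)
        assert len(seeds) == 1
        assert seeds[0].members == frozenset("ABCD")

    def test_small_intersection_dropped(self):
        optics = [frozenset("ABCDE")]
        c1 = [frozenset("ABCXY")]
        assert derive_seeds(optics, c1) == []

    def test_highest_overlap_cluster_selected(self):
        optics = [frozenset("ABCDEFG")]
        c1 = [frozenset("ABCDEXY"), frozenset("ABCQRS")]
        seeds = derive_seeds(optics, c1)
        assert seeds[0].members == frozenset("ABCDE")

    def test_each_c1_cluster_used_once(self):
        optics = [frozenset("ABCDE"), frozenset("ABCDX")]
        c1 = [frozenset("ABCDE")]
        seeds = derive_seeds(optics, c1)
        # best match (5-overlap) wins the only graph cluster
        assert len(seeds) == 1
        assert seeds[0].members == frozenset("ABCDE")

    def test_seed_subset_invariant(self, planted_matrix):
        """Every derived seed lies inside one OPTICS cluster and one
        cohesiveness cluster."""
        m, _ = planted_matrix
        forest = fit_surrogate_trees(m, seed=0)
        d = treeclust_dissimilarity(forest)
        oc = optics_clusters(d)
        net = top_edges(d, fraction=0.03)
        cc = clusterone_clusters(net)
        for s in derive_seeds(oc, cc):
            assert any(s.members <= c for c in oc)
            assert any(s.members <= c for c in cc)


class TestPlantedModuleRecovery:
    def test_recovers_planted_modules(self):
        """Dual clustering recovers >= 80% of tight planted modules
        (within-module rho ~ 0.9) at Jaccard >= 0.5, pooled over seeds."""
        recovered = total = 0
        for rs in range(4):
            mods = [ModuleSpec.from_rho(15, 0.9, detection_fraction=0.75)
                    for _ in range(5)]
            m, truth = simulate_proteomehd(
                250, 100, mods, background_detection=0.75, rng_seed=rs)
            forest = fit_surrogate_trees(m, seed=rs)
            d = treeclust_dissimilarity(forest)
            oc = optics_clusters(d)
            net = top_edges(d, fraction=0.02)
            cc = clusterone_clusters(net)
            seeds = derive_seeds(oc, cc)
            for tm in truth.module_members.values():
                total += 1
                best = max((len(tm & s.members) / len(tm | s.members)
                            for s in seeds), default=0.0)
                recovered += best >= 0.5
        assert recovered / total >= 0.8
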