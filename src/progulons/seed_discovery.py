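"""De novo seed derivation by intersecting two clusterings.

Small, tightly co-regulated protein groups are found twice, by
algorithms with different mathematical principles and different inputs:
density-based OPTICS on the full dissimilarity matrix, and a
cohesiveness-maximising graph clustering (in the style of ClusterONE) on
the sparse top-similarity network.  A seed is the intersection of an
OPTICS cluster with its best-overlapping graph cluster; proteins called
by only one algorithm are dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.cluster import OPTICS

from .data_io import ProgulonError, Provenance, SeedGroup
from .dissimilarity import CoregulationNetwork, DissimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class OpticsParams:
    xi: float = 0.0001
    min_pts: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.xi < 1:
            raise ValueError("xi must be in (0, 1)")
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")


@dataclass
class ClusterOneParams:
    min_size: int = 4
    density_threshold: float = 0.4
    penalty: float = 2.0
    merge_overlap: float = 0.8

    def __post_init__(self) -> None:
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if not 0 <= self.density_threshold <= 1:
            raise ValueError("density_threshold must be in [0, 1]")


# ---------------------------------------------------------------------------
# OPTICS
# ---------------------------------------------------------------------------

def optics_clusters(
    d: DissimilarityMatrix, p: OpticsParams | None = None
) -> list[frozenset[str]]:
    """Density clusters from the OPTICS reachability ordering (Xi method).

    Undefined dissimilarities are imputed to the maximum observed
    distance (a pair never seen in the same tree is maximally distant).
    Noise points stay unassigned.
    """
    p = p or OpticsParams()
    n = len(d.protein_ids)
    if n < p.min_pts:
        raise ProgulonError(f"only {n} points but min_pts={p.min_pts}")
    dist = d.d.copy()
    if np.isnan(dist).any():
        dmax = np.nanmax(dist)
        logger.info("imputing undefined dissimilarities to max distance %.3f", dmax)
        dist = np.where(np.isnan(dist), dmax, dist)
    np.fill_diagonal(dist, 0.0)
    model = OPTICS(
        min_samples=p.min_pts, metric="precomputed",
        cluster_method="xi", xi=p.xi,
    ).fit(dist)
    labels = model.labels_
    clusters: dict[int, set[str]] = {}
    for pid, lab in zip(d.protein_ids, labels):
        if lab >= 0:
            clusters.setdefault(int(lab), set()).add(pid)
    # a "cluster" spanning every point carries no density structure
    return [frozenset(clusters[k]) for k in sorted(clusters)
            if len(clusters[k]) < n]


def optics_reachability(
    d: DissimilarityMatrix, p: OpticsParams | None = None
) -> tuple[list[str], np.ndarray]:
    """Reachability profile (processing order, reachability distances)."""
    p = p or OpticsParams()
    dist = d.d.copy()
    if np.isnan(dist).any():
        dist = np.where(np.isnan(dist), np.nanmax(dist), dist)
    np.fill_diagonal(dist, 0.0)
    model = OPTICS(min_samples=p.min_pts, metric="precomputed",
                   cluster_method="xi", xi=p.xi).fit(dist)
    order = model.ordering_
    return [d.protein_ids[i] for i in order], model.reachability_[order]


# ---------------------------------------------------------------------------
# ClusterONE-style cohesiveness clustering
# ---------------------------------------------------------------------------

def cohesiveness(g: nx.Graph, nodes: set, penalty: float = 2.0) -> float:
    """w_in / (w_in + w_bound + penalty * |V|).

    w_in is the total edge weight inside ``nodes``; w_bound the weight
    crossing the boundary; the per-vertex penalty models unobserved
    external connectivity.
    """
    w_in = 0.0
    w_bound = 0.0
    for u in nodes:
        for v, data in g[u].items():
            w = data.get("weight", 1.0)
            if v in nodes:
                w_in += w / 2.0
            else:
                w_bound += w
    denom = w_in + w_bound + penalty * len(nodes)
    return w_in / denom if denom > 0 else 0.0


def _graph_density(g: nx.Graph, nodes: set) -> float:
    k = len(nodes)
    if k < 2:
        return 0.0
    e = sum(1 for u, v in itertools.combinations(nodes, 2) if g.has_edge(u, v))
    return e / (k * (k - 1) / 2)


def _grow_cluster(g: nx.Graph, seed, penalty: float) -> set:
    """Greedy cohesiveness maximisation from a seed vertex.

    Alternates best-addition (boundary vertices) and best-removal until
    no single move increases cohesiveness.  Ties break lexicographically
    for determinism.
    """
    current = {seed}
    f = cohesiveness(g, current, penalty)
    while True:
        best_gain = 0.0
        best_move = None
        boundary = sorted({v for u in current for v in g[u] if v not in current})
        for v in boundary:
            cand = current | {v}
            fc = cohesiveness(g, cand, penalty)
            if fc - f > best_gain + 1e-12:
                best_gain = fc - f
                best_move = ("add", v)
        if len(current) > 1:
            for v in sorted(current):
                if v == seed:
                    continue
                cand = current - {v}
                fc = cohesiveness(g, cand, penalty)
                if fc - f > best_gain + 1e-12:
                    best_gain = fc - f
                    best_move = ("remove", v)
        if best_move is None:
            return current
        op, v = best_move
        current = current | {v} if op == "add" else current - {v}
        f += best_gain


def _match_coefficient(a: set, b: set) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def clusterone_clusters(
    net: CoregulationNetwork, p: ClusterOneParams | None = None
) -> list[frozenset[str]]:
    """Greedy cohesiveness clusters on the co-regulation network.

    Vertices seed candidate clusters in order of decreasing weighted
    degree; each unused vertex grows a cluster by add/remove moves that
    increase cohesiveness; overlapping candidates (match coefficient >=
    merge_overlap) are merged; finally size and density filters apply.
    """
    p = p or ClusterOneParams()
    if not net.edges:
        raise ProgulonError("empty network")
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for e in net.edges:
        a, b = sorted(e)
        g.add_edge(a, b, weight=net.weights.get(e, 1.0))
    degree = dict(g.degree(weight="weight"))
    order = sorted((n for n in g.nodes if degree[n] > 0),
                   key=lambda n: (-degree[n], n))
    covered: set = set()
    candidates: list[set] = []
    for seed in order:
        if seed in covered:
            continue
        cluster = _grow_cluster(g, seed, p.penalty)
        candidates.append(cluster)
        covered |= cluster
    # merge highly overlapping candidates
    merged = True
    while merged:
        merged = False
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                if _match_coefficient(candidates[i], candidates[j]) >= p.merge_overlap:
                    candidates[i] = candidates[i] | candidates[j]
                    del candidates[j]
                    merged = True
                    break
            if merged:
                break
    out = []
    for c in candidates:
        if len(c) >= p.min_size and _graph_density(g, c) >= p.density_threshold:
            out.append(frozenset(c))
    # deterministic output order: by size desc, then sorted members
    out.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return out


# ---------------------------------------------------------------------------
# Seed derivation (intersection rule)
# ---------------------------------------------------------------------------

def derive_seeds(
    optics: list[frozenset[str]],
    c1: list[frozenset[str]],
    min_seed: int = 4,
) -> list[SeedGroup]:
    """Intersect each OPTICS cluster with its best-matching graph cluster.

    For every OPTICS cluster the single cohesiveness cluster with the
    largest overlap is selected (ties by larger Jaccard, then
    lexicographic member order); the seed is the intersection.  Each
    graph cluster can serve at most one OPTICS cluster (best match
    wins), and intersections below ``min_seed`` are dropped.
    """
    if not optics or not c1:
        raise ValueError("both cluster lists must be non-empty")

    def jaccard(a, b):
        return len(a & b) / len(a | b)

    # score all (optics, c1) pairs; assign greedily by best overlap first
    pairs = []
    for oi, oc in enumerate(optics):
        for ci, cc in enumerate(c1):
            ov = len(oc & cc)
            if ov > 0:
                pairs.append((ov, jaccard(oc, cc), -oi, -ci, oi, ci))
    pairs.sort(key=lambda t: (-t[0], -t[1], tuple(sorted(optics[t[4]])),
                              tuple(sorted(c1[t[5]]))))
    used_optics: set[int] = set()
    used_c1: set[int] = set()
    seeds: list[SeedGroup] = []
    for ov, _, _, _, oi, ci in pairs:
        if oi in used_optics or ci in used_c1:
            continue
        used_optics.add(oi)
        used_c1.add(ci)
        inter = optics[oi] & c1[ci]
        if len(inter) < min_seed:
            logger.info("intersection of size %d < %d dropped", len(inter), min_seed)
            continue
        seeds.append(SeedGroup(
            name=f"seed_{len(seeds) + 1:03d}",
            members=frozenset(inter),
            provenance=Provenance.clustering,
        ))
    return seeds
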