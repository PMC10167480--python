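"""From RF scores to a progulon: connectivity-driven membership cutoff.

An RF score only says a protein tracks the seed; a genuine module also
requires its members to be co-regulated with each other.  For a
candidate member set we therefore test, with a one-sided Fisher's exact
test, whether its internal protein pairs are enriched among the top
0.5% most-similar pairs of the global co-regulation network.  Scanning
the score cutoff from 0.50 to 1.00 in 0.01 steps, the minimum cutoff
whose member set is significantly interconnected (P < 0.05) defines the
progulon; if no cutoff works, the candidate is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ProgulonError, ValidationError
from .dissimilarity import CoregulationNetwork, DissimilarityMatrix
from .rf_core import ProgulonScores, QcReport

logger = logging.getLogger(__name__)

CUTOFF_GRID = [round(0.50 + 0.01 * i, 2) for i in range(51)]


@dataclass
class Progulon:
    name: str
    members: frozenset[str]
    cutoff: float
    connectivity_p: float
    qc: QcReport
    scores: ProgulonScores

    def __post_init__(self) -> None:
        if not 0.5 <= self.cutoff <= 1.0:
            raise ValidationError(f"cutoff {self.cutoff} outside [0.5, 1.0]")

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.table.copy()
        out["member"] = out.index.isin(self.members)
        return out


def connectivity_pvalue(
    members: frozenset[str] | set[str],
    net: CoregulationNetwork,
    universe: frozenset[str] | set[str],
) -> float:
    """One-sided Fisher P for enrichment of network edges inside ``members``.

    The 2x2 table classifies every unordered pair of universe proteins
    by (internal to members) x (is a network edge); pairs with undefined
    similarity simply count as non-edges.
    """
    members = set(members)
    universe = set(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 proteins")
    if not members <= universe:
        raise ValueError("members must be a subset of the universe")
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    n_u = len(universe)
    n_m = len(members)
    total_pairs = n_u * (n_u - 1) // 2
    internal_pairs = n_m * (n_m - 1) // 2
    edges_in_universe = sum(1 for e in net.edges if e <= universe)
    internal_edges = sum(1 for e in net.edges if e <= members)
    table = [
        [internal_edges, internal_pairs - internal_edges],
        [edges_in_universe - internal_edges,
         total_pairs - internal_pairs - (edges_in_universe - internal_edges)],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def select_cutoff(
    scores: ProgulonScores,
    net: CoregulationNetwork,
    universe: frozenset[str] | set[str],
    alpha: float = 0.05,
) -> tuple[float, float] | None:
    """Minimum grid cutoff yielding a significantly interconnected module.

    Evaluates the 51-point grid {0.50, 0.51, ..., 1.00} in ascending
    order and returns (cutoff, P) at the first point where the member
    set {score >= cutoff} has >= 2 members and connectivity P < alpha.
    Returns None (discard) if no cutoff qualifies.
    """
    eff = scores.effective_score()
    for cutoff in CUTOFF_GRID:
        members = set(eff.index[eff >= cutoff])
        if len(members) < 2:
            continue
        p = connectivity_pvalue(members, net, universe)
        if p < alpha:
            return cutoff, p
    return None


def finalize_progulon(
    name: str,
    scores: ProgulonScores,
    cutoff: float,
    connectivity_p: float,
    qc: QcReport,
    alpha: float = 0.05,
) -> Progulon:
    """Materialise the progulon; QC and connectivity gates must hold."""
    if not qc.passed:
        raise ProgulonError(f"{name}: QC gates not passed ({qc.to_dict()})")
    if not connectivity_p < alpha:
        raise ProgulonError(f"{name}: connectivity P {connectivity_p} >= {alpha}")
    eff = scores.effective_score()
    members = frozenset(eff.index[eff >= cutoff])
    return Progulon(name=name, members=members, cutoff=cutoff,
                    connectivity_p=connectivity_p, qc=qc, scores=scores)


def embed_tsne(
    d: DissimilarityMatrix,
    members: list[str] | None = None,
    perplexity: float = 30.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Exact (non-approximated) t-SNE of the member-restricted distances.

    Equivalent to running Barnes-Hut t-SNE with theta = 0.  Perplexity
    is shrunk with a warning when there are too few members.
    """
    from sklearn.manifold import TSNE

    ids = members if members is not None else d.protein_ids
    if len(ids) < 5:
        raise ValueError("need at least 5 members to embed")
    pos = {p: i for i, p in enumerate(d.protein_ids)}
    sel = np.array([pos[p] for p in ids])
    dist = d.d[np.ix_(sel, sel)]
    if np.isnan(dist).any():
        dist = np.where(np.isnan(dist), np.nanmax(dist), dist)
    max_perp = (len(ids) - 1) / 3
    if perplexity > max_perp:
        logger.warning("perplexity %.1f too large for %d members; using %.2f",
                       perplexity, len(ids), max_perp)
        perplexity = max_perp
    coords = TSNE(
        n_components=2, method="exact", metric="precomputed",
        perplexity=perplexity, init="random", random_state=rng_seed,
    ).fit_transform(dist)
    return pd.DataFrame(coords, index=pd.Index(ids, name="protein_id"),
                        columns=["tsne_1", "tsne_2"])
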