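"""Comparative statistics over protein groups.

Covers the downstream questions asked of co-regulation modules: which
annotation sets they are enriched for; how much mRNA changes contribute
to protein changes (per-gene mRNA-protein Spearman rho); how coordinated
a module's expression is (median within-group pairwise rho); whether a
group statistic is extreme relative to random same-size groups
(Monte-Carlo permutation test); whether co-regulation of pairs is
conserved in a second dataset; and whether a module's genes cluster on
chromosomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AnnotationCollection, ProgulonError


@dataclass
class PairedOmics:
    """Matched gene x sample mRNA and protein matrices (same ordering)."""

    mrna: pd.DataFrame
    protein: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.mrna.index.equals(self.protein.index):
            raise ValueError("mRNA and protein gene ordering differ")
        if not self.mrna.columns.equals(self.protein.columns):
            raise ValueError("mRNA and protein sample ordering differ")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mrna.index)


@dataclass
class GroupStats:
    contribution: float
    mrna_coordination: float
    protein_coordination: float
    scale: float
    perm_p_high: float | None = None
    perm_p_low: float | None = None


# ---------------------------------------------------------------------------
# Annotation enrichment (flat Fisher + Bonferroni)
# ---------------------------------------------------------------------------

def annotation_enrichment(
    groups: Mapping[str, Iterable[str]],
    ann: AnnotationCollection,
    analysed: Iterable[str],
    min_set_size: int = 20,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of each group for each annotation set.

    The universe is restricted to proteins that were both analysed and
    annotated; sets below ``min_set_size`` (within the universe) are not
    tested; Bonferroni correction spans all tested combinations.
    """
    universe = frozenset(analysed) & ann.universe
    if not universe:
        raise ProgulonError("empty universe: no analysed protein is annotated")
    rows = []
    testable = {name: s & universe for name, s in ann.sets.items()
                if len(s & universe) >= min_set_size}
    for gname, gmembers in groups.items():
        g = frozenset(gmembers) & universe
        for sname, s in testable.items():
            a = len(g & s)
            b = len(g - s)
            c = len(s - g)
            d = len(universe) - a - b - c
            p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            rows.append((gname, sname, a, len(g), len(s), float(p)))
    out = pd.DataFrame(rows, columns=["group", "set", "overlap", "group_size",
                                      "set_size", "p_raw"])
    n_tests = len(out)
    out["p_bonferroni"] = np.minimum(out["p_raw"] * n_tests, 1.0)
    return out


# ---------------------------------------------------------------------------
# Contribution, coordination, scale
# ---------------------------------------------------------------------------

def _pairwise_complete_spearman(x: np.ndarray, y: np.ndarray,
                                min_overlap: int = 3) -> float:
    both = ~np.isnan(x) & ~np.isnan(y)
    if both.sum() < min_overlap:
        return np.nan
    return float(stats.spearmanr(x[both], y[both]).statistic)


def contribution_rho(po: PairedOmics, gene: str, min_overlap: int = 3) -> float:
    """Spearman rho between a gene's mRNA and protein profiles.

    High rho means transcript changes propagate to the protein
    (transcriptional control); low rho points to regulation at the
    protein level.  NaN when fewer than ``min_overlap`` samples have
    both measurements.
    """
    x = po.mrna.loc[gene].to_numpy(dtype=float)
    y = po.protein.loc[gene].to_numpy(dtype=float)
    return _pairwise_complete_spearman(x, y, min_overlap)


def group_coordination(
    matrix: pd.DataFrame,
    group: Iterable[str],
    min_overlap: int = 3,
) -> float:
    """Median pairwise-complete Spearman rho over within-group pairs."""
    members = [g for g in group if g in matrix.index]
    if len(members) < 2:
        raise ValueError("group needs at least 2 members present in the matrix")
    sub = matrix.loc[members]
    rho = sub.T.corr(method="spearman", min_periods=min_overlap).to_numpy()
    iu, ju = np.triu_indices(len(members), k=1)
    vals = rho[iu, ju]
    vals = vals[~np.isnan(vals)]
    return float(np.median(vals)) if len(vals) else np.nan


def scale_of_variation(matrix: pd.DataFrame, group: Iterable[str]) -> float:
    """Median over members of the (unscaled) MAD of their profiles."""
    members = [g for g in group if g in matrix.index]
    if not members:
        raise ValueError("no group member present in the matrix")
    mads = []
    for g in members:
        row = matrix.loc[g].to_numpy(dtype=float)
        row = row[~np.isnan(row)]
        if len(row):
            mads.append(np.median(np.abs(row - np.median(row))))
    return float(np.median(mads)) if mads else np.nan


def group_stats(
    po: PairedOmics,
    group: Iterable[str],
    min_overlap: int = 3,
) -> GroupStats:
    """Contribution, coordination and scale summaries for one group."""
    members = [g for g in group if g in po.mrna.index]
    contrib = [contribution_rho(po, g, min_overlap) for g in members]
    contrib = [c for c in contrib if not np.isnan(c)]
    return GroupStats(
        contribution=float(np.median(contrib)) if contrib else np.nan,
        mrna_coordination=group_coordination(po.mrna, members, min_overlap),
        protein_coordination=group_coordination(po.protein, members, min_overlap),
        scale=scale_of_variation(po.protein, members),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo permutation test
# ---------------------------------------------------------------------------

def group_permutation_test(
    per_gene_stat: pd.Series,
    group: Iterable[str],
    universe: Iterable[str],
    B: int = 10000,
    side: str = "high",
    rng_seed: int = 0,
) -> float:
    """Monte-Carlo P for the group median of a per-gene statistic.

    The null draws B uniform gene sets of the same size from the
    universe; P = (r + 1) / (B + 1), with r the number of null medians
    at least as extreme in the tested direction.  The minimum attainable
    P is therefore 1 / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if side not in ("high", "low"):
        raise ValueError("side must be 'high' or 'low'")
    group = list(dict.fromkeys(group))
    universe = list(dict.fromkeys(universe))
    if not set(group) <= set(universe):
        raise ValueError("group must be a subset of the universe")
    if len(group) > len(universe):
        raise ValueError("group larger than universe")
    vals = per_gene_stat.reindex(universe).to_numpy(dtype=float)
    gvals = per_gene_stat.reindex(group).to_numpy(dtype=float)
    observed = np.nanmedian(gvals)
    rng = np.random.default_rng(rng_seed)
    k = len(group)
    draws = np.empty(B)
    for b in range(B):
        idx = rng.choice(len(universe), size=k, replace=False)
        draws[b] = np.nanmedian(vals[idx])
    if side == "high":
        r = int(np.sum(draws >= observed))
    else:
        r = int(np.sum(draws <= observed))
    return (r + 1) / (B + 1)


# ---------------------------------------------------------------------------
# Conservation of co-regulation across datasets
# ---------------------------------------------------------------------------

def conservation_of_coregulation(
    rho_a: pd.DataFrame,
    rho_b: pd.DataFrame,
    ortholog_map: Mapping[str, str],
    progulon_membership: Mapping[str, str],
    rho_min: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Conservation of co-regulated pairs (rho > rho_min) in dataset B.

    Pairs co-regulated in A are split into three categories -- both
    proteins in the same progulon, in different progulons, or neither in
    any progulon -- and the fraction still co-regulated in B is
    reported per category, plus a Fisher's exact P comparing
    same-progulon pairs against the rest.
    """
    mapped = {a: b for a, b in ortholog_map.items()
              if a in rho_a.index and b in rho_b.index}
    genes = sorted(mapped)
    if len(genes) < 2:
        raise ProgulonError("no mappable protein pairs")
    counts = {c: [0, 0] for c in ("same_progulon", "different_progulons", "no_progulon")}
    for ga, gb in itertools.combinations(genes, 2):
        ra = rho_a.loc[ga, gb]
        if not (pd.notna(ra) and ra > rho_min):
            continue
        rb = rho_b.loc[mapped[ga], mapped[gb]]
        pa = progulon_membership.get(ga)
        pb = progulon_membership.get(gb)
        if pa is None and pb is None:
            cat = "no_progulon"
        elif pa is not None and pa == pb:
            cat = "same_progulon"
        else:
            cat = "different_progulons"
        conserved = bool(pd.notna(rb) and rb > rho_min)
        counts[cat][0] += int(conserved)
        counts[cat][1] += 1
    rows = []
    for cat, (k, n) in counts.items():
        rows.append((cat, k, n, k / n if n else np.nan))
    table = pd.DataFrame(rows, columns=["category", "conserved", "total", "fraction"])
    same = counts["same_progulon"]
    rest = [counts["different_progulons"][0] + counts["no_progulon"][0],
            counts["different_progulons"][1] + counts["no_progulon"][1]]
    ftab = [[same[0], same[1] - same[0]], [rest[0], rest[1] - rest[0]]]
    p = float(stats.fisher_exact(ftab, alternative="greater")[1]) \
        if same[1] and rest[1] else np.nan
    return table, p


# ---------------------------------------------------------------------------
# Same-chromosome enrichment
# ---------------------------------------------------------------------------

def same_chromosome_enrichment(
    group: Iterable[str],
    chrom_map: Mapping[str, str],
) -> tuple[float, float, float]:
    """(observed, expected, two-sided Fisher P) for same-chromosome pairs.

    Observed: fraction of within-group gene pairs on one chromosome.
    Expected: the same fraction over all mapped genes.  The Fisher test
    contrasts group pairs against non-group pairs of the universe.
    """
    group = sorted(dict.fromkeys(group))
    unmapped = [g for g in group if g not in chrom_map]
    if unmapped:
        import logging
        logging.getLogger(__name__).warning("unmapped genes excluded: %s", unmapped)
        group = [g for g in group if g in chrom_map]
    if len(group) < 2:
        raise ValueError("need at least 2 mapped group genes")
    universe = sorted(chrom_map)

    def pair_counts(genes: Sequence[str]) -> tuple[int, int]:
        per_chrom: dict[str, int] = {}
        for g in genes:
            per_chrom[chrom_map[g]] = per_chrom.get(chrom_map[g], 0) + 1
        n = len(genes)
        total = n * (n - 1) // 2
        same = sum(k * (k - 1) // 2 for k in per_chrom.values())
        return same, total

    g_same, g_total = pair_counts(group)
    u_same, u_total = pair_counts(universe)
    rest_same = u_same - g_same
    rest_total = u_total - g_total
    table = [[g_same, g_total - g_same], [rest_same, rest_total - rest_same]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return g_same / g_total, u_same / u_total, p
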