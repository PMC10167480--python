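"""Tree-based and rank-based protein-protein (dis)similarity.

The workhorse metric is a tree-based dissimilarity in the style of
treeClust (Buttrey & Whitaker): one pruned regression tree is fitted per
experiment column, predicting that column from all others, and the
dissimilarity of two proteins is the fraction of retained trees in which
they land in different leaves.  This copes naturally with missing data
and non-linear co-regulation, which is why it outperforms plain
correlation on sparse perturbation-response matrices.

Also provided: pairwise-complete Spearman correlation and extraction of
the top-fraction most-similar pairs as a co-regulation network.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .data_io import ProgulonError, RatioMatrix

logger = logging.getLogger(__name__)


class NoInformativeTreesError(ProgulonError):
    pass


@dataclass
class TreeParams:
    """Hyperparameters of the per-column surrogate trees.

    Trees are grown with a minimum leaf size, then pruned by
    weakest-link cost-complexity pruning with a cross-validated 1-SE
    rule, mimicking rpart's default pruning behaviour.
    """

    min_samples_leaf: int = 5
    cv_folds: int = 10
    min_rows: int = 20  # columns observed in fewer rows are skipped


@dataclass
class SurrogateForest:
    """One pruned regression tree per retained experiment column.

    ``leaf_assignments`` maps every protein to a leaf of every retained
    tree (routing missing predictors through training-median imputation);
    ``usable`` flags proteins that had at least one observed predictor.
    """

    protein_ids: list[str]
    tree_columns: list[str]
    leaf_assignments: np.ndarray  # (n_proteins, n_trees) int
    usable: np.ndarray  # (n_proteins, n_trees) bool

    @property
    def n_trees(self) -> int:
        return len(self.tree_columns)


@dataclass
class DissimilarityMatrix:
    protein_ids: list[str]
    d: np.ndarray  # symmetric, in [0,1], NaN where undefined
    n_trees_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.protein_ids, columns=self.protein_ids)


@dataclass
class CorrelationMatrix:
    protein_ids: list[str]
    rho: np.ndarray  # symmetric, NaN where overlap < min_overlap
    n_overlap: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.protein_ids, columns=self.protein_ids)


@dataclass
class CoregulationNetwork:
    """Top-fraction most-similar protein pairs (default top 0.5%)."""

    nodes: list[str]
    edges: set[frozenset[str]]
    selection_fraction: float = 0.005
    weights: dict[frozenset[str], float] = field(default_factory=dict)

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges


# ---------------------------------------------------------------------------
# Surrogate-tree fitting (treeClust-style)
# ---------------------------------------------------------------------------

class _PrunableTree:
    """A fitted sklearn regression tree with weakest-link prune thresholds.

    ``collapse_alpha[t]`` is the cost-complexity alpha at which internal
    node ``t`` becomes a leaf; routing a sample at a given alpha stops
    at the first node whose threshold is reached.  This allows exact
    evaluation of every pruned subtree from a single unpruned fit,
    instead of refitting at each candidate alpha.
    """

    def __init__(self, tree: DecisionTreeRegressor):
        t = tree.tree_
        self.left = t.children_left.copy()
        self.right = t.children_right.copy()
        self.feature = t.feature.copy()
        self.threshold = t.threshold.copy()
        self.value = t.value[:, 0, 0].copy()
        n_nodes = t.node_count
        total_w = t.weighted_n_node_samples[0]
        risk = t.impurity * t.weighted_n_node_samples / total_w
        # bottom-up subtree risk and leaf counts (children have larger ids)
        sub_risk = risk.copy()
        n_leaves = np.ones(n_nodes)
        for node in range(n_nodes - 1, -1, -1):
            if self.left[node] >= 0:
                sub_risk[node] = sub_risk[self.left[node]] + sub_risk[self.right[node]]
                n_leaves[node] = n_leaves[self.left[node]] + n_leaves[self.right[node]]
        # iterative weakest-link pruning
        collapse = np.full(n_nodes, np.inf)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        for node in range(n_nodes):
            if self.left[node] >= 0:
                parent[self.left[node]] = node
                parent[self.right[node]] = node
        live = self.left >= 0
        while live.any():
            with np.errstate(invalid="ignore", divide="ignore"):
                g = np.where(live, (risk - sub_risk) / np.maximum(n_leaves - 1, 1),
                             np.inf)
            t_star = int(np.argmin(g))
            alpha = float(g[t_star])
            # collapse t_star and any still-live internal descendants
            stack = [t_star]
            while stack:
                node = stack.pop()
                if self.left[node] >= 0:
                    if live[node]:
                        collapse[node] = alpha
                        live[node] = False
                    stack.extend((self.left[node], self.right[node]))
            # update ancestors
            delta_risk = risk[t_star] - sub_risk[t_star]
            delta_leaves = n_leaves[t_star] - 1
            sub_risk[t_star] = risk[t_star]
            n_leaves[t_star] = 1
            node = parent[t_star]
            while node >= 0:
                sub_risk[node] += delta_risk
                n_leaves[node] -= delta_leaves
                node = parent[node]
        self.collapse_alpha = collapse

    @property
    def alphas(self) -> np.ndarray:
        """Distinct collapse alphas, ascending (last one collapses the root)."""
        finite = self.collapse_alpha[np.isfinite(self.collapse_alpha)]
        return np.unique(finite)

    def route(self, X: np.ndarray, alpha: float) -> np.ndarray:
        """Terminal node index per row of ``X`` in the alpha-pruned tree."""
        out = np.empty(len(X), dtype=np.int64)
        for i in range(len(X)):
            node = 0
            while self.left[node] >= 0 and self.collapse_alpha[node] > alpha:
                if X[i, self.feature[node]] <= self.threshold[node]:
                    node = self.left[node]
                else:
                    node = self.right[node]
            out[i] = node
        return out

    def predict(self, X: np.ndarray, alpha: float) -> np.ndarray:
        return self.value[self.route(X, alpha)]

    def n_leaves_at(self, alpha: float) -> int:
        pruned_internal = (self.left >= 0) & (self.collapse_alpha > alpha)
        return int(pruned_internal.sum()) + 1


def _select_alpha_1se(X: np.ndarray, y: np.ndarray, params: TreeParams,
                      rng_seed: int) -> tuple[float, _PrunableTree]:
    """Cost-complexity alpha by K-fold CV with the 1-SE rule.

    The candidate grid is the full tree's own alpha sequence (geometric
    midpoints, rpart-style); each fold fits one unpruned tree whose
    pruned predictions at every candidate are obtained by thresholded
    routing, so the CV curve is exact at K+1 tree fits total.
    """
    full = _PrunableTree(DecisionTreeRegressor(
        min_samples_leaf=params.min_samples_leaf, random_state=rng_seed,
    ).fit(X, y))
    seq = full.alphas
    if len(seq) == 0:  # already a stump
        return 0.0, full
    mids = np.sqrt(np.maximum(seq[:-1], 1e-12) * seq[1:]) if len(seq) > 1 \
        else np.empty(0)
    grid = np.concatenate([[0.0], mids, [seq[-1] * 1.0001]])
    n = len(y)
    folds = min(params.cv_folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    errs = np.zeros((folds, len(grid)))
    for f, (tr, te) in enumerate(kf.split(X)):
        ft = _PrunableTree(DecisionTreeRegressor(
            min_samples_leaf=params.min_samples_leaf, random_state=rng_seed,
        ).fit(X[tr], y[tr]))
        for j, a in enumerate(grid):
            errs[f, j] = np.mean((ft.predict(X[te], a) - y[te]) ** 2)
    mean = errs.mean(axis=0)
    se = errs.std(axis=0, ddof=1) / math.sqrt(folds)
    best = int(np.argmin(mean))
    limit = mean[best] + se[best]
    # largest alpha (simplest tree) whose CV error is within 1 SE of the best
    within = np.nonzero(mean <= limit)[0]
    return float(grid[within.max()]), full


def fit_surrogate_trees(
    m: RatioMatrix,
    tree_params: TreeParams | None = None,
    seed: int = 0,
) -> SurrogateForest:
    """Fit one pruned regression tree per experiment column.

    Each tree predicts its column from all other columns, on the rows
    where that column is observed.  Trees pruned back to a root (no
    split survives the 1-SE rule) are discarded.  Missing predictor
    values are median-imputed from the tree's training rows, both during
    fitting and when routing proteins to leaves.
    """
    params = tree_params or TreeParams()
    if m.n_experiments < 2:
        raise ValueError("need at least 2 experiment columns")
    values = m.values.to_numpy(dtype=float)
    n_prot, n_exp = values.shape
    cols: list[str] = []
    leaves: list[np.ndarray] = []
    usable_cols: list[np.ndarray] = []
    predictor_any = None
    for j, col_name in enumerate(m.experiment_ids):
        y_mask = ~np.isnan(values[:, j])
        if y_mask.sum() < params.min_rows:
            continue
        predictors = np.delete(np.arange(n_exp), j)
        Xfull = values[:, predictors]
        y = values[y_mask, j]
        Xtrain = Xfull[y_mask]
        with warnings.catch_warnings():
            # a predictor column entirely missing among training rows is
            # legitimate; its median falls back to 0
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(Xtrain, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        Xtrain_imp = np.where(np.isnan(Xtrain), med, Xtrain)
        alpha, tree = _select_alpha_1se(Xtrain_imp, y, params, rng_seed=seed + j)
        if tree.n_leaves_at(alpha) < 2:
            logger.debug("column %s: tree pruned to root, discarded", col_name)
            continue
        Xall_imp = np.where(np.isnan(Xfull), med, Xfull)
        leaves.append(tree.route(Xall_imp, alpha))
        usable_cols.append((~np.isnan(Xfull)).any(axis=1))
        cols.append(col_name)
    if not cols:
        raise NoInformativeTreesError(
            "no surrogate tree retained a split; the matrix has no usable structure"
        )
    return SurrogateForest(
        protein_ids=m.protein_ids,
        tree_columns=cols,
        leaf_assignments=np.column_stack(leaves),
        usable=np.column_stack(usable_cols),
    )


def treeclust_dissimilarity(
    forest: SurrogateForest,
    proteins: list[str] | None = None,
    weighted: bool = False,
    deviance_weights: np.ndarray | None = None,
) -> DissimilarityMatrix:
    """Leaf-disagreement dissimilarity over the retained trees.

    d(i, k) = fraction of trees, usable for both proteins, in which the
    two proteins sit in different leaves (treeClust's d1).  A
    deviance-weighted variant (d4-style) is available via ``weighted``.
    Pairs with zero usable trees are NaN, never silently 0.
    """
    if forest.n_trees == 0:
        raise ValueError("empty forest")
    ids = forest.protein_ids
    if proteins is not None:
        pos = {p: i for i, p in enumerate(ids)}
        sel = np.array([pos[p] for p in proteins])
        leaves = forest.leaf_assignments[sel]
        usable = forest.usable[sel]
        ids = list(proteins)
    else:
        leaves = forest.leaf_assignments
        usable = forest.usable
    n = len(ids)
    T = forest.n_trees
    if weighted:
        w = np.asarray(deviance_weights, dtype=float) if deviance_weights is not None \
            else np.ones(T)
    else:
        w = np.ones(T)
    disagree = np.zeros((n, n))
    denom = np.zeros((n, n))
    for t in range(T):
        lt = leaves[:, t]
        ut = usable[:, t]
        both = np.outer(ut, ut)
        diff = lt[:, None] != lt[None, :]
        disagree += w[t] * (both & diff)
        denom += w[t] * both
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, disagree / denom, np.nan)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(protein_ids=ids, d=d, n_trees_used=T)


# ---------------------------------------------------------------------------
# Pairwise-complete Spearman correlation
# ---------------------------------------------------------------------------

def spearman_matrix(m: RatioMatrix, min_overlap: int = 3) -> CorrelationMatrix:
    """Spearman rho over pairwise-complete observations.

    rho(i, j) uses only the experiments where both rows are observed and
    is undefined (NaN) below ``min_overlap`` shared observations.
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    values = m.values.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    overlap = mask.astype(int) @ mask.astype(int).T
    rho = m.values.T.corr(method="spearman", min_periods=min_overlap).to_numpy()
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(protein_ids=m.protein_ids, rho=rho, n_overlap=overlap)


# ---------------------------------------------------------------------------
# Top-fraction edge extraction
# ---------------------------------------------------------------------------

def top_edges(
    source: DissimilarityMatrix | CorrelationMatrix,
    fraction: float = 0.005,
) -> CoregulationNetwork:
    """The ``fraction`` most-similar protein pairs as a network.

    Similarity is 1 - d for a dissimilarity source and rho for a
    correlation source.  Exactly ceil(fraction x n_defined_pairs) edges
    are returned; boundary ties are broken by lexicographic pair order.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if isinstance(source, DissimilarityMatrix):
        sim = 1.0 - source.d
    else:
        sim = source.rho
    ids = source.protein_ids
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    s = sim[iu, ju]
    defined = ~np.isnan(s)
    if not defined.any():
        raise ValueError("all pairwise similarities are undefined")
    iu, ju, s = iu[defined], ju[defined], s[defined]
    n_edges = math.ceil(fraction * len(s))
    # sort by (-similarity, id_a, id_b): deterministic boundary tie-break
    pair_names = [(ids[a], ids[b]) if ids[a] < ids[b] else (ids[b], ids[a])
                  for a, b in zip(iu, ju)]
    order = sorted(range(len(s)), key=lambda k: (-s[k], pair_names[k]))
    chosen = order[:n_edges]
    edges = set()
    weights: dict[frozenset[str], float] = {}
    for k in chosen:
        e = frozenset(pair_names[k])
        edges.add(e)
        weights[e] = float(s[k])
    return CoregulationNetwork(
        nodes=list(ids), edges=edges, selection_fraction=fraction, weights=weights
    )


def write_edge_list(net: CoregulationNetwork, path) -> None:
    rows = sorted((tuple(sorted(e)), net.weights.get(e, np.nan)) for e in net.edges)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tsimilarity\n")
        for (a, b), w in rows:
            fh.write(f"{a}\t{b}\t{w:.6g}\n")
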