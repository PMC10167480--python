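"""End-to-end orchestration: seed -> scores -> QC -> progulon.

Thin glue over the library modules, shared by the command-line
interface and the test suite.  ``find_progulon`` runs the full chain
for one seed and reports either a finished progulon or the reason it
was discarded; the co-regulation network needed for the connectivity
cutoff is only computed (or accepted precomputed) once QC has passed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .data_io import RatioMatrix, SeedGroup, eligible_proteins
from .dissimilarity import (
    CoregulationNetwork,
    TreeParams,
    fit_surrogate_trees,
    top_edges,
    treeclust_dissimilarity,
)
from .progulon_assembly import Progulon, finalize_progulon, select_cutoff
from .rf_core import (
    ProgulonScores,
    QcReport,
    assemble_training,
    ensemble_scores,
    loo_cross_validate,
    qc_check,
)

logger = logging.getLogger(__name__)


@dataclass
class ProgulonRun:
    """Outcome of one seed run: a progulon, or the stage that failed."""

    seed_name: str
    status: str  # "ok" | "qc_fail" | "discard"
    scores: ProgulonScores
    qc: QcReport
    progulon: Progulon | None = None

    @property
    def passed(self) -> bool:
        return self.status == "ok"


def build_network(
    m: RatioMatrix,
    fraction: float = 0.005,
    tree_params: TreeParams | None = None,
    seed: int = 0,
) -> CoregulationNetwork:
    """Tree-based dissimilarity -> top-fraction co-regulation network."""
    forest = fit_surrogate_trees(m, tree_params=tree_params, seed=seed)
    d = treeclust_dissimilarity(forest)
    return top_edges(d, fraction=fraction)


def find_progulon(
    m: RatioMatrix,
    seed: SeedGroup,
    net: CoregulationNetwork | None = None,
    n_negatives: int = 1000,
    n_trees: int = 500,
    min_train_features: int = 45,
    min_test_features: int = 30,
    edge_fraction: float = 0.005,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> ProgulonRun:
    """Score, cross-validate, QC-gate and cut one candidate progulon.

    The connectivity universe is the set of scoreable proteins.  When
    ``net`` is None the network is built lazily, only for candidates
    that survive the QC gates.
    """
    cfg = assemble_training(
        seed, m, n_negatives=n_negatives, n_trees=n_trees,
        min_train_features=min_train_features,
        min_test_features=min_test_features, rng_seed=rng_seed,
    )
    scores = ensemble_scores(m, cfg)
    scores = loo_cross_validate(m, cfg, scores)
    qc = qc_check(scores, cfg)
    if not qc.passed:
        logger.info("seed %s failed QC: %s", seed.name, qc.to_dict())
        return ProgulonRun(seed.name, "qc_fail", scores, qc)
    if net is None:
        net = build_network(m, fraction=edge_fraction, seed=rng_seed)
    universe = eligible_proteins(m, min_test_features)
    selected = select_cutoff(scores, net, universe, alpha=alpha)
    if selected is None:
        logger.info("seed %s: no cutoff gives a connected module; discarded",
                    seed.name)
        return ProgulonRun(seed.name, "discard", scores, qc)
    cutoff, p = selected
    prog = finalize_progulon(seed.name, scores, cutoff, p, qc, alpha=alpha)
    return ProgulonRun(seed.name, "ok", scores, qc, progulon=prog)
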