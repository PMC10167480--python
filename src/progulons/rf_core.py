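"""Balanced Random-Forest ensemble scoring of co-regulation.

A seed group defines the positive class; a large pool of randomly drawn
proteins the negative class.  Because the positive class is tiny (often
< 15 proteins), a single forest would suffer from class imbalance.
Instead, many balanced models are trained -- each on all positives plus
an equally sized subset of the negative pool -- and their tree votes are
averaged into an RF score in [0, 1] per protein: the fraction of trees
voting the protein into the seed-co-regulated class.

Every seed protein additionally receives a leave-one-out (LOO) score
from ensembles retrained without it, which feeds two quality gates:
ROC AUC of LOO positives vs pool negatives must reach 0.99, and at
least 4 of the 10 top-scoring proteins must be cross-validated seed
proteins.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._forest import forest_votes
from .data_io import RatioMatrix, SeedGroup, ValidationError, eligible_proteins

logger = logging.getLogger(__name__)

AUC_THRESHOLD = 0.99
TOP10_MIN_TRAINING = 4


class SeedIneligibleError(ValidationError):
    pass


@dataclass
class TrainingConfig:
    """Resolved training classes and hyperparameters for one seed."""

    seed_name: str
    positives: list[str]
    negatives: list[str]
    n_trees: int = 500
    min_train_features: int = 45
    min_test_features: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValidationError("positives and negatives overlap")

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_models(self) -> int:
        """One balanced model per negative-pool chunk of size n_pos."""
        return math.ceil(len(self.negatives) / self.n_pos)


@dataclass
class ProgulonScores:
    """Per-protein ensemble scores plus LOO scores for the positives."""

    table: pd.DataFrame  # index protein_id; rf_score, is_training, loo_score, feature_count
    n_models: int
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def rf_score(self) -> pd.Series:
        return self.table["rf_score"]

    @property
    def loo_score(self) -> pd.Series:
        return self.table["loo_score"]

    def effective_score(self) -> pd.Series:
        """Scores with training positives represented by their LOO score."""
        s = self.table["rf_score"].copy()
        pos = self.table.index[self.table["is_training"] == "positive"]
        s.loc[pos] = self.table.loc[pos, "loo_score"]
        return s


@dataclass
class QcReport:
    auc: float
    top10_training_count: int

    @property
    def passed(self) -> bool:
        return self.auc >= AUC_THRESHOLD and self.top10_training_count >= TOP10_MIN_TRAINING

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "top10_training_count": self.top10_training_count,
            "pass": self.passed,
        }


# ---------------------------------------------------------------------------
# Training assembly
# ---------------------------------------------------------------------------

def assemble_training(
    seed: SeedGroup,
    m: RatioMatrix,
    n_negatives: int = 1000,
    n_trees: int = 500,
    min_train_features: int = 45,
    min_test_features: int = 30,
    rng_seed: int = 0,
) -> TrainingConfig:
    """Positive class = eligible seed members; negatives drawn at random.

    Negatives are sampled uniformly without replacement from eligible
    non-seed proteins; a pool smaller than ``n_negatives`` is used in
    full with a warning.
    """
    counts = m.feature_counts
    positives = sorted(p for p in seed.members if p in counts.index
                       and counts[p] >= min_train_features)
    dropped = sorted(set(seed.members) - set(positives))
    if len(positives) < 4:
        raise SeedIneligibleError(
            f"seed {seed.name!r}: only {len(positives)} members have >= "
            f"{min_train_features} features (dropped: {dropped})"
        )
    if dropped:
        logger.info("seed %s: dropped below-threshold members %s", seed.name, dropped)
    pool = sorted(eligible_proteins(m, min_train_features) - set(seed.members))
    rng = np.random.default_rng(rng_seed)
    if len(pool) <= n_negatives:
        logger.warning(
            "negative pool (%d) smaller than requested %d; using all",
            len(pool), n_negatives,
        )
        negatives = list(pool)
    else:
        negatives = sorted(rng.choice(pool, size=n_negatives, replace=False))
    return TrainingConfig(
        seed_name=seed.name,
        positives=positives,
        negatives=negatives,
        n_trees=n_trees,
        min_train_features=min_train_features,
        min_test_features=min_test_features,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Ensemble scoring
# ---------------------------------------------------------------------------

def _negative_chunks(negatives: list[str], n_pos: int, n_models: int,
                     rng: np.random.Generator) -> list[list[str]]:
    """Cycle the negative pool without replacement; reshuffle on exhaustion."""
    chunks: list[list[str]] = []
    stream: list[str] = []
    while len(chunks) < n_models:
        if len(stream) < n_pos:
            fresh = list(rng.permutation(negatives))
            # avoid duplicates within the chunk spanning the reshuffle
            fresh = [x for x in fresh if x not in stream] + \
                    [x for x in fresh if x in stream]
            stream = stream + fresh
        chunks.append(stream[:n_pos])
        stream = stream[n_pos:]
    return chunks


def _score_models(
    values: np.ndarray,
    row_index: dict[str, int],
    positives: list[str],
    chunks: list[list[str]],
    test_rows: np.ndarray,
    n_trees: int,
    model_seeds: np.ndarray,
) -> np.ndarray:
    """Mean tree-vote fraction over balanced models for the test rows.

    Missing values are median-imputed per feature from each model's own
    training rows; the imputation is frozen and reused for scoring.
    """
    n_feat = values.shape[1]
    mtry = max(1, int(math.sqrt(n_feat)))
    pos_rows = np.array([row_index[p] for p in positives])
    acc = np.zeros(len(test_rows))
    for chunk, seed in zip(chunks, model_seeds):
        neg_rows = np.array([row_index[p] for p in chunk])
        tr_rows = np.concatenate([pos_rows, neg_rows])
        X_tr = values[tr_rows]
        with warnings.catch_warnings():
            # features unobserved across a model's training rows fall back to 0
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(X_tr, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        X_tr = np.where(np.isnan(X_tr), med, X_tr)
        y_tr = np.concatenate([np.ones(len(pos_rows)), np.zeros(len(neg_rows))])
        X_te = values[test_rows]
        X_te = np.where(np.isnan(X_te), med, X_te)
        acc += forest_votes(X_tr, y_tr, X_te, n_trees, mtry, int(seed))
    return acc / len(chunks)


def ensemble_scores(m: RatioMatrix, t: TrainingConfig) -> ProgulonScores:
    """RF score for every protein with enough test features.

    ceil(|negatives| / n_pos) balanced models are trained so that every
    pool negative is used about once; each model is a forest of
    ``n_trees`` unlimited-depth trees.  Proteins below
    ``min_test_features`` are excluded with a recorded reason, not
    scored 0.
    """
    counts = m.feature_counts
    scoreable = [p for p in m.protein_ids if counts[p] >= t.min_test_features]
    excluded = {p: f"feature_count {counts[p]} < {t.min_test_features}"
                for p in m.protein_ids if p not in set(scoreable)}
    values = m.values.to_numpy(dtype=float)
    row_index = {p: i for i, p in enumerate(m.protein_ids)}
    rng = np.random.default_rng(t.rng_seed)
    chunks = _negative_chunks(t.negatives, t.n_pos, t.n_models, rng)
    model_seeds = rng.integers(0, 2**31 - 1, size=len(chunks))
    test_rows = np.array([row_index[p] for p in scoreable])
    scores = _score_models(values, row_index, t.positives, chunks,
                           test_rows, t.n_trees, model_seeds)
    table = pd.DataFrame(index=pd.Index(scoreable, name="protein_id"))
    table["rf_score"] = scores
    table["is_training"] = "none"
    table.loc[[p for p in t.positives if p in table.index], "is_training"] = "positive"
    table.loc[[p for p in t.negatives if p in table.index], "is_training"] = "negative"
    table["loo_score"] = np.nan
    table["feature_count"] = counts.reindex(table.index)
    return ProgulonScores(table=table, n_models=len(chunks), excluded=excluded)


def loo_cross_validate(m: RatioMatrix, t: TrainingConfig,
                       scores: ProgulonScores) -> ProgulonScores:
    """Leave-one-out score per positive.

    For each seed protein the full balanced ensemble is retrained with
    that protein removed from the positive class (same negative pool,
    same rng stream per fold) and the held-out protein is scored by the
    retrained ensemble.  Other proteins keep their ensemble scores.
    """
    if t.n_pos < 4:
        raise ValidationError("leave-one-out requires >= 4 positives")
    values = m.values.to_numpy(dtype=float)
    row_index = {p: i for i, p in enumerate(m.protein_ids)}
    for q in t.positives:
        fold_pos = [p for p in t.positives if p != q]
        n_models = math.ceil(len(t.negatives) / len(fold_pos))
        rng = np.random.default_rng(t.rng_seed)
        chunks = _negative_chunks(t.negatives, len(fold_pos), n_models, rng)
        model_seeds = rng.integers(0, 2**31 - 1, size=len(chunks))
        votes = _score_models(values, row_index, fold_pos, chunks,
                              np.array([row_index[q]]), t.n_trees, model_seeds)
        scores.table.loc[q, "loo_score"] = votes[0]
    return scores


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_check(scores: ProgulonScores, t: TrainingConfig) -> QcReport:
    """QC gates on cross-validated training data.

    AUC: LOO scores of the positives against the ensemble scores of the
    negative training proteins.  Top-10 rule: among the 10 highest
    scoring proteins overall (positives represented by LOO score), at
    least 4 must be cross-validated training positives.
    """
    table = scores.table
    pos_mask = table["is_training"] == "positive"
    loo = table.loc[pos_mask, "loo_score"]
    if loo.isna().any():
        raise ValidationError("run loo_cross_validate before qc_check")
    neg = table.loc[table["is_training"] == "negative", "rf_score"]
    y = np.concatenate([np.ones(len(loo)), np.zeros(len(neg))])
    s = np.concatenate([loo.to_numpy(), neg.to_numpy()])
    auc = float(roc_auc_score(y, s))
    eff = scores.effective_score()
    top10 = eff.sort_values(ascending=False, kind="mergesort").index[:10]
    count = int(pos_mask.reindex(top10, fill_value=False).sum())
    return QcReport(auc=auc, top10_training_count=count)
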