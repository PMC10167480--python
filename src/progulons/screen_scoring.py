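"""Scoring of high-content siRNA validation screens.

Candidate genes are knocked down with three independent siRNAs each and
phenotyped across readouts grouped into three processes: DNA replication
(EdU incorporation and RPA loading, with or without replication stress),
DNA damage (53BP1, gamma-H2A.X) and cell-cycle distribution (G1/S/G2M
fractions under four experimental conditions).  Wells are normalised to
the negative-control median of their plate; per-readout hit thresholds
are tiered by assay variability (3x SD for SD <= 0.05, 2x SD for
0.05 < SD <= 0.13, 1x SD for SD > 0.13); a gene is a hit in a readout
when at least two of its three siRNAs deviate beyond the threshold in
the same direction.  Hits accumulate into a validation score capped at
5 (replication) + 4 (DNA damage) + 4 (cell cycle, one point per
condition) = 13, tiered into high (> 1/2 max), medium (> 1/3 max) and
unvalidated confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .data_io import ProgulonError, ValidationError

logger = logging.getLogger(__name__)

MAX_SCORE = 13
PROCESS_CAPS = {"replication": 5, "dna_damage": 4, "cell_cycle": 4}

#: Default readout catalog of the validation screen: readout -> process.
DEFAULT_READOUT_CATALOG: dict[str, str] = {
    "EdU": "replication",
    "EdU_Aph": "replication",
    "RPA": "replication",
    "RPA_HU": "replication",
    "RPA_Aph": "replication",
    "53BP1": "dna_damage",
    "gH2AX": "dna_damage",
    "gH2AX_HU": "dna_damage",
    "gH2AX_Aph": "dna_damage",
    # cell-cycle phase fractions, scored per experimental condition
    "CC_G1": "cell_cycle",
    "CC_S": "cell_cycle",
    "CC_G2M": "cell_cycle",
}

#: The four cell-cycle experimental conditions (one point each at most).
DEFAULT_CONDITIONS = ["EdU_untreated", "PCNA_untreated", "PCNA_HU", "EdU_Aph"]


class Confidence(str, Enum):
    high = "high"
    medium = "medium"
    unvalidated = "unvalidated"


@dataclass
class ScreenDataset:
    """Long-format well table with control labels and a readout catalog.

    ``wells`` columns: plate, well, sirna, gene, readout, condition,
    replicate, value, is_negative_control.  ``condition`` is only
    meaningful for cell-cycle readouts and may be empty elsewhere.
    """

    wells: pd.DataFrame
    readout_catalog: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_READOUT_CATALOG))
    conditions: list[str] = field(default_factory=lambda: list(DEFAULT_CONDITIONS))

    REQUIRED = ["plate", "well", "sirna", "gene", "readout", "condition",
                "replicate", "value", "is_negative_control"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.wells.columns]
        if missing:
            raise ValidationError(f"screen table lacks columns: {missing}")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "ScreenDataset":
        wells = pd.read_csv(path, sep="\t")
        wells["is_negative_control"] = wells["is_negative_control"].astype(bool)
        return cls(wells=wells, **kwargs)


# ---------------------------------------------------------------------------
# Plate normalisation
# ---------------------------------------------------------------------------

def normalize_plates(s: ScreenDataset) -> pd.DataFrame:
    """Subtract the plate's negative-control median, per readout/replicate.

    The custom library is biased towards real phenotypes, so plates are
    centred on their negative controls rather than the plate median.
    """
    wells = s.wells.reset_index(drop=True).copy()
    normalized = np.empty(len(wells))
    for (plate, readout, replicate), grp in wells.groupby(
            ["plate", "readout", "replicate"], sort=False):
        ctrl = grp.loc[grp["is_negative_control"], "value"]
        if len(ctrl) < 2:
            raise ProgulonError(
                f"plate {plate!r} (readout {readout!r}, replicate {replicate!r}) "
                f"has {len(ctrl)} negative-control wells; >= 2 required"
            )
        normalized[grp.index.to_numpy()] = grp["value"] - ctrl.median()
    wells["normalized"] = normalized
    return wells


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

def _combine_replicates(wells: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Replicate-combined normalised activity per siRNA and readout."""
    agg = {"mean": "mean", "median": "median"}[how]
    keys = ["gene", "sirna", "readout", "condition", "is_negative_control"]
    return (wells.groupby(keys, sort=False, dropna=False)["normalized"]
            .agg(agg).reset_index())


def threshold_multiplier(sd: float) -> float:
    """Variability tier: 3x for SD <= 0.05, 2x for SD <= 0.13, else 1x."""
    if sd <= 0.05:
        return 3.0
    if sd <= 0.13:
        return 2.0
    return 1.0


def readout_threshold(neg_control_values: np.ndarray) -> float:
    """Tiered hit threshold from normalised negative-control variability."""
    vals = np.asarray(neg_control_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 3:
        raise ValueError("need >= 3 negative-control values")
    sd = float(np.std(vals, ddof=1))
    if sd < 1e-12:
        logger.warning("negative-control SD is 0; threshold 0")
        return 0.0
    return threshold_multiplier(sd) * sd


def readout_thresholds(wells: pd.DataFrame) -> pd.Series:
    """Per-(readout, condition) thresholds from control-well variability.

    The SD is taken over the normalised negative-control *wells* across
    all plates and replicates of a readout, before any replicate
    combination.
    """
    ctrl = wells[wells["is_negative_control"]]
    out = {}
    for (readout, condition), grp in ctrl.groupby(["readout", "condition"],
                                                  dropna=False):
        out[(readout, condition)] = readout_threshold(grp["normalized"].to_numpy())
    return pd.Series(out, name="threshold")


# ---------------------------------------------------------------------------
# Hit calling and cumulative score
# ---------------------------------------------------------------------------

def call_gene_hits(
    s: ScreenDataset,
    combine: str = "mean",
) -> pd.DataFrame:
    """Per-gene, per-readout(-condition) hit flags by the 2-of-3 rule.

    A gene scores a readout when >= 2 of its 3 siRNAs deviate beyond the
    threshold in the same direction; up- and downregulation both count
    but a readout contributes at most one hit.
    """
    wells = normalize_plates(s)
    thresholds = readout_thresholds(wells)
    combined = _combine_replicates(wells, combine)
    cand = combined[~combined["is_negative_control"]]
    rows = []
    for (gene, readout, condition), grp in cand.groupby(
            ["gene", "readout", "condition"], dropna=False, sort=False):
        if grp["sirna"].nunique() != 3:
            raise ValidationError(
                f"gene {gene!r} has {grp['sirna'].nunique()} siRNAs in readout "
                f"{readout!r}; exactly 3 required"
            )
        thr = thresholds[(readout, condition)]
        vals = grp.groupby("sirna")["normalized"].first().to_numpy()
        n_up = int(np.sum(vals > thr))
        n_down = int(np.sum(vals < -thr))
        hit = n_up >= 2 or n_down >= 2
        rows.append((gene, readout, condition, hit,
                     "up" if n_up >= 2 else ("down" if n_down >= 2 else "")))
    return pd.DataFrame(rows, columns=["gene", "readout", "condition", "hit",
                                       "direction"])


@dataclass
class GeneScoreCard:
    gene: str
    replication: int
    dna_damage: int
    cell_cycle: int

    def __post_init__(self) -> None:
        for proc in PROCESS_CAPS:
            if getattr(self, proc) > PROCESS_CAPS[proc]:
                raise ValidationError(
                    f"{proc} subtotal {getattr(self, proc)} exceeds cap "
                    f"{PROCESS_CAPS[proc]}")

    @property
    def cumulative(self) -> int:
        return self.replication + self.dna_damage + self.cell_cycle

    @property
    def confidence(self) -> Confidence:
        if self.cumulative > MAX_SCORE / 2:
            return Confidence.high
        if self.cumulative > MAX_SCORE / 3:
            return Confidence.medium
        return Confidence.unvalidated

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "replication": self.replication,
            "dna_damage": self.dna_damage,
            "cell_cycle": self.cell_cycle,
            "cumulative": self.cumulative,
            "confidence": self.confidence.value,
        }


def cumulative_score(
    flags: pd.DataFrame,
    readout_catalog: dict[str, str] | None = None,
) -> list[GeneScoreCard]:
    """Capped cumulative validation score per gene.

    Replication and DNA-damage readouts contribute one point per hit;
    cell-cycle hits contribute at most one point per experimental
    condition (phase shifts within one condition are not independent).
    """
    catalog = readout_catalog or DEFAULT_READOUT_CATALOG
    unknown = set(flags["readout"]) - set(catalog)
    if unknown:
        raise ValidationError(f"readouts missing from catalog: {sorted(unknown)}")
    cards = []
    for gene, grp in flags.groupby("gene", sort=True):
        proc = grp["readout"].map(catalog)
        repl = int(grp.loc[(proc == "replication") & grp["hit"], "readout"].nunique())
        dam = int(grp.loc[(proc == "dna_damage") & grp["hit"], "readout"].nunique())
        cc = grp[(proc == "cell_cycle") & grp["hit"]]
        cc_points = int(cc["condition"].nunique())
        cards.append(GeneScoreCard(
            gene=gene,
            replication=min(repl, PROCESS_CAPS["replication"]),
            dna_damage=min(dam, PROCESS_CAPS["dna_damage"]),
            cell_cycle=min(cc_points, PROCESS_CAPS["cell_cycle"]),
        ))
    return cards


def score_screen(s: ScreenDataset, combine: str = "mean") -> pd.DataFrame:
    """End-to-end screen scoring: normalise, threshold, call, accumulate."""
    flags = call_gene_hits(s, combine=combine)
    cards = cumulative_score(flags, s.readout_catalog)
    return pd.DataFrame([c.to_dict() for c in cards]).set_index("gene")
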