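"""Input/output for ratio matrices, seed lists and annotation sets.

The substrate of progulon discovery is a protein x experiment matrix of
log2 expression ratios (SILAC-style), with missing values wherever a
protein was not quantified in an experiment.  Every quantified ratio is
one "feature" of that protein; eligibility filters operate on the number
of features, re-derived from whichever (possibly column-subset) matrix is
actually passed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_SEED_SIZE = 4


class ProgulonError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(ProgulonError):
    pass


class ParseError(ProgulonError):
    pass


class SeedTooSmallError(ValidationError):
    pass


class Provenance(str, Enum):
    clustering = "clustering"
    user = "user"


@dataclass
class RatioMatrix:
    """Protein x experiment log-ratio matrix with explicit missingness.

    ``values`` is a float DataFrame indexed by protein ID with experiment
    IDs as columns; missing ratios are NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate protein ID: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate experiment ID: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError("non-finite ratio values present")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]

    @property
    def feature_counts(self) -> pd.Series:
        """Number of non-missing ratios per protein."""
        return self.values.notna().sum(axis=1)

    def subset_experiments(self, experiment_ids: Sequence[str]) -> "RatioMatrix":
        """Column subset; feature counts are re-derived downstream."""
        missing = [e for e in experiment_ids if e not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown experiment IDs: {missing}")
        return RatioMatrix(self.values.loc[:, list(experiment_ids)].copy())


@dataclass
class SeedGroup:
    """A small, tightly co-regulated protein set used as positive class."""

    name: str
    members: frozenset[str]
    provenance: Provenance = Provenance.user

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if len(self.members) < MIN_SEED_SIZE:
            raise SeedTooSmallError(
                f"seed {self.name!r} has {len(self.members)} members; "
                f"at least {MIN_SEED_SIZE} required"
            )


@dataclass
class AnnotationCollection:
    """Named protein sets (e.g. pathways) plus the annotation universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    unmapped: frozenset[str] = frozenset()

    @classmethod
    def from_sets(
        cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str]
    ) -> "AnnotationCollection":
        uni = frozenset(universe)
        clean: dict[str, frozenset[str]] = {}
        unmapped: set[str] = set()
        for name, members in sets.items():
            mem = frozenset(members)
            unmapped |= mem - uni
            clean[name] = mem
        return cls(sets=clean, universe=uni, unmapped=frozenset(unmapped))


# ---------------------------------------------------------------------------
# Ratio matrix I/O
# ---------------------------------------------------------------------------

_NA_VALUES = ["", "NA", "NaN", "nan"]


def read_ratio_matrix(path: str | Path, dialect: str = "tsv") -> RatioMatrix:
    """Read a ratio matrix; first column = protein IDs, header = experiments.

    Empty cells and "NA" are treated as missing.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, na_values=_NA_VALUES,
            keep_default_na=False, dtype=str,
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no experiment columns found (malformed header?)")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric ratio value: {exc}") from exc
    values.index = values.index.astype(str)
    return RatioMatrix(values)


def write_ratio_matrix(m: RatioMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a matrix; missing values become empty cells."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    m.values.to_csv(path, sep=sep, na_rep="", index_label="protein_id")


def read_seed_list(path: str | Path) -> list[str]:
    """Plain-text seed list, one protein ID per line; blanks ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# GMT / GMX annotation I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationCollection:
    """Read GMT: one set per line as ``name<TAB>description<TAB>member...``."""
    sets: dict[str, frozenset[str]] = {}
    members_all: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, members")
            name = parts[0]
            members = frozenset(p for p in parts[2:] if p)
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            members_all |= members
    uni = frozenset(universe) if universe is not None else frozenset(members_all)
    return AnnotationCollection.from_sets(sets, uni)


def write_gmt(
    sets: Mapping[str, Iterable[str]], path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_gmx(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Column-oriented GMX export (one set per column)."""
    names = list(sets)
    cols = {n: [ (descriptions or {}).get(n, "na"), *sorted(sets[n]) ] for n in names}
    depth = max((len(c) for c in cols.values()), default=0)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(names) + "\n")
        for i in range(depth):
            fh.write("\t".join(cols[n][i] if i < len(cols[n]) else "" for n in names) + "\n")


# ---------------------------------------------------------------------------
# Eligibility and seed mapping
# ---------------------------------------------------------------------------

def eligible_proteins(m: RatioMatrix, min_features: int) -> frozenset[str]:
    """Proteins with at least ``min_features`` quantified ratios.

    Evaluated on the matrix actually passed, so column-subset runs
    (e.g. a 15-experiment subset with relaxed minima) re-derive counts.
    """
    if min_features < 1:
        raise ValueError("min_features must be >= 1")
    counts = m.feature_counts
    return frozenset(counts.index[counts >= min_features])


def map_seed_ids(
    user_ids: Sequence[str],
    m: RatioMatrix,
    synonym_table: Mapping[str, str] | None = None,
    name: str = "user_seed",
) -> tuple[SeedGroup, list[str]]:
    """Map user-supplied IDs onto matrix rows.

    Matching order is exact -> synonym table -> case-insensitive; every
    input ID ends up either in the seed or in the unmatched report.
    """
    if not user_ids:
        raise ValueError("user_ids is empty")
    known = set(m.protein_ids)
    lower_map: dict[str, str] = {}
    for pid in m.protein_ids:
        lower_map.setdefault(pid.lower(), pid)
    synonyms = {str(k): str(v) for k, v in (synonym_table or {}).items()}

    matched: set[str] = set()
    unmatched: list[str] = []
    for uid in user_ids:
        if uid in known:
            matched.add(uid)
        elif uid in synonyms and synonyms[uid] in known:
            matched.add(synonyms[uid])
            logger.info("seed ID %r mapped via synonym to %r", uid, synonyms[uid])
        elif uid.lower() in lower_map:
            matched.add(lower_map[uid.lower()])
            logger.info("seed ID %r matched case-insensitively to %r", uid, lower_map[uid.lower()])
        else:
            unmatched.append(uid)
    if len(matched) < MIN_SEED_SIZE:
        raise SeedTooSmallError(
            f"only {len(matched)} of {len(user_ids)} seed IDs matched the matrix "
            f"(minimum {MIN_SEED_SIZE}); unmatched: {unmatched}"
        )
    return SeedGroup(name=name, members=frozenset(matched), provenance=Provenance.user), unmatched
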