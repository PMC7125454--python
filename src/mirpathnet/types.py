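"""Core in-memory containers shared across the pipeline.

The pipeline works on three kinds of input — raw count matrices with a
tumor/control label per sample, a named gene-set (pathway) collection, and
a validated miRNA->target interaction table — plus the derived result
containers produced by each stage.  All containers are thin, validated
wrappers over pandas structures so that every stage can round-trip through
plain TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TUMOR = "tumor"
CONTROL = "control"
CONDITIONS = (TUMOR, CONTROL)


class FormatError(ValueError):
    """Structured parse/validation error for pipeline inputs."""


@dataclass
class CountMatrix:
    """Integer feature x sample expression counts with condition labels.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows = feature ids,
        columns = sample ids.  Row/column order is preserved throughout.
    condition
        Series indexed by sample id with values ``"tumor"`` / ``"control"``.
    """

    counts: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise FormatError("negative count")
        missing = self.counts.columns.difference(self.condition.index)
        if len(missing):
            raise FormatError(f"samples missing a condition label: {list(missing)}")
        self.condition = self.condition.reindex(self.counts.columns)
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition labels: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])

    def require_two_per_condition(self) -> None:
        for cond in CONDITIONS:
            if len(self.samples_of(cond)) < 2:
                raise FormatError(
                    f"need at least 2 samples per condition, found "
                    f"{len(self.samples_of(cond))} for {cond!r}"
                )

    def subset_features(self, ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(ids)], self.condition.copy())


@dataclass
class GeneSetCollection:
    """Named pathways -> member gene ids (GMT-style).

    Member lists are deduplicated preserving first occurrence; empty sets
    are rejected.  Insertion order of pathways is preserved.
    """

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for pid, members in self.sets.items():
            seen: dict[str, None] = dict.fromkeys(members)
            if not seen:
                raise FormatError(f"pathway {pid!r} has no members")
            clean[pid] = tuple(seen)
        self.sets = clean
        for pid in self.sets:
            self.descriptions.setdefault(pid, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, pid: str) -> bool:
        return pid in self.sets

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return {k: set(v) for k, v in self.sets.items()} == {
            k: set(v) for k, v in other.sets.items()
        }

    def members(self, pid: str) -> frozenset[str]:
        return frozenset(self.sets[pid])

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sets)


@dataclass
class MiRNATargetTable:
    """Validated miRNA -> target-gene interactions.

    ``table`` has columns ``mirna``, ``target`` and optionally ``source``;
    rows are deduplicated on (mirna, target) and the number of dropped
    duplicates is recorded.
    """

    table: pd.DataFrame
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        required = {"mirna", "target"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"interaction table missing columns: {sorted(missing)}")
        tab = self.table.copy()
        for col in ("mirna", "target"):
            tab[col] = tab[col].astype(str)
            if tab[col].str.len().eq(0).any():
                raise FormatError(f"empty id in column {col!r}")
        before = len(tab)
        tab = tab.drop_duplicates(subset=["mirna", "target"], keep="first")
        self.n_duplicates_dropped += before - len(tab)
        self.table = tab.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["mirna"], self.table["target"]))

    def targets_of(self, mirna: str) -> set[str]:
        return set(self.table.loc[self.table["mirna"] == mirna, "target"])


@dataclass
class RiskGeneResult:
    """Risk genes: DE genes that are validated targets of DE miRNAs."""

    pairs: list[tuple[str, str]]  # (miRNA id, risk gene id), deduplicated
    n_de_mirnas_with_targets: int
    n_targets_of_de_mirnas: int

    @property
    def risk_gene_ids(self) -> set[str]:
        return {g for _, g in self.pairs}

    @property
    def mirna_ids(self) -> set[str]:
        return {m for m, _ in self.pairs}


def make_condition_series(label_map: Mapping[str, str]) -> pd.Series:
    return pd.Series(dict(label_map), dtype=object)


def significant_features(de_table: pd.DataFrame) -> list[str]:
    """Feature ids flagged significant (direction up or down) in a DE table."""
    mask = de_table["direction"] != "ns"
    return list(de_table.loc[mask, "feature"])
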