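"""Ranked lineages and rank-level agreement.

Lineages follow a fixed eight-level schema from strain up to
superkingdom. Any rank may carry the reserved token ``UNKNOWN`` —
uncultured or unclassified taxa legitimately have lineage gaps, and those
gaps are propagated as *indeterminate* comparisons rather than being
counted as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "RANKS",
    "UNKNOWN",
    "Lineage",
    "TaxonomyTable",
    "load_taxonomy",
    "lineage_at_rank",
    "agree_at_rank",
    "TaxonomyFormatError",
    "DuplicateTaxonError",
    "UnknownTaxonError",
]

#: Fixed rank schema, finest first.
RANKS = (
    "strain",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
)

#: Reserved token for a lineage gap.
UNKNOWN = "UNKNOWN"


class TaxonomyFormatError(ValueError):
    pass


class DuplicateTaxonError(ValueError):
    pass


class UnknownTaxonError(KeyError):
    pass


@dataclass(frozen=True)
class Lineage:
    """Ordered rank labels for one taxon; missing ranks hold ``UNKNOWN``."""

    labels: tuple = field(default_factory=lambda: (UNKNOWN,) * len(RANKS))

    def __post_init__(self):
        if len(self.labels) != len(RANKS):
            raise ValueError(
                f"lineage needs {len(RANKS)} labels, got {len(self.labels)}"
            )
        if any(not lab for lab in self.labels):
            raise ValueError("lineage labels must be non-empty (use UNKNOWN)")

    def at_rank(self, rank: str) -> str:
        return self.labels[RANKS.index(rank)]

    @classmethod
    def from_dict(cls, labels: Mapping[str, str]) -> "Lineage":
        return cls(tuple(labels.get(r) or UNKNOWN for r in RANKS))


@dataclass
class TaxonomyTable:
    """taxon_id -> :class:`Lineage`."""

    lineages: dict = field(default_factory=dict)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def lineage(self, taxon_id: str) -> Lineage:
        try:
            return self.lineages[taxon_id]
        except KeyError:
            raise UnknownTaxonError(f"taxon {taxon_id!r} absent from taxonomy") from None

    def add(self, taxon_id: str, lineage: Lineage) -> None:
        if taxon_id in self.lineages:
            raise DuplicateTaxonError(f"duplicate taxon_id {taxon_id!r}")
        self.lineages[taxon_id] = lineage

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon_id": t, **dict(zip(RANKS, lin.labels))}
            for t, lin in self.lineages.items()
        ]
        return pd.DataFrame(rows, columns=["taxon_id", *RANKS])

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_taxonomy(path) -> TaxonomyTable:
    """Read a taxonomy TSV: header ``taxon_id`` + one column per rank.

    Empty cells become ``UNKNOWN``; duplicated taxon_ids are an error.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("taxon_id", *RANKS) if c not in df.columns]
    if missing:
        raise TaxonomyFormatError(f"taxonomy file {path} missing columns: {missing}")
    table = TaxonomyTable()
    for _, row in df.iterrows():
        table.add(row["taxon_id"], Lineage.from_dict({r: row[r] for r in RANKS}))
    return table


def lineage_at_rank(table: TaxonomyTable, taxon_id: str, rank: str) -> str:
    """The stored label at ``rank``, or ``UNKNOWN`` for a lineage gap."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    return table.lineage(taxon_id).at_rank(rank)


def agree_at_rank(table: TaxonomyTable, taxon_a: str, taxon_b: str, rank: str) -> str:
    """``match`` / ``mismatch`` / ``indeterminate`` at one rank.

    ``indeterminate`` whenever either lineage is UNKNOWN at that rank; a
    gap is never scored as disagreement.
    """
    a = lineage_at_rank(table, taxon_a, rank)
    b = lineage_at_rank(table, taxon_b, rank)
    if a == UNKNOWN or b == UNKNOWN:
        return "indeterminate"
    return "match" if a == b else "mismatch"
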