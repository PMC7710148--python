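"""Gene-set collection I/O (GMT) and interaction-based pathway extension.

GMT is the Broad dialect: one set per line, tab-separated ``id``,
``description``, then member identifiers.  Pathway extension adds interaction
partners (at or above a confidence tier) of *original* members — one hop only,
so pathway boundaries stay recognizable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .core import GeneSet, GeneSetCollection
from .errors import ParseError, ValidationError

__all__ = [
    "read_gmt",
    "write_gmt",
    "InteractionTable",
    "read_interactions",
    "extend_with_interactions",
]

_CONFIDENCE_ORDER = {"low": 0, "medium": 1, "high": 2}

# Numeric-score loaders map interaction scores onto the categorical tiers.
# Cutoffs follow common practice for curated interaction scores; both are
# configurable at load time.
MEDIUM_SCORE_CUTOFF = 0.45
HIGH_SCORE_CUTOFF = 0.60


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Members are deduplicated within each set; the collection computes the
    per-gene membership count.  An empty file yields an empty collection.
    """
    sets = []
    seen_ids = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} fields, expected at least 3",
                    line=lineno,
                )
            set_id, desc = fields[0], fields[1]
            if set_id in seen_ids:
                raise ParseError(
                    f"duplicate pathway id {set_id!r}", line=lineno
                )
            seen_ids.add(set_id)
            members = frozenset(m for m in fields[2:] if m)
            sets.append(GeneSet(set_id, desc, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection as GMT; members in lexicographic order.

    ``read_gmt(write_gmt(c))`` reproduces ``c`` exactly.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fields = [s.id, s.name, *sorted(s.members)]
            fh.write("\t".join(fields) + "\n")


@dataclass(frozen=True)
class InteractionTable:
    """Undirected gene-gene interactions with a confidence tier.

    Pairs are canonicalized (sorted) and self-interactions dropped at load.
    """

    pairs: frozenset[tuple[str, str, str]]  # (gene_a, gene_b, confidence)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "InteractionTable":
        pairs = set()
        for a, b, conf in records:
            if a == b:
                continue
            if conf not in _CONFIDENCE_ORDER:
                raise ValidationError(f"unknown confidence label {conf!r}")
            a, b = sorted((a, b))
            pairs.add((a, b, conf))
        return cls(frozenset(pairs))

    def partners(self, min_confidence: str) -> dict[str, frozenset[str]]:
        """gene -> interactors at or above ``min_confidence``."""
        if min_confidence not in ("medium", "high"):
            raise ValidationError(
                f"min_confidence must be 'medium' or 'high', got "
                f"{min_confidence!r}"
            )
        floor = _CONFIDENCE_ORDER[min_confidence]
        adj: dict[str, set[str]] = {}
        for a, b, conf in self.pairs:
            if _CONFIDENCE_ORDER[conf] >= floor:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
        return {g: frozenset(p) for g, p in adj.items()}


def read_interactions(
    path,
    *,
    medium_cutoff: float = MEDIUM_SCORE_CUTOFF,
    high_cutoff: float = HIGH_SCORE_CUTOFF,
) -> InteractionTable:
    """Read an interaction TSV with columns gene_a, gene_b, confidence.

    ``confidence`` may be a categorical tier (low/medium/high) or a numeric
    score, in which case score >= ``high_cutoff`` -> high,
    >= ``medium_cutoff`` -> medium, else low.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b", "confidence"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"interaction table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )

    def tier(value: str) -> str:
        if value in _CONFIDENCE_ORDER:
            return value
        try:
            score = float(value)
        except ValueError:
            raise ValidationError(
                f"confidence {value!r} is neither a tier nor a score"
            ) from None
        if score >= high_cutoff:
            return "high"
        if score >= medium_cutoff:
            return "medium"
        return "low"

    records = [
        (row.gene_a, row.gene_b, tier(row.confidence))
        for row in df.itertuples(index=False)
    ]
    return InteractionTable.from_records(records)


def extend_with_interactions(
    collection: GeneSetCollection,
    interactions: InteractionTable,
    min_confidence: str = "medium",
) -> GeneSetCollection:
    """Extend every set with interaction partners of its original members.

    One hop only: a partner is added if it interacts (at or above
    ``min_confidence``) with a member of the *input* set, so repeated
    application grows sets one interaction hop at a time.  The input
    collection is left unchanged and membership counts are recomputed.
    """
    adj = interactions.partners(min_confidence)
    extended = []
    for s in collection:
        added: set[str] = set()
        for member in s.members:
            added |= adj.get(member, frozenset())
        extended.append(GeneSet(s.id, s.name, s.members | added))
    return GeneSetCollection(extended)
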