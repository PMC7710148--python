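"""Identifier mapping with pathway-level one-to-many resolution.

Cross-species or cross-type identifier conversion is rarely one-to-one.  The
engine resolves one-to-many mappings at the pathway level: a source gene
belongs to a mapped pathway if *any* of its targets is annotated there, and it
is added exactly once even when several of its targets sit in the same
pathway.  This keeps set cardinalities honest — no gene is double-counted
because an identifier system splits it in two.

Two directions are offered:

* :func:`map_collection` rewrites the gene-set collection into the dataset's
  identifier namespace (the default route, where the resolution rule lives);
* :func:`map_dataset_rows` rewrites the dataset's rows into the collection's
  namespace, aggregating rows that share a target.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .core import ExpressionDataset, GeneSet, GeneSetCollection, MappingTable
from .errors import AnalysisError, ParseError

__all__ = [
    "MappingLog",
    "map_collection",
    "map_dataset_rows",
    "read_mapping_table",
    "strip_identifier_versions",
]


@dataclass
class MappingLog:
    """Record of every one-to-many event and every miss."""

    one_to_many: dict[str, frozenset[str]] = field(default_factory=dict)
    unmapped: set[str] = field(default_factory=set)
    dropped_rows: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"{len(self.one_to_many)} one-to-many sources, "
            f"{len(self.unmapped)} unmapped identifiers, "
            f"{len(self.dropped_rows)} dropped rows"
        )


def map_collection(
    collection: GeneSetCollection,
    mapping: MappingTable,
    *,
    source_ids: list[str] | None = None,
) -> tuple[GeneSetCollection, MappingLog]:
    """Rewrite a collection into the source namespace of ``mapping``.

    A source gene ``g`` is a member of mapped set ``S`` iff at least one of
    ``g``'s targets is a member of ``S``; it appears exactly once in ``S``
    no matter how many of its targets do.  ``source_ids`` limits which source
    identifiers are considered (defaults to every source in the table).
    Set membership counts are recomputed on the mapped collection.
    """
    log = MappingLog()
    sources = source_ids if source_ids is not None else list(mapping.entries)
    target_sets: dict[str, frozenset[str]] = {}
    for g in sources:
        targets = mapping.get(g)
        if not targets:
            log.unmapped.add(g)
            continue
        if len(targets) > 1:
            log.one_to_many[g] = targets
        target_sets[g] = targets

    mapped = []
    for s in collection:
        members = frozenset(
            g for g, targets in target_sets.items() if targets & s.members
        )
        mapped.append(GeneSet(s.id, s.name, members))
    return GeneSetCollection(mapped), log


def map_dataset_rows(
    dataset: ExpressionDataset,
    mapping: MappingTable,
    aggregate: str | None = None,
) -> tuple[ExpressionDataset, MappingLog]:
    """Rewrite dataset rows into the target namespace of ``mapping``.

    Rows whose sources share a target are combined with ``aggregate``
    (``sum``, ``mean`` or ``max``; default ``sum`` for discrete data types,
    ``mean`` otherwise — sums preserve count semantics, means preserve
    intensity semantics).  A source with several targets contributes its row
    to each.  Unmapped rows are dropped and logged; an entirely unmapped
    matrix is an error.
    """
    if aggregate is None:
        aggregate = "sum" if dataset.data_type.is_discrete else "mean"
    if aggregate not in ("sum", "mean", "max"):
        raise AnalysisError(f"unknown aggregate {aggregate!r}")

    log = MappingLog()
    rows: list[pd.Series] = []
    row_targets: list[str] = []
    for g in dataset.gene_ids:
        targets = mapping.get(g)
        if not targets:
            log.unmapped.add(g)
            log.dropped_rows.append(g)
            continue
        if len(targets) > 1:
            log.one_to_many[g] = targets
        for t in sorted(targets):
            rows.append(dataset.matrix.loc[g])
            row_targets.append(t)
    if not rows:
        raise AnalysisError(
            f"dataset {dataset.name!r}: no row identifier could be mapped"
        )
    stacked = pd.DataFrame(rows)
    stacked.index = pd.Index(row_targets, name=dataset.matrix.index.name)
    grouped = stacked.groupby(level=0, sort=True)
    combined = getattr(grouped, aggregate)()
    out = ExpressionDataset(
        name=dataset.name,
        matrix=combined,
        data_type=dataset.data_type,
        design=dataset.design,
    )
    return out, log


def read_mapping_table(path) -> MappingTable:
    """Read a two-column TSV (source_id, target_id; header optional).

    Multiple lines per source accumulate into one target set.
    """
    entries: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"mapping line has {len(fields)} fields, expected 2",
                    line=lineno,
                )
            src, tgt = fields
            if lineno == 1 and (src, tgt) == ("source_id", "target_id"):
                continue
            entries.setdefault(src, set()).add(tgt)
    return MappingTable(entries)


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_identifier_versions(ids: list[str]) -> list[str]:
    """Normalization pre-pass removing version suffixes like ``.2``.

    Off by default everywhere; mapping itself is case-sensitive and exact.
    """
    return [_VERSION_SUFFIX.sub("", i) for i in ids]
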