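"""Shared domain types and request validation.

The engine analyses one or more quantitative gene-by-sample matrices
("datasets") against a collection of gene sets.  Each dataset declares one of
five data types; the declared type — not the values themselves — decides which
normalization branch and which single-sample kernel the pipeline applies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DataType",
    "TwoGroupDesign",
    "ExpressionDataset",
    "GeneSet",
    "GeneSetCollection",
    "MappingTable",
    "AnalysisRequest",
    "GeneLevelStats",
    "ValidationReport",
    "validate_request",
]


class DataType(str, Enum):
    """Declared kind of quantitative 'omics data.

    Raw RNA-seq counts and proteomics spectral counts are *discrete* and go
    through the count branch (TMM scaling, log-CPM, precision weights, Poisson
    kernel); the other three types are *continuous* and go through
    between-sample normalization and the Gaussian kernel.
    """

    MICROARRAY_INTENSITY = "microarray_intensity"
    RNASEQ_RAW_COUNTS = "rnaseq_raw_counts"
    RNASEQ_NORM_COUNTS = "rnaseq_norm_counts"
    PROTEOMICS_SPECTRAL_COUNTS = "proteomics_spectral_counts"
    PROTEOMICS_INTENSITY = "proteomics_intensity"

    @property
    def is_discrete(self) -> bool:
        return self in (
            DataType.RNASEQ_RAW_COUNTS,
            DataType.PROTEOMICS_SPECTRAL_COUNTS,
        )

    @property
    def is_count_like(self) -> bool:
        """Types whose values must be non-negative (all counts)."""
        return self in (
            DataType.RNASEQ_RAW_COUNTS,
            DataType.RNASEQ_NORM_COUNTS,
            DataType.PROTEOMICS_SPECTRAL_COUNTS,
        )


@dataclass(frozen=True)
class TwoGroupDesign:
    """Two-group comparison design: ``comparison`` vs ``reference``.

    ``groups`` maps every sample id to its group label.  Extra covariates may
    be attached but only the two-group contrast is fitted.
    """

    comparison_variable: str
    reference_group: str
    comparison_group: str
    groups: Mapping[str, str]
    covariates: pd.DataFrame | None = None

    def group_vector(self, sample_ids: Iterable[str]) -> np.ndarray:
        """0/1 indicator (1 = comparison group) aligned to ``sample_ids``."""
        out = []
        for s in sample_ids:
            g = self.groups.get(s)
            if g == self.comparison_group:
                out.append(1)
            elif g == self.reference_group:
                out.append(0)
            else:
                raise ValidationError(
                    f"sample {s!r} has group {g!r}, expected "
                    f"{self.reference_group!r} or {self.comparison_group!r}"
                )
        return np.asarray(out, dtype=int)

    def problems(self, sample_ids: list[str]) -> list[str]:
        """Design violations for the given samples (empty list = clean)."""
        issues = []
        missing = [s for s in sample_ids if s not in self.groups]
        if missing:
            issues.append(f"samples without group label: {missing[:5]}")
        labels = [self.groups[s] for s in sample_ids if s in self.groups]
        extra = sorted(
            set(labels) - {self.reference_group, self.comparison_group}
        )
        if extra:
            issues.append(f"unknown group labels: {extra}")
        for grp in (self.reference_group, self.comparison_group):
            n = sum(1 for l in labels if l == grp)
            if n < 2:
                issues.append(
                    f"group {grp!r} below minimum size 2 (has {n})"
                )
        return issues


@dataclass
class ExpressionDataset:
    """One quantitative genes-by-samples matrix with its declared data type.

    ``matrix`` rows are gene identifiers, columns are sample identifiers.
    """

    name: str
    matrix: pd.DataFrame
    data_type: DataType
    design: TwoGroupDesign | None = None

    def __post_init__(self):
        if isinstance(self.data_type, str):
            self.data_type = DataType(self.data_type)
        self.matrix = self.matrix.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def check(self) -> list[str]:
        """Structural violations (empty list = invariants hold).

        Negative values in a count-typed matrix are a hard error because no
        downstream branch can interpret them.
        """
        issues = []
        if self.matrix.index.has_duplicates:
            dups = self.matrix.index[self.matrix.index.duplicated()][:5]
            issues.append(f"duplicate gene ids: {list(dups)}")
        if self.matrix.columns.has_duplicates:
            dups = self.matrix.columns[self.matrix.columns.duplicated()][:5]
            issues.append(f"duplicate sample ids: {list(dups)}")
        values = self.matrix.to_numpy()
        if not np.isfinite(values).all():
            issues.append("matrix contains non-finite values")
        if self.data_type.is_count_like and np.isfinite(values).all():
            if (values < 0).any():
                g, s = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"dataset {self.name!r}: negative value "
                    f"{values[g, s]:g} for gene "
                    f"{self.matrix.index[g]!r} in sample "
                    f"{self.matrix.columns[s]!r} in a counts-typed matrix"
                )
        if self.data_type in (
            DataType.RNASEQ_RAW_COUNTS,
            DataType.PROTEOMICS_SPECTRAL_COUNTS,
        ) and np.isfinite(values).all():
            if not np.allclose(values, np.round(values)):
                issues.append(
                    f"{self.data_type.value} matrix contains non-integer values"
                )
        if self.design is not None:
            issues.extend(self.design.problems(self.sample_ids))
        return issues


@dataclass(frozen=True)
class GeneSet:
    id: str
    name: str
    members: frozenset[str]


class GeneSetCollection:
    """Named gene sets plus the per-gene set-membership count.

    The membership count (how many sets a gene belongs to) is the quantity the
    permutation method uses to down-weight promiscuously annotated genes.
    """

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.id in self._sets:
                raise ValidationError(f"duplicate pathway id {s.id!r}")
            self._sets[s.id] = s
        counter: Counter[str] = Counter()
        for s in self._sets.values():
            counter.update(s.members)
        self._membership_count = dict(counter)

    @property
    def sets(self) -> dict[str, GeneSet]:
        return dict(self._sets)

    @property
    def membership_count(self) -> dict[str, int]:
        return dict(self._membership_count)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return {
            (s.id, s.name, s.members) for s in self
        } == {(s.id, s.name, s.members) for s in other}

    def all_members(self) -> frozenset[str]:
        return frozenset(self._membership_count)

    def restrict_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe`` (empty sets retained)."""
        uni = frozenset(universe)
        return GeneSetCollection(
            GeneSet(s.id, s.name, s.members & uni) for s in self
        )


class MappingTable:
    """Source identifier -> non-empty set of target identifiers.

    Lookup of an unknown source is a defined miss (empty set), never an error.
    """

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self._entries: dict[str, frozenset[str]] = {}
        for src, targets in entries.items():
            t = frozenset(targets)
            if not t:
                raise ValidationError(f"source id {src!r} maps to an empty set")
            self._entries[src] = t

    @classmethod
    def identity(cls, ids: Iterable[str]) -> "MappingTable":
        return cls({i: {i} for i in ids})

    @property
    def entries(self) -> dict[str, frozenset[str]]:
        return dict(self._entries)

    def get(self, source: str) -> frozenset[str]:
        return self._entries.get(source, frozenset())

    def __contains__(self, source: str) -> bool:
        return source in self._entries

    def __len__(self) -> int:
        return len(self._entries)


VALID_METHODS = ("camera", "padog", "ssgsea")


@dataclass
class AnalysisRequest:
    """What to run: the method, the datasets and the gene sets.

    ``parameters`` accepts: n_perm, seed, fdr_threshold, kernel (override),
    min_set_size, alpha, use_kernel, normalize_ssgsea, max_unmapped_fraction.
    """

    method: str
    datasets: list[ExpressionDataset]
    gene_sets: "GeneSetCollection"
    parameters: dict = field(default_factory=dict)

    _PARAM_RANGES = {
        "n_perm": (100, 10_000_000),
        "fdr_threshold": (0.0, 1.0),
        "min_set_size": (1, 10_000),
        "alpha": (0.0, 2.0),
        "max_unmapped_fraction": (0.0, 1.0),
    }

    def parameter_problems(self) -> list[str]:
        issues = []
        if self.method not in VALID_METHODS:
            issues.append(
                f"unknown method {self.method!r}; supported methods are "
                + ", ".join(VALID_METHODS)
            )
        for key, (lo, hi) in self._PARAM_RANGES.items():
            if key in self.parameters:
                v = self.parameters[key]
                if not (lo <= v <= hi):
                    issues.append(
                        f"parameter {key}={v!r} outside range [{lo}, {hi}]"
                    )
        kernel = self.parameters.get("kernel")
        if kernel not in (None, "poisson", "gaussian", "none"):
            issues.append(f"unknown kernel {kernel!r}")
        return issues


@dataclass
class GeneLevelStats:
    """Per-gene two-group differential expression result for one dataset.

    ``table`` has one row per analyzed gene with columns ``log2fc``,
    ``t`` (moderated), ``p``, ``sd`` (posterior residual sd), ``df``
    (residual + prior df).  ``residuals`` is the genes-by-samples residual
    matrix of the underlying fit; the competitive test needs it to estimate
    inter-gene correlation.
    """

    table: pd.DataFrame
    residuals: pd.DataFrame
    prior_df: float
    prior_var: float

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class ValidationReport:
    """Per-dataset validation outcome; empty ``violations`` = processable."""

    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    unmapped_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_request(
    request: AnalysisRequest,
    mapping: MappingTable | None = None,
    *,
    max_unmapped_fraction: float = 0.90,
    warn_unmapped_fraction: float = 0.20,
) -> ValidationReport:
    """Validate a request before any analysis stage runs.

    Checks experimental design (two groups of >=2 samples for the comparative
    methods), value/data-type consistency, and — when a mapping table is given
    — the fraction of row identifiers with no mapping target.  A dataset whose
    unmapped fraction exceeds ``max_unmapped_fraction`` is a hard error, as is
    an empty dataset list or a negative value in a counts-typed matrix.  The
    request object itself is never modified.
    """
    if not request.datasets:
        raise ValidationError("request contains no datasets")
    report = ValidationReport()
    report.violations.extend(request.parameter_problems())
    seen = set()
    for ds in request.datasets:
        if ds.name in seen:
            report.violations.append(f"duplicate dataset name {ds.name!r}")
        seen.add(ds.name)
        for issue in ds.check():
            report.violations.append(f"dataset {ds.name!r}: {issue}")
        if request.method in ("camera", "padog") and ds.design is None:
            report.violations.append(
                f"dataset {ds.name!r}: method {request.method!r} requires a "
                "two-group design"
            )
        if ds.matrix.shape[0] == 0 or ds.matrix.shape[1] == 0:
            report.violations.append(f"dataset {ds.name!r}: empty matrix")
        if mapping is not None and ds.matrix.shape[0] > 0:
            unmapped = sum(1 for g in ds.gene_ids if g not in mapping)
            frac = unmapped / len(ds.gene_ids)
            report.unmapped_fraction[ds.name] = frac
            threshold = request.parameters.get(
                "max_unmapped_fraction", max_unmapped_fraction
            )
            if frac > threshold:
                raise ValidationError(
                    f"dataset {ds.name!r}: {frac:.0%} of identifiers have no "
                    f"mapping (limit {threshold:.0%})"
                )
            if frac > warn_unmapped_fraction:
                report.warnings.append(
                    f"dataset {ds.name!r}: {frac:.0%} of identifiers unmapped"
                )
    return report


def _copy_dataset(ds: ExpressionDataset, matrix: pd.DataFrame) -> ExpressionDataset:
    """New dataset sharing name/type/design but with a different matrix."""
    return replace(ds, matrix=matrix)
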