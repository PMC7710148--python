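"""Synthetic data generators with known ground truth.

Every stage of the engine is testable without downloads: these simulators
produce count matrices, gene-set collections, mapping tables and single-cell
data in the exact shapes (and, on request, the exact file formats) the engine
consumes, together with a truth table recording every planted effect.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DataType,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    MappingTable,
    TwoGroupDesign,
)
from .errors import AnalysisError
from .pathway_io import write_gmt
from .sc import ClusterAssignment

__all__ = [
    "simulate_bulk",
    "simulate_gaussian",
    "simulate_sc",
    "simulate_mapping",
    "write_bulk_fixture",
]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _make_design(samples_ref: list[str], samples_cmp: list[str]) -> TwoGroupDesign:
    groups = {s: "low" for s in samples_ref}
    groups.update({s: "high" for s in samples_cmp})
    return TwoGroupDesign(
        comparison_variable="signature",
        reference_group="low",
        comparison_group="high",
        groups=groups,
    )


def _null_sets(
    rng: np.random.Generator,
    genes: list[str],
    n_sets: int,
    set_size: int,
    start: int = 0,
) -> list[GeneSet]:
    return [
        GeneSet(
            f"NULL{start + k:04d}",
            f"random set {start + k}",
            frozenset(rng.choice(genes, size=set_size, replace=False)),
        )
        for k in range(n_sets)
    ]


def simulate_bulk(
    n_genes: int = 2000,
    n_samples_per_group: int = 5,
    spiked_sets: list[tuple[str, int, float]] | None = None,
    n_null_sets: int = 50,
    set_size: int = 20,
    dispersion: float = 0.1,
    seed: int | None = None,
) -> tuple[ExpressionDataset, GeneSetCollection, pd.DataFrame]:
    """Negative-binomial RNA-seq counts with planted pathway effects.

    Baseline abundances are log-normal, library sizes vary 3-fold across
    samples, and gene-wise dispersions are drawn from a log-normal around
    ``dispersion`` — the mean-variance structure the precision-weight step is
    built for.  Members of each spiked set (id, size, log2 effect) are
    shifted by the stated effect in the comparison ("high") group; spiked
    sets are disjoint.  Remaining sets are random null sets.  The truth table
    records every planted effect.
    """
    rng = np.random.default_rng(seed)
    spiked_sets = spiked_sets or []
    total_spiked = sum(size for _, size, _ in spiked_sets)
    if total_spiked > n_genes:
        raise AnalysisError(
            f"spiked sets need {total_spiked} genes but universe has {n_genes}"
        )
    genes = _gene_ids(n_genes)
    n = n_samples_per_group
    samples_ref = [f"S{i:02d}_low" for i in range(n)]
    samples_cmp = [f"S{i:02d}_high" for i in range(n)]
    samples = samples_ref + samples_cmp

    base = rng.lognormal(mean=np.log(150.0), sigma=1.2, size=n_genes)
    lib = rng.uniform(1.0, 3.0, size=2 * n)  # 3-fold library-size range
    phi = rng.lognormal(mean=np.log(dispersion), sigma=0.5, size=n_genes)

    log2_effect = np.zeros(n_genes)
    pool = rng.permutation(n_genes)
    cursor = 0
    sets: list[GeneSet] = []
    truth_rows = []
    for set_id, size, effect in spiked_sets:
        idx = pool[cursor : cursor + size]
        cursor += size
        members = frozenset(genes[i] for i in idx)
        log2_effect[idx] = effect
        sets.append(GeneSet(set_id, f"spiked set {set_id}", members))
        truth_rows.append(
            {"set_id": set_id, "log2_effect": effect, "n_members": size}
        )
    sets.extend(_null_sets(rng, genes, n_null_sets, set_size))

    mu = base[:, None] * lib[None, :]
    shift = np.ones((n_genes, 2 * n))
    shift[:, n:] = 2.0 ** log2_effect[:, None]
    mu = mu * shift
    r = 1.0 / phi[:, None]
    counts = rng.negative_binomial(r, r / (r + mu))
    matrix = pd.DataFrame(counts.astype(float), index=genes, columns=samples)
    dataset = ExpressionDataset(
        name="bulk_sim",
        matrix=matrix,
        data_type=DataType.RNASEQ_RAW_COUNTS,
        design=_make_design(samples_ref, samples_cmp),
    )
    truth = pd.DataFrame(
        truth_rows, columns=["set_id", "log2_effect", "n_members"]
    )
    return dataset, GeneSetCollection(sets), truth


def simulate_gaussian(
    n_genes: int = 2000,
    n_samples_per_group: int = 5,
    spiked_sets: list[tuple[str, int, float]] | None = None,
    n_null_sets: int = 200,
    set_size: int = 20,
    seed: int | None = None,
) -> tuple[ExpressionDataset, GeneSetCollection, pd.DataFrame]:
    """Independent N(0,1) genes with planted mean shifts, continuous type.

    The simplest calibration surface for the comparative tests: every gene is
    standard normal, so a planted shift of 1.0 is exactly a one-sd effect and
    the null sets are genuinely independent.  Declared as microarray
    intensities (already on a symmetric continuous scale), so the continuous
    branch applies.
    """
    rng = np.random.default_rng(seed)
    spiked_sets = spiked_sets or []
    total_spiked = sum(size for _, size, _ in spiked_sets)
    if total_spiked > n_genes:
        raise AnalysisError("spiked sets exceed the gene universe")
    genes = _gene_ids(n_genes)
    n = n_samples_per_group
    samples_ref = [f"S{i:02d}_low" for i in range(n)]
    samples_cmp = [f"S{i:02d}_high" for i in range(n)]

    X = rng.standard_normal((n_genes, 2 * n))
    pool = rng.permutation(n_genes)
    cursor = 0
    sets: list[GeneSet] = []
    truth_rows = []
    for set_id, size, shift in spiked_sets:
        idx = pool[cursor : cursor + size]
        cursor += size
        X[np.ix_(idx, np.arange(n, 2 * n))] += shift
        sets.append(
            GeneSet(set_id, f"spiked set {set_id}", frozenset(genes[i] for i in idx))
        )
        truth_rows.append(
            {"set_id": set_id, "log2_effect": shift, "n_members": size}
        )
    sets.extend(_null_sets(rng, genes, n_null_sets, set_size))
    matrix = pd.DataFrame(X, index=genes, columns=samples_ref + samples_cmp)
    dataset = ExpressionDataset(
        name="gaussian_sim",
        matrix=matrix,
        data_type=DataType.MICROARRAY_INTENSITY,
        design=_make_design(samples_ref, samples_cmp),
    )
    truth = pd.DataFrame(
        truth_rows, columns=["set_id", "log2_effect", "n_members"]
    )
    return dataset, GeneSetCollection(sets), truth


def simulate_sc(
    n_genes: int = 500,
    clusters: list[tuple[str, int, str | None]] | None = None,
    base_rate: float = 1.0,
    elevation: float = 5.0,
    set_size: int = 20,
    n_null_sets: int = 10,
    seed: int | None = None,
) -> tuple[pd.DataFrame, ClusterAssignment, GeneSetCollection, pd.DataFrame]:
    """Poisson single-cell counts with one optionally active pathway per cluster.

    ``clusters`` is a list of (label, n_cells, active set id or None); members
    of a cluster's active set have their Poisson rate multiplied by
    ``elevation`` (default 5) in that cluster's cells.  Returns the
    genes-by-cells matrix, the cell-to-cluster assignment, the collection
    (active sets plus random null sets) and the truth table naming the active
    pathway per cluster.
    """
    if clusters is None:
        # default: a scaled-down many-cluster fixture (real scRNA-seq cell
        # typings commonly yield on the order of ten clusters)
        clusters = [(f"c{i}", 30, f"ACTIVE{i}") for i in range(6)]
    if len(clusters) < 2:
        raise AnalysisError("need at least 2 clusters")
    labels = [c[0] for c in clusters]
    if len(set(labels)) != len(labels):
        raise AnalysisError(f"duplicate cluster labels in {labels}")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)

    active_ids = [c[2] for c in clusters if c[2] is not None]
    pool = rng.permutation(n_genes)
    members_of: dict[str, np.ndarray] = {}
    cursor = 0
    sets: list[GeneSet] = []
    for sid in dict.fromkeys(active_ids):  # unique, order-preserving
        idx = pool[cursor : cursor + set_size]
        cursor += set_size
        if idx.size < set_size:
            raise AnalysisError("gene universe too small for the active sets")
        members_of[sid] = idx
        sets.append(
            GeneSet(sid, f"active set {sid}", frozenset(genes[i] for i in idx))
        )
    sets.extend(_null_sets(rng, genes, n_null_sets, set_size))

    cell_ids: list[str] = []
    assignment: dict[str, str] = {}
    cols = []
    truth_rows = []
    base = rng.uniform(0.5, 1.5, size=n_genes) * base_rate
    for label, n_cells, active in clusters:
        rates = base.copy()
        if active is not None:
            rates[members_of[active]] *= elevation
        counts = rng.poisson(rates[:, None], size=(n_genes, n_cells))
        cols.append(counts)
        for k in range(n_cells):
            cid = f"{label}_cell{k:03d}"
            cell_ids.append(cid)
            assignment[cid] = label
        truth_rows.append(
            {"cluster": label, "active_set": active, "n_cells": n_cells}
        )
    matrix = pd.DataFrame(
        np.hstack(cols).astype(float), index=genes, columns=cell_ids
    )
    truth = pd.DataFrame(truth_rows, columns=["cluster", "active_set", "n_cells"])
    return matrix, ClusterAssignment(assignment), GeneSetCollection(sets), truth


def simulate_mapping(
    n_sources: int = 100,
    fanout_distribution: dict[int, float] | None = None,
    seed: int | None = None,
) -> tuple[MappingTable, pd.DataFrame]:
    """Mapping table with a controlled fraction of one-to-many entries.

    ``fanout_distribution`` maps fanout (targets per source, >= 1) to its
    probability; default 80% one-to-one, 20% one-to-two.  Returns the table
    and a summary of the realized fanout counts.
    """
    fanout_distribution = fanout_distribution or {1: 0.8, 2: 0.2}
    fans = sorted(fanout_distribution)
    if min(fans) < 1:
        raise AnalysisError("fanout must be at least 1")
    probs = np.array([fanout_distribution[f] for f in fans], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    entries: dict[str, set[str]] = {}
    counter = 0
    realized: dict[int, int] = {f: 0 for f in fans}
    for i in range(n_sources):
        fan = int(rng.choice(fans, p=probs))
        realized[fan] += 1
        targets = {f"T{counter + k:05d}" for k in range(fan)}
        counter += fan
        entries[f"SRC{i:05d}"] = targets
    summary = pd.DataFrame(
        {"fanout": list(realized), "n_sources": list(realized.values())}
    )
    return MappingTable(entries), summary


def write_bulk_fixture(
    out_dir,
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    method: str = "camera",
    parameters: dict | None = None,
    mapping: MappingTable | None = None,
) -> Path:
    """Write a simulated dataset in the engine's on-disk input formats.

    Produces ``<name>_matrix.tsv``, ``sets.gmt``, optionally ``mapping.tsv``,
    and ``request.json`` referencing them; returns the request path so CLI
    round-trips can start from files alone.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix_file = out / f"{dataset.name}_matrix.tsv"
    m = dataset.matrix.copy()
    m.index.name = "gene_id"
    m.to_csv(matrix_file, sep="\t", float_format="%.6g")
    write_gmt(collection, out / "sets.gmt")
    if mapping is not None:
        with open(out / "mapping.tsv", "w", encoding="utf-8") as fh:
            fh.write("source_id\ttarget_id\n")
            for src in sorted(mapping.entries):
                for tgt in sorted(mapping.entries[src]):
                    fh.write(f"{src}\t{tgt}\n")
    design = dataset.design
    request = {
        "method": method,
        "parameters": parameters or {},
        "datasets": [
            {
                "name": dataset.name,
                "data_type": dataset.data_type.value,
                "matrix_file": matrix_file.name,
                "design": {
                    "comparison_variable": design.comparison_variable,
                    "reference_group": design.reference_group,
                    "comparison_group": design.comparison_group,
                    "samples": dict(design.groups),
                },
            }
        ],
    }
    request_path = out / "request.json"
    request_path.write_text(json.dumps(request, indent=2))
    return request_path
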