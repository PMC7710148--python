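"""Model-object layer: one class to configure an analysis, one for results.

`PathwayAnalysis` plays the role a model class plays in a regression
package: it is constructed from data (datasets + gene sets + optional
mapping), holds the method and its parameters, and `fit()` executes the
pipeline — validate, map, normalize, test, assemble — returning a
`PathwayAnalysisResults` with the estimates, per-gene diagnostics and a
`summary()` table.  The command-line interface is a thin shell over these
two objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as cmp
from .core import (
    AnalysisRequest,
    ExpressionDataset,
    GeneLevelStats,
    GeneSetCollection,
    MappingTable,
    ValidationReport,
    validate_request,
)
from .diffexp import fit_gene_models, pathway_mean_fold_change
from .errors import AnalysisError
from .gsa import PathwayTestResult, camera_test, padog_test, ssgsea_scores
from .id_mapping import map_collection
from .preprocess import dispatch
from .sc import zscore_by_pathway

__all__ = ["PathwayAnalysis", "PathwayAnalysisResults"]


def _derive_seed(master: int | None, stage: int) -> int | None:
    """Deterministic per-stage seed from the single request seed."""
    if master is None:
        return None
    return int(np.random.SeedSequence(master, spawn_key=(stage,)).generate_state(1)[0] % (2**31))


class PathwayAnalysis:
    """Comparative gene set analysis of one or more datasets.

    Parameters
    ----------
    datasets : list of ExpressionDataset
        The matrices to analyze side-by-side.
    gene_sets : GeneSetCollection
        Pathways in the target identifier namespace.
    mapping : MappingTable, optional
        Source-to-target identifier mapping; when given, the collection is
        rewritten into each dataset's namespace with one-to-many mappings
        resolved at the pathway level.  Without it, identifiers are assumed
        to already match.
    method : {'camera', 'padog', 'ssgsea'}
    **parameters
        Method options: ``n_perm``, ``seed``, ``fdr_threshold``,
        ``min_set_size``, ``alpha``, ``kernel``, ``use_kernel``,
        ``normalize_ssgsea``, plus the preprocessing keys accepted by
        :func:`multigsa.preprocess.dispatch` (``filter_counts``,
        ``continuous_method``, ...).
    """

    _DISPATCH_KEYS = (
        "filter_counts",
        "filter_min_value",
        "filter_min_fraction",
        "tmm_trim_m",
        "tmm_trim_a",
        "logcpm_prior",
        "voom_span",
        "continuous_method",
        "continuous_log_transform",
    )

    def __init__(
        self,
        datasets: list[ExpressionDataset],
        gene_sets: GeneSetCollection,
        mapping: MappingTable | None = None,
        method: str = "camera",
        **parameters,
    ):
        self.datasets = list(datasets)
        self.gene_sets = gene_sets
        self.mapping = mapping
        self.method = method
        self.parameters = dict(parameters)

    @classmethod
    def from_request(
        cls, request: AnalysisRequest, mapping: MappingTable | None = None
    ) -> "PathwayAnalysis":
        return cls(
            datasets=request.datasets,
            gene_sets=request.gene_sets,
            mapping=mapping,
            method=request.method,
            **request.parameters,
        )

    def _request(self) -> AnalysisRequest:
        return AnalysisRequest(
            method=self.method,
            datasets=self.datasets,
            gene_sets=self.gene_sets,
            parameters={
                k: v
                for k, v in self.parameters.items()
                if k in AnalysisRequest._PARAM_RANGES or k == "kernel"
            },
        )

    def validate(self) -> ValidationReport:
        return validate_request(self._request(), self.mapping)

    def fit(self, seed: int | None = None) -> "PathwayAnalysisResults":
        """Run the full pipeline and return the results object.

        ``seed`` (or ``parameters['seed']``) governs every stochastic stage;
        per-dataset seeds are derived deterministically from it.
        """
        report = self.validate()
        if not report.ok:
            raise AnalysisError(
                "request failed validation: " + "; ".join(report.violations)
            )
        master_seed = seed if seed is not None else self.parameters.get("seed")
        min_set_size = self.parameters.get("min_set_size", 3)
        fdr_threshold = self.parameters.get("fdr_threshold", 0.1)
        dispatch_kw = {
            k: self.parameters[k]
            for k in self._DISPATCH_KEYS
            if k in self.parameters
        }
        provenance: list[dict] = []
        gene_stats: dict[str, GeneLevelStats] = {}
        tests: dict[str, PathwayTestResult] = {}
        mean_fc: dict[str, pd.Series] = {}
        scores: dict[str, pd.DataFrame] = {}
        mapping_logs: dict[str, str] = {}

        for i, ds in enumerate(self.datasets):
            if self.mapping is not None:
                collection, log = map_collection(
                    self.gene_sets, self.mapping, source_ids=ds.gene_ids
                )
                mapping_logs[ds.name] = log.summary()
            else:
                collection = self.gene_sets
            norm = dispatch(ds, self.method, **dispatch_kw)
            stage_seed = _derive_seed(master_seed, i)
            entry = {
                "dataset": ds.name,
                "data_type": ds.data_type.value,
                "branch": norm.provenance,
                "method": self.method,
                "seed": stage_seed,
            }
            if self.method in ("camera", "padog"):
                stats_ = fit_gene_models(norm)
                gene_stats[ds.name] = stats_
                collection_in_data = collection.restrict_to(norm.matrix.index)
                if self.method == "camera":
                    res = camera_test(
                        stats_, collection_in_data, min_set_size=min_set_size
                    )
                else:
                    res = padog_test(
                        norm,
                        None,
                        collection_in_data,
                        n_perm=self.parameters.get("n_perm", 500),
                        seed=stage_seed,
                        min_set_size=min_set_size,
                    )
                tests[ds.name] = res
                mean_fc[ds.name] = pathway_mean_fold_change(
                    stats_, collection_in_data
                )
            else:  # ssgsea
                kernel = self.parameters.get("kernel")
                if kernel is None:
                    kernel = (
                        "poisson" if ds.data_type.is_discrete else "gaussian"
                    )
                use_kernel = self.parameters.get(
                    "use_kernel", kernel != "none"
                )
                scores[ds.name] = ssgsea_scores(
                    norm.matrix,
                    collection,
                    alpha=self.parameters.get("alpha", 0.25),
                    use_kernel=use_kernel,
                    kernel=None if kernel == "none" else kernel,
                    normalize=self.parameters.get("normalize_ssgsea", True),
                    min_set_size=self.parameters.get("min_set_size", 1),
                )
                entry["kernel"] = kernel if use_kernel else "none"
            provenance.append(entry)

        comparative = None
        if self.method in ("camera", "padog"):
            comparative = cmp.assemble(
                [(name, tests[name], mean_fc[name]) for name in tests]
            )
        return PathwayAnalysisResults(
            model=self,
            comparative=comparative,
            gene_stats=gene_stats,
            pathway_tests=tests,
            score_matrices=scores,
            provenance=provenance,
            mapping_logs=mapping_logs,
            validation=report,
            seed=master_seed,
            fdr_threshold=fdr_threshold,
        )


@dataclass
class PathwayAnalysisResults:
    """Fitted comparative pathway analysis.

    For the comparative methods, ``comparative`` holds the side-by-side
    per-pathway table and ``gene_stats`` the per-dataset gene-level fits; for
    single-sample scoring, ``score_matrices`` holds one pathways-by-samples
    matrix per dataset.
    """

    model: PathwayAnalysis
    comparative: cmp.ComparativeResult | None
    gene_stats: dict[str, GeneLevelStats]
    pathway_tests: dict[str, PathwayTestResult]
    score_matrices: dict[str, pd.DataFrame]
    provenance: list[dict]
    mapping_logs: dict[str, str]
    validation: ValidationReport
    seed: int | None
    fdr_threshold: float = 0.1

    def discordant(self, dataset_a: str, dataset_b: str) -> list[str]:
        if self.comparative is None:
            raise AnalysisError(
                "discordance is defined for the comparative methods only; "
                "single-sample scores carry no direction"
            )
        return cmp.discordant_pathways(
            self.comparative, dataset_a, dataset_b, self.fdr_threshold
        )

    def concordance(self, dataset_a: str, dataset_b: str) -> dict:
        if self.comparative is None:
            raise AnalysisError("no comparative result on a ssgsea fit")
        return cmp.concordance_summary(
            self.comparative, dataset_a, dataset_b, self.fdr_threshold
        )

    def zscored_scores(self, dataset: str) -> pd.DataFrame:
        return zscore_by_pathway(self.score_matrices[dataset])

    def summary(self, top: int = 10) -> str:
        """Plain-text overview in the style of a regression summary."""
        lines = []
        lines.append("Comparative Gene Set Analysis Results")
        lines.append("=" * 60)
        lines.append(f"Method:            {self.model.method}")
        lines.append(f"Datasets:          {len(self.model.datasets)}")
        lines.append(f"Gene sets:         {len(self.model.gene_sets)}")
        lines.append(f"Seed:              {self.seed}")
        for entry in self.provenance:
            lines.append(
                f"  {entry['dataset']}: {entry['data_type']} -> {entry['branch']}"
            )
        if self.comparative is not None and len(self.comparative.long):
            lines.append("-" * 60)
            lines.append(
                f"Top pathways by FDR (threshold {self.fdr_threshold}):"
            )
            best = (
                self.comparative.long.sort_values("fdr")
                .head(top)
                .loc[
                    :,
                    ["pathway", "dataset", "p", "fdr", "mean_log2fc", "direction"],
                ]
            )
            lines.append(
                best.to_string(
                    index=False,
                    float_format=lambda v: f"{v:.4g}",
                )
            )
            n_sig = int((self.comparative.long["fdr"] < self.fdr_threshold).sum())
            lines.append(
                f"{n_sig} (pathway, dataset) results at FDR < {self.fdr_threshold}"
            )
        for name, sc in self.score_matrices.items():
            lines.append("-" * 60)
            lines.append(
                f"{name}: {sc.shape[0]} pathways x {sc.shape[1]} columns "
                "of single-sample scores"
            )
        return "\n".join(lines)

    def plot_comparison(self, dataset_a: str, dataset_b: str, ax=None):
        """Scatter of per-pathway mean log2FC in one dataset vs the other."""
        import matplotlib.pyplot as plt

        if self.comparative is None:
            raise AnalysisError("no comparative result to plot")
        a = self.comparative.block(dataset_a)["mean_log2fc"]
        b = self.comparative.block(dataset_b)["mean_log2fc"]
        shared = a.index.intersection(b.index)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        disc = set(self.discordant(dataset_a, dataset_b))
        colors = ["crimson" if p in disc else "steelblue" for p in shared]
        ax.scatter(a.loc[shared], b.loc[shared], s=12, c=colors, alpha=0.7)
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel(f"mean log2FC ({dataset_a})")
        ax.set_ylabel(f"mean log2FC ({dataset_b})")
        return ax

    def save(self, out_dir) -> Path:
        """Write all result tables and the provenance log to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, stats_ in self.gene_stats.items():
            stats_.to_tsv(out / f"{name}_gene_stats.tsv")
        for name, res in self.pathway_tests.items():
            res.to_tsv(out / f"{name}_pathways.tsv")
        if self.comparative is not None:
            self.comparative.to_tsv(out / "comparative_long.tsv", "long")
            self.comparative.to_tsv(out / "comparative_wide.tsv", "wide")
        for name, sc in self.score_matrices.items():
            sc.to_csv(
                out / f"{name}_pathway_scores.tsv",
                sep="\t",
                float_format="%.6g",
            )
        log = {
            "method": self.model.method,
            "seed": self.seed,
            "parameters": {
                k: v
                for k, v in self.model.parameters.items()
                if isinstance(v, (int, float, str, bool, type(None)))
            },
            "stages": self.provenance,
            "mapping": self.mapping_logs,
            "warnings": self.validation.warnings,
        }
        (out / "provenance.json").write_text(json.dumps(log, indent=2, sort_keys=True))
        return out
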