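"""Side-by-side assembly of per-dataset results and discordance detection.

Every dataset is analyzed separately; the comparative result is an outer join
on pathway id, with the FDR recomputed within each dataset (never pooled —
datasets may cover different pathway subsets after mapping).  A pathway is
*discordant* between two datasets when it is significant in both and its mean
member fold-change points in opposite directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError
from .gsa import PathwayTestResult, bh_fdr

__all__ = [
    "ComparativeResult",
    "assemble",
    "discordant_pathways",
    "concordance_summary",
]


def _direction(mean_fc: float) -> str:
    if np.isnan(mean_fc) or mean_fc == 0:
        return "zero"
    return "up" if mean_fc > 0 else "down"


@dataclass
class ComparativeResult:
    """Long-format per-pathway, per-dataset comparative table.

    ``long`` has one row per (pathway, dataset) actually tested, with columns
    ``pathway``, ``name``, ``dataset``, ``p``, ``fdr``, ``mean_log2fc``,
    ``direction``, ``n_genes``.  Combinations missing from a dataset simply
    have no row; the wide view shows them as NaN (an explicit missing
    marker, never a silent zero).
    """

    long: pd.DataFrame
    datasets: list[str]

    def wide(self, value: str = "fdr") -> pd.DataFrame:
        return self.long.pivot(index="pathway", columns="dataset", values=value)

    def block(self, dataset: str) -> pd.DataFrame:
        if dataset not in self.datasets:
            raise AnalysisError(f"unknown dataset {dataset!r}")
        blk = self.long[self.long["dataset"] == dataset]
        return blk.set_index("pathway")

    @property
    def pathways(self) -> list[str]:
        return sorted(self.long["pathway"].unique())

    def to_tsv(self, path, fmt: str = "long") -> None:
        if fmt == "long":
            self.long.to_csv(path, sep="\t", index=False, float_format="%.6g")
        elif fmt == "wide":
            parts = []
            for value in ("p", "fdr", "mean_log2fc", "direction", "n_genes"):
                w = self.wide(value)
                w.columns = [f"{c}.{value}" for c in w.columns]
                parts.append(w)
            pd.concat(parts, axis=1).to_csv(
                path, sep="\t", float_format="%.6g"
            )
        else:
            raise AnalysisError(f"unknown format {fmt!r}")

    def to_excel(self, path) -> None:
        """Spreadsheet export: one sheet per dataset plus the joined view."""
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            self.long.to_excel(xl, sheet_name="all_datasets", index=False)
            for ds in self.datasets:
                self.block(ds).to_excel(xl, sheet_name=ds[:31])


def assemble(
    results: list[tuple[str, PathwayTestResult, pd.Series]],
) -> ComparativeResult:
    """Join per-dataset pathway results into one comparative result.

    ``results`` holds (dataset name, test result, per-pathway mean member
    log2FC) triples.  The FDR is recomputed per dataset over its own tested
    pathways; the direction column is the sign of the mean member
    fold-change.  Duplicate dataset names are an error.
    """
    if not results:
        raise AnalysisError("nothing to assemble")
    names = [name for name, _, _ in results]
    if len(set(names)) != len(names):
        raise AnalysisError(f"duplicate dataset names in {names}")
    frames = []
    for name, res, mean_fc in results:
        tab = res.table
        if not len(tab):
            continue
        fc = mean_fc.reindex(tab.index)
        frames.append(
            pd.DataFrame(
                {
                    "pathway": tab.index,
                    "name": tab["name"].to_numpy(),
                    "dataset": name,
                    "p": tab["p"].to_numpy(),
                    "fdr": bh_fdr(tab["p"].to_numpy()),
                    "mean_log2fc": fc.to_numpy(),
                    "direction": [_direction(v) for v in fc.to_numpy()],
                    "n_genes": tab["n_genes"].to_numpy(),
                }
            )
        )
    long = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "pathway",
                "name",
                "dataset",
                "p",
                "fdr",
                "mean_log2fc",
                "direction",
                "n_genes",
            ]
        )
    )
    long = long.sort_values(["pathway", "dataset"], kind="stable").reset_index(
        drop=True
    )
    return ComparativeResult(long=long, datasets=names)


def discordant_pathways(
    cr: ComparativeResult,
    dataset_a: str,
    dataset_b: str,
    fdr_threshold: float = 0.1,
) -> list[str]:
    """Pathways significant in both datasets with opposite fold-change sign.

    Requires FDR below ``fdr_threshold`` in *both* datasets and strictly
    opposite signs of the mean member log2 fold-change; a zero mean
    fold-change counts as neither direction.  Symmetric in the two dataset
    names.
    """
    a = cr.block(dataset_a)
    b = cr.block(dataset_b)
    shared = a.index.intersection(b.index)
    out = []
    for pw in shared:
        if a.loc[pw, "fdr"] < fdr_threshold and b.loc[pw, "fdr"] < fdr_threshold:
            fa, fb = a.loc[pw, "mean_log2fc"], b.loc[pw, "mean_log2fc"]
            if np.isnan(fa) or np.isnan(fb):
                continue
            if fa * fb < 0:
                out.append(pw)
    return sorted(out)


def concordance_summary(
    cr: ComparativeResult,
    dataset_a: str,
    dataset_b: str,
    fdr_threshold: float = 0.1,
) -> dict:
    """Counts of shared significance plus a rank correlation of p-values.

    Returns ``significant_any`` (significant in at least one dataset),
    ``significant_both``, ``discordant`` and ``rank_correlation`` (Spearman
    over pathways tested in both; None when fewer than 2 overlap).
    """
    a = cr.block(dataset_a)
    b = cr.block(dataset_b)
    sig_a = set(a.index[a["fdr"] < fdr_threshold])
    sig_b = set(b.index[b["fdr"] < fdr_threshold])
    shared = a.index.intersection(b.index)
    if len(shared) >= 2:
        rho = sps.spearmanr(
            a.loc[shared, "p"].to_numpy(), b.loc[shared, "p"].to_numpy()
        ).statistic
        rho = None if np.isnan(rho) else float(rho)
    else:
        rho = None
    return {
        "significant_any": len(sig_a | sig_b),
        "significant_both": len(sig_a & sig_b),
        "discordant": len(
            discordant_pathways(cr, dataset_a, dataset_b, fdr_threshold)
        ),
        "rank_correlation": rho,
        "fdr_threshold": fdr_threshold,
    }
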