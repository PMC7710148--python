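"""Data-type-dispatched normalization ahead of gene set analysis.

Two branches, chosen by the declared data type:

* **discrete** (raw RNA-seq counts, proteomics spectral counts): relative
  library scaling by the trimmed mean of M-values (TMM), log2 counts-per-
  million with a small prior, then per-observation precision weights from a
  smoothed mean-variance trend — so ordinary linear-model machinery applies
  to count data.
* **continuous** (microarray intensities, normalized counts, proteomics
  intensities): between-sample normalization (quantile by default).

For single-sample scoring the branches instead select the kernel (Poisson for
discrete, Gaussian for continuous) and the matrix is passed through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import DataType, ExpressionDataset, TwoGroupDesign
from .errors import AnalysisError

__all__ = [
    "NormalizedDataset",
    "filter_low_expression",
    "tmm_factors",
    "counts_to_logcpm",
    "voom_weights",
    "normalize_continuous",
    "dispatch",
]


@dataclass
class NormalizedDataset:
    """Output of the normalization stage for one dataset.

    ``matrix`` is on the analysis scale (log2 for the linear-model branches,
    raw values for the kernel branches).  ``weights`` are per-observation
    precision weights (unit for continuous data).  ``factors`` are the
    effective library scaling factors (discrete branch only; geometric mean
    1).  ``provenance`` names the branch that was applied.
    """

    name: str
    matrix: pd.DataFrame
    weights: pd.DataFrame
    data_type: DataType
    design: TwoGroupDesign | None
    provenance: str
    factors: pd.Series | None = None
    lib_sizes: pd.Series | None = None
    log: list[str] = field(default_factory=list)


def filter_low_expression(
    dataset: ExpressionDataset,
    min_value: float = 10,
    min_fraction: float = 0.30,
) -> ExpressionDataset:
    """Drop genes not reaching ``min_value`` in ``min_fraction`` of samples.

    The default keeps genes with at least 10 reads in at least 30% of
    samples.  Intended for count data; removing every gene is an error.
    """
    values = dataset.matrix.to_numpy()
    n = values.shape[1]
    keep = (values >= min_value).sum(axis=1) >= min_fraction * n
    if not keep.any():
        raise AnalysisError(
            f"dataset {dataset.name!r}: low-expression filter removed every "
            f"gene (min_value={min_value}, min_fraction={min_fraction})"
        )
    return ExpressionDataset(
        name=dataset.name,
        matrix=dataset.matrix.loc[keep],
        data_type=dataset.data_type,
        design=dataset.design,
    )


def tmm_factors(
    counts: pd.DataFrame | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values relative library scaling factors.

    The reference sample is the column whose 75th-percentile-to-total ratio
    is closest to the mean such ratio (ties broken by lowest column index).
    For each sample, per-gene log ratios M and average log abundances A
    against the reference are formed over genes positive in both; the 30%
    tails of M and the 5% tails of A are trimmed (rank-based, double
    trimming); the factor is 2 to the precision-weighted mean of the
    surviving M values, with weights the inverse delta-method binomial
    variances.  Factors are rescaled to geometric mean 1.
    """
    X = np.asarray(counts, dtype=float)
    if (X < 0).any():
        raise AnalysisError("TMM requires a non-negative matrix")
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        raise AnalysisError("TMM requires positive totals in every sample")
    n_samples = X.shape[1]

    f75 = np.array([np.quantile(X[:, j], 0.75) for j in range(n_samples)]) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = X[:, ref_idx]
    n_ref = lib[ref_idx]

    log_factors = np.zeros(n_samples)
    for j in range(n_samples):
        obs = X[:, j]
        n_obs = lib[j]
        pos = (obs > 0) & (ref > 0)
        if not pos.any():
            raise AnalysisError(
                f"sample {j} shares no positive gene with the reference "
                f"sample {ref_idx}"
            )
        o, r = obs[pos], ref[pos]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

        n = m.size
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = rankdata(m)
        rank_a = rankdata(a)
        keep = (
            (rank_m >= lo_m)
            & (rank_m <= hi_m)
            & (rank_a >= lo_a)
            & (rank_a <= hi_a)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            if keep.any():
                f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
                if np.isfinite(f):
                    log_factors[j] = f
        # non-finite f (zero-variance genes, e.g. sample == reference) and
        # fully degenerate trims leave the factor at 1 (log 0)

    log_factors -= log_factors.mean()  # geometric mean 1
    return 2.0 ** log_factors


def counts_to_logcpm(
    counts: pd.DataFrame,
    factors: np.ndarray | pd.Series | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + prior)/(total*factor + 1) * 1e6)."""
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    f = np.ones_like(lib) if factors is None else np.asarray(factors, float)
    if (f <= 0).any():
        raise AnalysisError("scaling factors must be positive")
    eff = lib * f + 1.0
    logcpm = np.log2((X + prior) / eff[None, :] * 1e6)
    return pd.DataFrame(logcpm, index=counts.index, columns=counts.columns)


def _group_fit(y: np.ndarray, z: np.ndarray):
    """Per-gene two-group OLS: fitted values and residual sd (df = n-2)."""
    n1 = z.sum()
    n0 = z.size - n1
    mean1 = y[:, z == 1].mean(axis=1)
    mean0 = y[:, z == 0].mean(axis=1)
    fitted = np.where(z[None, :] == 1, mean1[:, None], mean0[:, None])
    resid = y - fitted
    df = z.size - 2
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df)
    return fitted, sigma, mean1, mean0


def voom_weights(
    logcpm: pd.DataFrame,
    group: np.ndarray,
    lib_sizes: np.ndarray,
    factors: np.ndarray | None = None,
    span: float = 0.5,
    weight_floor: float = 1e-8,
) -> pd.DataFrame:
    """Precision weights from the log-count mean-variance trend.

    Fits the two-group model gene-wise on log-CPM, smooths the square root of
    the residual standard deviation against mean log2 count with locally
    weighted regression (span 0.5), then evaluates the trend at every
    observation's fitted log-count; the weight is the predicted value to the
    power −4 (i.e. the inverse predicted variance), clipped to a positive
    floor.  Requires at least 10 genes for the trend to be estimable.
    """
    if logcpm.shape[0] < 10:
        raise AnalysisError(
            f"mean-variance trend needs >=10 genes, got {logcpm.shape[0]}"
        )
    if group.size != logcpm.shape[1]:
        raise AnalysisError("group vector length does not match sample count")
    y = logcpm.to_numpy(dtype=float)
    f = np.ones(y.shape[1]) if factors is None else np.asarray(factors, float)
    eff = np.asarray(lib_sizes, float) * f + 1.0

    fitted, sigma, _, _ = _group_fit(y, group)
    # mean log2 count per gene: mean log-CPM shifted back to the count scale
    sx = y.mean(axis=1) + np.mean(np.log2(eff)) - np.log2(1e6)
    sy = np.sqrt(sigma)

    order = np.argsort(sx, kind="stable")
    smooth = lowess(sy[order], sx[order], frac=span, return_sorted=True)
    trend_x, trend_y = smooth[:, 0], smooth[:, 1]
    # constant extrapolation beyond the fitted range
    fitted_logcount = fitted + (np.log2(eff) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, trend_x, trend_y)
    pred = np.clip(pred, 1e-6, None)
    w = pred ** -4.0
    w = np.clip(w, weight_floor, None)
    return pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns)


def normalize_continuous(
    matrix: pd.DataFrame,
    method: str = "quantile",
    log_transform: bool | None = None,
) -> pd.DataFrame:
    """Between-sample normalization for continuous data.

    ``quantile`` replaces each column's order statistics with their
    across-sample means, making column distributions identical (ties get the
    average of the tied order-statistic means).  ``scale`` equalizes column
    medians (dividing by median over geometric-mean-of-medians).  ``none``
    passes through.  ``log_transform=None`` auto-enables log2 for all-positive
    matrices spanning more than 3 orders of magnitude.
    """
    X = matrix.to_numpy(dtype=float)
    if log_transform is None:
        positive = (X > 0).all()
        log_transform = bool(
            positive and X.max() / X.min() > 1e3
        )
    if log_transform:
        if (X <= 0).any():
            raise AnalysisError(
                "log transform requested but matrix has non-positive values"
            )
        X = np.log2(X)

    if method == "none":
        out = X
    elif method == "scale":
        med = np.median(X, axis=0)
        if (med <= 0).any():
            raise AnalysisError("scale normalization needs positive medians")
        scale = med / np.exp(np.mean(np.log(med)))
        out = X / scale[None, :]
    elif method == "quantile":
        n = X.shape[0]
        if n == 0:
            raise AnalysisError("empty matrix")
        for j in range(X.shape[1]):
            if X[:, j].max() == X[:, j].min():
                raise AnalysisError(
                    f"column {matrix.columns[j]!r} is constant; quantile "
                    "normalization undefined"
                )
        sorted_cols = np.sort(X, axis=0)
        target = sorted_cols.mean(axis=1)
        out = np.empty_like(X)
        positions = np.arange(1, n + 1, dtype=float)
        for j in range(X.shape[1]):
            ranks = rankdata(X[:, j], method="average")
            out[:, j] = np.interp(ranks, positions, target)
    else:
        raise AnalysisError(f"unknown continuous normalization {method!r}")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def dispatch(
    dataset: ExpressionDataset,
    method: str,
    *,
    filter_counts: bool = False,
    filter_min_value: float = 10,
    filter_min_fraction: float = 0.30,
    tmm_trim_m: float = 0.30,
    tmm_trim_a: float = 0.05,
    logcpm_prior: float = 0.5,
    voom_span: float = 0.5,
    continuous_method: str = "quantile",
    continuous_log_transform: bool | None = None,
) -> NormalizedDataset:
    """Route a dataset through the branch its declared data type selects.

    Discrete data feeding the linear-model methods (camera/padog) get
    TMM + log-CPM + precision weights; for single-sample scoring the raw
    counts are forwarded to the Poisson kernel.  Continuous data get
    between-sample normalization with unit weights, or the Gaussian kernel
    branch for single-sample scoring.  The branch taken is recorded in
    ``provenance``.
    """
    log: list[str] = []
    if dataset.data_type.is_discrete:
        ds = dataset
        if filter_counts:
            before = ds.matrix.shape[0]
            ds = filter_low_expression(ds, filter_min_value, filter_min_fraction)
            log.append(
                f"low-expression filter: {before} -> {ds.matrix.shape[0]} genes"
            )
        if method == "ssgsea":
            return NormalizedDataset(
                name=ds.name,
                matrix=ds.matrix.copy(),
                weights=pd.DataFrame(
                    1.0, index=ds.matrix.index, columns=ds.matrix.columns
                ),
                data_type=ds.data_type,
                design=ds.design,
                provenance="discrete: poisson kernel",
                lib_sizes=ds.matrix.sum(axis=0),
                log=log,
            )
        factors = tmm_factors(ds.matrix, trim_m=tmm_trim_m, trim_a=tmm_trim_a)
        logcpm = counts_to_logcpm(ds.matrix, factors, prior=logcpm_prior)
        lib = ds.matrix.to_numpy().sum(axis=0)
        if ds.design is None:
            raise AnalysisError(
                f"dataset {ds.name!r}: method {method!r} needs a design"
            )
        group = ds.design.group_vector(ds.sample_ids)
        weights = voom_weights(logcpm, group, lib, factors, span=voom_span)
        return NormalizedDataset(
            name=ds.name,
            matrix=logcpm,
            weights=weights,
            data_type=ds.data_type,
            design=ds.design,
            provenance="discrete: TMM+voom",
            factors=pd.Series(factors, index=ds.matrix.columns),
            lib_sizes=pd.Series(lib, index=ds.matrix.columns),
            log=log,
        )

    # continuous branch
    if method == "ssgsea":
        provenance = "continuous: gaussian kernel"
        out = dataset.matrix.copy()
    else:
        provenance = "continuous: between-array"
        out = normalize_continuous(
            dataset.matrix,
            method=continuous_method,
            log_transform=continuous_log_transform,
        )
        if continuous_method != "quantile":
            provenance = f"continuous: between-array ({continuous_method})"
    return NormalizedDataset(
        name=dataset.name,
        matrix=out,
        weights=pd.DataFrame(1.0, index=out.index, columns=out.columns),
        data_type=dataset.data_type,
        design=dataset.design,
        provenance=provenance,
        log=log,
    )
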