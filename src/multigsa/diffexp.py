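"""Per-gene two-group differential expression with variance moderation.

Fits a weighted two-group linear model per gene and shrinks the residual
variances toward a common prior before forming t-statistics.  The prior (a
scaled inverse-chi-square distribution on the gene-wise variances) is fitted
by method of moments on the log variances; moderation stabilizes the
statistics at small sample sizes and feeds both the competitive and the
permutation pathway tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import GeneLevelStats, GeneSetCollection, TwoGroupDesign
from .errors import AnalysisError
from .preprocess import NormalizedDataset

__all__ = ["fit_gene_models", "pathway_mean_fold_change", "moderated_t_matrix"]

_MAX_DF = 1e6  # stands in for an infinite prior df


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 (vectorized Newton iteration)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior df d0, prior variance s0^2).

    Matches the moments of log(s^2) against those implied by a scaled
    inverse-chi-square prior: the excess variance of the log variances beyond
    the chi-square sampling noise determines d0 via the inverse trigamma; no
    excess means an effectively infinite prior df (complete shrinkage).
    Genes with zero sample variance are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise AnalysisError("zero residual variance in every gene")
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    if n < 2:
        return float(_MAX_DF), float(np.exp(e_mean))
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if e_var <= 0:
        return float(_MAX_DF), float(np.exp(e_mean))
    d0 = float(2.0 * _trigamma_inverse(np.array([e_var]))[0])
    d0 = min(d0, _MAX_DF)
    s0 = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0


def _weighted_group_fit(y: np.ndarray, w: np.ndarray, z: np.ndarray):
    """Weighted LS fit of the two-group model for every gene at once.

    Returns (log2fc, residuals, s2, se_unscaled, df) where ``se_unscaled``
    is the coefficient standard error per unit residual sd.
    """
    z = np.asarray(z)
    in1 = z == 1
    in0 = ~in1
    w1 = w[:, in1]
    w0 = w[:, in0]
    sw1 = w1.sum(axis=1)
    sw0 = w0.sum(axis=1)
    if (sw1 <= 0).any() or (sw0 <= 0).any():
        raise AnalysisError("non-positive weight sum within a group")
    mean1 = (w1 * y[:, in1]).sum(axis=1) / sw1
    mean0 = (w0 * y[:, in0]).sum(axis=1) / sw0
    fitted = np.where(in1[None, :], mean1[:, None], mean0[:, None])
    resid = y - fitted
    df = y.shape[1] - 2
    if df < 1:
        raise AnalysisError("fewer than 1 residual degree of freedom")
    s2 = (w * resid ** 2).sum(axis=1) / df
    se_unscaled = np.sqrt(1.0 / sw1 + 1.0 / sw0)
    return mean1 - mean0, resid, s2, se_unscaled, df


def fit_gene_models(
    norm: NormalizedDataset, design: TwoGroupDesign | None = None
) -> GeneLevelStats:
    """Per-gene moderated two-group statistics for a normalized dataset.

    The log2 fold-change is comparison-minus-reference on the (log2) analysis
    scale.  Residual variances are shrunk toward the fitted prior
    (a convex combination weighted by the respective degrees of freedom) and
    the moderated t uses the combined residual + prior degrees of freedom.
    Genes with zero sample variance take the prior variance alone, so no
    statistic is infinite.
    """
    design = design or norm.design
    if design is None:
        raise AnalysisError("a two-group design is required")
    y = norm.matrix.to_numpy(dtype=float)
    w = norm.weights.to_numpy(dtype=float)
    z = design.group_vector(list(norm.matrix.columns))
    if z.sum() < 1 or (z == 0).sum() < 1:
        raise AnalysisError("both groups need at least one sample")

    log2fc, resid, s2, se_unscaled, df = _weighted_group_fit(y, w, z)
    d0, s0 = fit_variance_prior(s2, df)
    post_var = np.where(
        s2 > 0, (d0 * s0 + df * s2) / (d0 + df), s0
    )
    total_df = min(df + d0, _MAX_DF)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / (np.sqrt(post_var) * se_unscaled)
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "sd": np.sqrt(post_var),
            "df": total_df,
        },
        index=norm.matrix.index,
    )
    residuals = pd.DataFrame(
        resid, index=norm.matrix.index, columns=norm.matrix.columns
    )
    return GeneLevelStats(
        table=table, residuals=residuals, prior_df=d0, prior_var=s0
    )


def moderated_t_matrix(
    y: np.ndarray, w: np.ndarray, memberships: np.ndarray
) -> np.ndarray:
    """Moderated |t|-free t-statistics for many group assignments at once.

    ``memberships`` is samples-by-B; column b is the 0/1 comparison-group
    indicator of assignment b.  Returns a genes-by-B matrix of moderated
    t-statistics, each column using its own method-of-moments prior.  This is
    the workhorse of the label-permutation test: everything is expressed as
    matrix products so thousands of permutations cost a few BLAS calls.
    """
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    Z = np.asarray(memberships, float)  # n x B
    n = y.shape[1]
    df = n - 2
    wy = w * y
    wyy = w * y * y
    sw_tot = w.sum(axis=1, keepdims=True)
    swy_tot = wy.sum(axis=1, keepdims=True)
    tot_wyy = wyy.sum(axis=1, keepdims=True)
    chi_offset = -special.digamma(df / 2.0) + np.log(df / 2.0)
    chi_var = special.polygamma(1, df / 2.0)

    # chunked over assignments: keeps the working set cache-sized
    out = np.empty((y.shape[0], Z.shape[1]))
    for start in range(0, Z.shape[1], 512):
        Zc = Z[:, start : start + 512]
        sw1 = w @ Zc  # G x b
        sw0 = sw_tot - sw1
        s1 = wy @ Zc
        mean1 = s1 / sw1
        mean0 = (swy_tot - s1) / sw0
        delta = mean1 - mean0
        # weighted RSS = sum w y^2 - sw1*mean1^2 - sw0*mean0^2
        rss = tot_wyy - sw1 * mean1 ** 2 - sw0 * mean0 ** 2
        s2 = np.maximum(rss, 0.0) / df
        se_unscaled = np.sqrt(1.0 / sw1 + 1.0 / sw0)

        pos = s2 > 0
        if not pos.any(axis=0).all():
            raise AnalysisError("zero residual variance in every gene")
        z_log = np.where(pos, np.log(np.where(pos, s2, 1.0)), np.nan)
        e_mean = np.nanmean(z_log, axis=0) + chi_offset
        with np.errstate(invalid="ignore"):
            e_var = np.nanvar(z_log, axis=0, ddof=1) - chi_var
        d0 = np.full(Zc.shape[1], _MAX_DF)
        has_excess = np.nan_to_num(e_var) > 0
        if has_excess.any():
            d0[has_excess] = np.minimum(
                2.0 * _trigamma_inverse(e_var[has_excess]), _MAX_DF
            )
        s0_var = np.where(
            has_excess,
            np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)),
            np.exp(e_mean),
        )
        post = np.where(
            pos,
            (d0[None, :] * s0_var[None, :] + df * s2) / (d0[None, :] + df),
            s0_var[None, :],
        )
        out[:, start : start + 512] = delta / (np.sqrt(post) * se_unscaled)
    return out


def pathway_mean_fold_change(
    stats_: GeneLevelStats, collection: GeneSetCollection
) -> pd.Series:
    """Arithmetic mean of member log2 fold-changes per pathway.

    Members absent from the gene-level table are ignored; a pathway with no
    scored member gets NaN (an explicit missing marker).
    """
    fc = stats_.table["log2fc"]
    out = {}
    for s in collection:
        members = [g for g in s.members if g in fc.index]
        out[s.id] = float(fc.loc[members].mean()) if members else np.nan
    return pd.Series(out, name="mean_log2fc")
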