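"""The three gene-set-analysis methods.

* :func:`camera_test` — competitive test of member vs non-member moderated
  t-statistics, corrected for inter-gene correlation through a variance
  inflation factor VIF = 1 + (m-1)*rho estimated from residual correlations.
* :func:`padog_test` — permutation test on down-weighted absolute moderated
  t-scores; genes annotated to many sets count less (weight between 1 and 2),
  significance comes from sample-label permutation with per-run
  standardization of set scores.
* :func:`ssgsea_scores` — single-sample enrichment: a weighted running sum
  over each sample's gene ranking, optionally preceded by a kernel-CDF
  transform (Poisson kernel for counts, Gaussian for continuous data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .core import GeneLevelStats, GeneSetCollection, TwoGroupDesign
from .diffexp import fit_gene_models, moderated_t_matrix
from .errors import AnalysisError
from .preprocess import NormalizedDataset

__all__ = [
    "PathwayTestResult",
    "bh_fdr",
    "camera_test",
    "padog_test",
    "padog_gene_weights",
    "kernel_cdf_transform",
    "ssgsea_scores",
]


@dataclass
class PathwayTestResult:
    """Per-pathway test outcome: score, direction, p, FDR, member count.

    ``table`` is indexed by pathway id with columns ``name``, ``n_genes``,
    ``score``, ``direction`` (up/down), ``p``, ``fdr``.  ``skipped`` lists
    pathways below the minimum set size after mapping.
    """

    table: pd.DataFrame
    method: str
    skipped: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "pathway_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise AnalysisError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finish_table(rows: dict, method: str, skipped: list[str]) -> PathwayTestResult:
    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table["fdr"] = bh_fdr(table["p"].to_numpy())
        table.index.name = "pathway_id"
    else:
        table = pd.DataFrame(
            columns=["name", "n_genes", "score", "direction", "p", "fdr"]
        )
    return PathwayTestResult(table=table, method=method, skipped=skipped)


def camera_test(
    stats_: GeneLevelStats,
    collection: GeneSetCollection,
    min_set_size: int = 3,
) -> PathwayTestResult:
    """Competitive test with an inter-gene-correlation correction.

    For a set of m genes, the mean pairwise correlation of member residuals
    gives the variance inflation factor VIF = 1 + (m-1)*rho (floored at 1:
    negative estimated correlation is not allowed to anti-conservatively
    deflate the variance).  Members' moderated t-values are compared with
    non-members' via a pooled-variance two-sample statistic divided by
    sqrt(VIF), referred to a t distribution with G-2 degrees of freedom.
    """
    t = stats_.table["t"]
    genes = t.index
    g_total = len(genes)
    resid = stats_.residuals.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    t_values = t.to_numpy(dtype=float)

    rows = {}
    skipped = []
    for s in collection:
        members = sorted(m for m in s.members if m in gene_pos)
        m = len(members)
        if m < min_set_size or g_total - m < 2:
            skipped.append(s.id)
            continue
        idx = np.array([gene_pos[g] for g in members])
        rho = _mean_residual_correlation(resid[idx])
        vif = max(1.0, 1.0 + (m - 1) * rho)

        in_mask = np.zeros(g_total, dtype=bool)
        in_mask[idx] = True
        t_in = t_values[in_mask]
        t_out = t_values[~in_mask]
        mean_in, mean_out = t_in.mean(), t_out.mean()
        df = g_total - 2
        var_in = t_in.var(ddof=1) if m > 1 else 0.0
        pooled = ((m - 1) * var_in + (g_total - m - 1) * t_out.var(ddof=1)) / df
        if pooled <= 0:
            skipped.append(s.id)
            continue
        stat = (mean_in - mean_out) / (
            np.sqrt(pooled) * np.sqrt(1.0 / m + 1.0 / (g_total - m))
        )
        stat /= np.sqrt(vif)
        p = float(2.0 * sps.t.sf(abs(stat), df))
        rows[s.id] = {
            "name": s.name,
            "n_genes": m,
            "score": float(stat),
            "direction": "up" if mean_in >= mean_out else "down",
            "p": max(p, np.finfo(float).tiny),
        }
    return _finish_table(rows, "camera", skipped)


def _mean_residual_correlation(resid_rows: np.ndarray) -> float:
    """Mean off-diagonal correlation among residual rows (0 if degenerate)."""
    if resid_rows.shape[0] < 2:
        return 0.0
    sd = resid_rows.std(axis=1)
    ok = sd > 0
    if ok.sum() < 2:
        return 0.0
    c = np.corrcoef(resid_rows[ok])
    m = c.shape[0]
    off = (c.sum() - m) / (m * (m - 1))
    return float(off)


def padog_gene_weights(
    membership_count: dict[str, int], genes: list[str]
) -> pd.Series:
    """Down-weighting of promiscuously annotated genes.

    w_g = 1 + sqrt((max f - f_g) / (max f - min f)) with f the number of sets
    a gene belongs to, computed over the given genes; a gene in the most sets
    weighs exactly 1, one in the fewest exactly 2.  When all genes share the
    same f the weights are identically 1.
    """
    f = np.array([membership_count.get(g, 0) for g in genes], dtype=float)
    fmax, fmin = f.max(), f.min()
    if fmax == fmin:
        w = np.ones_like(f)
    else:
        w = 1.0 + np.sqrt((fmax - f) / (fmax - fmin))
    return pd.Series(w, index=genes)


def _distinct_splits(n: int, n1: int) -> int:
    total = comb(n, n1)
    if 2 * n1 == n:
        total //= 2
    return total


def _enumerate_splits(n: int, n1: int) -> np.ndarray:
    """All distinct comparison-group index sets as an n-by-B 0/1 matrix.

    When group sizes are equal, complementary splits are the same test
    (absolute statistics are label-symmetric) and are enumerated once, by
    pinning sample 0 to the comparison group.
    """
    cols = []
    if 2 * n1 == n:
        for rest in combinations(range(1, n), n1 - 1):
            z = np.zeros(n)
            z[[0, *rest]] = 1
            cols.append(z)
    else:
        for chosen in combinations(range(n), n1):
            z = np.zeros(n)
            z[list(chosen)] = 1
            cols.append(z)
    return np.column_stack(cols)


def padog_test(
    norm: NormalizedDataset,
    design: TwoGroupDesign | None,
    collection: GeneSetCollection,
    n_perm: int = 500,
    seed: int | None = None,
    min_set_size: int = 3,
) -> PathwayTestResult:
    """Permutation pathway test with gene down-weighting.

    The observed score of a set is the mean over members of |moderated t|
    times the gene weight.  Group labels are permuted (group sizes
    preserved); within every run — observed and each permutation — the set
    scores are standardized across sets, and the p-value is the fraction of
    permuted standardized scores reaching the observed one.  If ``n_perm``
    meets or exceeds the number of distinct label splits the test is exact:
    all splits are enumerated (the observed split included in the
    denominator).  Direction is the sign of the observed mean member log2FC.
    """
    design = design or norm.design
    if design is None:
        raise AnalysisError("padog requires a two-group design")
    if n_perm < 100:
        raise AnalysisError("n_perm must be at least 100")
    y = norm.matrix.to_numpy(dtype=float)
    w = norm.weights.to_numpy(dtype=float)
    genes = list(norm.matrix.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    z_obs = design.group_vector(list(norm.matrix.columns))
    n = z_obs.size
    n1 = int(z_obs.sum())

    member_idx: dict[str, np.ndarray] = {}
    skipped = []
    for s in collection:
        idx = np.array(sorted(gene_pos[g] for g in s.members if g in gene_pos))
        if idx.size < min_set_size:
            skipped.append(s.id)
        else:
            member_idx[s.id] = idx
    if not member_idx:
        return _finish_table({}, "padog", skipped)

    scored_genes = sorted({g for s in collection for g in s.members if g in gene_pos})
    weights = padog_gene_weights(collection.membership_count, scored_genes)
    gene_w = np.zeros(len(genes))
    gene_w[[gene_pos[g] for g in scored_genes]] = weights.to_numpy()

    total = _distinct_splits(n, n1)
    exact = n_perm >= total
    if exact:
        Z_perm = _enumerate_splits(n, n1)
    else:
        rng = np.random.default_rng(seed)
        cols = []
        for _ in range(n_perm):
            z = np.zeros(n)
            z[rng.permutation(n)[:n1]] = 1
            cols.append(z)
        Z_perm = np.column_stack(cols)

    Z_all = np.column_stack([z_obs.astype(float), Z_perm])
    t_all = np.abs(moderated_t_matrix(y, w, Z_all))  # genes x (1+B)
    wt_all = t_all * gene_w[:, None]

    set_ids = list(member_idx)
    scores = np.vstack(
        [wt_all[member_idx[sid]].mean(axis=0) for sid in set_ids]
    )  # sets x runs
    if scores.shape[0] >= 2:
        run_sd = scores.std(axis=0, ddof=1)
        run_mean = scores.mean(axis=0)
        safe = run_sd > 0
        std_scores = scores.copy()
        std_scores[:, safe] = (scores[:, safe] - run_mean[safe]) / run_sd[safe]
    else:
        std_scores = scores

    obs = std_scores[:, 0]
    perm = std_scores[:, 1:]
    # numerical tie guard: standardized scores are O(1), and permutations
    # that reproduce the observed split must count as exceedances even when
    # the two standardizations differ in the last float digit
    exceeds = perm >= obs[:, None] - 1e-9
    if exact:
        # the observed split is one of the enumerated runs
        p = exceeds.sum(axis=1) / total
    else:
        p = (1.0 + exceeds.sum(axis=1)) / (n_perm + 1.0)

    obs_stats = fit_gene_models(norm, design)
    fc = obs_stats.table["log2fc"]
    rows = {}
    for i, sid in enumerate(set_ids):
        s = collection[sid]
        members = [genes[j] for j in member_idx[sid]]
        mean_fc = float(fc.loc[members].mean())
        rows[sid] = {
            "name": s.name,
            "n_genes": int(member_idx[sid].size),
            "score": float(obs[i]),
            "direction": "up" if mean_fc >= 0 else "down",
            "p": float(p[i]),
        }
    return _finish_table(rows, "padog", skipped)


def kernel_cdf_transform(
    matrix: pd.DataFrame,
    kernel: str,
    rate_prior: float = 0.5,
    bandwidth_floor: float = 1e-6,
) -> pd.DataFrame:
    """Smoothed empirical CDF statistic per gene across samples.

    Each value is replaced by the average kernel CDF over the gene's sample
    values: a Poisson CDF with rate x_k + ``rate_prior`` for count data, or a
    Gaussian CDF centered at x_k with bandwidth sd/4 (floored for constant
    genes) for continuous data.  Output values lie in (0, 1) and preserve the
    within-gene ordering.
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[1]
    if kernel == "poisson":
        if (X < 0).any() or not np.allclose(X, np.round(X)):
            raise AnalysisError(
                "poisson kernel requires non-negative integer values"
            )
        rates = X + rate_prior  # genes x samples (kernel centers)
        out = np.empty_like(X)
        for j in range(n):
            # CDF of each kernel component evaluated at column j's values
            out[:, j] = sps.poisson.cdf(X[:, j][:, None], rates).mean(axis=1)
    elif kernel == "gaussian":
        sd = X.std(axis=1, ddof=1) if n > 1 else np.zeros(X.shape[0])
        h = np.maximum(sd / 4.0, bandwidth_floor)
        out = np.empty_like(X)
        for j in range(n):
            zscores = (X[:, j][:, None] - X) / h[:, None]
            out[:, j] = sps.norm.cdf(zscores).mean(axis=1)
    else:
        raise AnalysisError(f"unknown kernel {kernel!r}")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def ssgsea_scores(
    matrix: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.25,
    use_kernel: bool = False,
    kernel: str | None = None,
    normalize: bool = True,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Single-sample enrichment scores (pathways by samples).

    Per sample, genes are ranked (average ranks on ties; higher value =
    higher rank), optionally after a kernel-CDF transform.  Walking the
    ranking from top to bottom, the running sum gains rank^alpha (normalized
    over members) at member genes and loses 1/(G-m) at non-members; the score
    is the sum of the running sum over all positions.  With ``normalize`` the
    whole score matrix is divided by its max - min range.
    """
    if matrix.shape[0] < 2:
        raise AnalysisError("single-sample scoring needs at least 2 genes")
    work = matrix
    if use_kernel:
        if kernel not in ("poisson", "gaussian"):
            raise AnalysisError(
                f"use_kernel requires kernel 'poisson' or 'gaussian', "
                f"got {kernel!r}"
            )
        work = kernel_cdf_transform(matrix, kernel)
    X = work.to_numpy(dtype=float)
    g_total, n_samples = X.shape
    genes = list(work.index)
    gene_pos = {g: i for i, g in enumerate(genes)}

    usable = []
    for s in collection:
        idx = np.array(sorted(gene_pos[g] for g in s.members if g in gene_pos))
        if idx.size < max(min_set_size, 1):
            continue
        if idx.size == g_total:
            raise AnalysisError(
                f"set {s.id!r} covers the whole gene universe; the "
                "non-member decrement is undefined"
            )
        usable.append((s.id, idx))
    if not usable:
        return pd.DataFrame(columns=work.columns)

    scores = np.zeros((len(usable), n_samples))
    for j in range(n_samples):
        ranks = rankdata(X[:, j], method="average")
        # descending by rank; index as deterministic tie-break
        order = np.lexsort((np.arange(g_total), -ranks))
        r_ord = ranks[order]
        ra = np.abs(r_ord) ** alpha
        pos_of = np.empty(g_total, dtype=int)
        pos_of[order] = np.arange(g_total)
        for i, (_, idx) in enumerate(usable):
            m = idx.size
            member_mask = np.zeros(g_total, dtype=bool)
            member_mask[pos_of[idx]] = True
            w = np.where(member_mask, ra, 0.0)
            denom = w.sum()
            p_hit = np.cumsum(w) / denom
            p_miss = np.cumsum(~member_mask) / (g_total - m)
            scores[i, j] = float(np.sum(p_hit - p_miss))

    if normalize:
        rng_ = scores.max() - scores.min()
        if rng_ > 0:
            scores = scores / rng_
    return pd.DataFrame(
        scores, index=[sid for sid, _ in usable], columns=work.columns
    )
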