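# Methods

This note documents the statistical procedures implemented in `multigsa`,
the choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about behavior on real data.

## Data model and dispatch

A dataset is a genes-by-samples matrix with a *declared* data type. The type,
not the values, selects the processing branch:

| declared type | comparative methods (camera/padog) | single-sample (ssgsea) |
|---|---|---|
| RNA-seq raw counts, proteomics spectral counts | TMM scaling → log2 CPM → precision weights | raw values → Poisson kernel CDF |
| microarray intensity, normalized counts, proteomics intensity | between-sample normalization, unit weights | raw values → Gaussian kernel CDF |

Validation runs first and is side-effect free: group sizes (≥ 2 per group —
the minimum leaving at least one residual degree of freedom), value/type
consistency (counts non-negative; raw and spectral counts integral), and the
fraction of identifiers without a mapping entry (warning above 20%, hard
error above 90%; both configurable). A request that validates cleanly is
guaranteed to run through every downstream stage; this is property-tested on
100 random synthetic requests.

## Identifier mapping

One-to-many mappings are resolved at the pathway level: source gene *g*
belongs to mapped set *S* iff at least one of *g*'s targets is a member of
*S*, and it is added exactly once even when several targets land in the same
set. This bounds each mapped set's size by the number of distinct source
genes hitting it — identifier fan-out cannot inflate pathway statistics.
Mapping is case-sensitive; an optional pre-pass strips accession version
suffixes (off by default). The complementary direction (aggregating data
rows that share a target: sum for counts, mean for continuous values, max on
request) is provided for the case where several measured rows collapse onto
one target identifier.

Pathway extension adds interaction partners (at or above a medium/high
confidence tier) of *original* members only — one hop, so repeated
application grows by one hop each time and pathway boundaries stay
interpretable. Numeric interaction scores map to tiers at ≥ 0.45 (medium)
and ≥ 0.60 (high); both cutoffs are load-time parameters.

## Normalization

**TMM factors.** Reference column: 75th-percentile/total ratio closest to
the mean ratio (ties → lowest index). Per sample vs reference, over genes
positive in both: M = log2 ratio of proportions, A = mean log2 proportion;
rank-based double trimming removes the 30% tails of M and 5% tails of A;
the factor is 2^(weighted mean of surviving M) with inverse delta-method
binomial variances as weights; factors are rescaled to geometric mean 1.
Trim fractions and the log-CPM prior (0.5) are the published defaults of the
named procedures and are exposed in configuration. The implementation agrees
with an independently coded step-by-step oracle to < 1e-6 on random count
matrices, and with the reference R implementation to ~1e-12 on a spot-check.

**Precision weights.** Per-gene two-group fits on log-CPM give residual
standard deviations; sqrt(sd) is smoothed against mean log2 count by lowess
(span 0.5, constant extrapolation beyond the fitted range), the trend is
evaluated at each observation's fitted log-count, and the weight is
trend^(−4), floored at 1e-8 (and the trend itself at 1e-6) so weights stay
positive and finite. Fewer than 10 genes leaves the trend unestimable and is
an error.

**Continuous branch.** Quantile normalization by default (each column's
order statistics replaced by their across-sample means; ties receive the
average of the tied positions' means; constant columns are an error), with
`scale` (median equalization) and `none` as alternatives. log2 is
auto-applied to all-positive matrices spanning more than three orders of
magnitude; the flag can be forced either way.

## Gene-level model

Weighted least squares of the two-group contrast per gene (covariates are
accepted in the design container but not fitted — every comparison this
engine targets is two-group). The variance prior (d0, s0²) is fitted by
method of moments on log s²: the excess of the observed log-variance spread
over the chi-square sampling noise determines d0 through the inverse
trigamma function; no excess means complete shrinkage (d0 effectively
infinite, capped at 1e6). Posterior variances are the df-weighted convex
combination of s² and s0²; genes with zero sample variance take s0² alone so
no statistic is infinite. Moderated t is referred to a t distribution with
d + d0 degrees of freedom. In the no-moderation limit the machinery
reproduces the classical pooled-variance two-sample t to 1e-8.

## Pathway tests

**camera.** Mean pairwise correlation ρ̄ of member residuals (rows with zero
residual variance excluded; fewer than two usable rows → ρ̄ = 0) gives
VIF = 1 + (m−1)ρ̄, floored at 1 — a negative estimate may not deflate the
variance. Members vs non-members are compared by a pooled-variance
two-sample statistic divided by sqrt(VIF), with G−2 degrees of freedom.
Two-sided p; direction = sign of the member minus non-member mean.

**padog.** Gene weight w = 1 + sqrt((fmax−f)/(fmax−fmin)) over the genes
appearing in at least one analyzed set and in the data (w ≡ 1 when all f are
equal): the most promiscuously annotated gene weighs exactly 1, the least
exactly 2. Set score = mean member |moderated t|·w. Group labels are
permuted preserving group sizes; within every run the set scores are
standardized across sets (skipped when fewer than two sets or zero spread —
standardization is monotone, so the p-value is unaffected in that case).
p = (1 + #{permutation ≥ observed})/(n_perm + 1); when n_perm covers all
distinct label splits, all of them are enumerated instead (complementary
splits counted once for equal group sizes, since absolute statistics are
label-symmetric) and p = #{split ≥ observed}/#splits with the observed split
in the count — the test is then exact and seed-independent. The exceedance
comparison carries a 1e-9 tie guard: standardized scores are O(1), and runs
that reproduce the observed split must count as exceedances even when two
algebraically equal standardizations differ in the last float digit (with
two sets the standardization degenerates to ±1/√2, making exact ties
generic rather than measure-zero). Permutation statistics are computed for
all runs at once as a handful of matrix products, in blocks of 512
assignments, so tens of thousands of permutations are routine. Balancing
heuristics of the original down-weighting method's permutation scheme are
not reproduced; permutations here are unrestricted size-preserving label
permutations.

**ssgsea.** Per sample (or cluster): optional kernel-CDF transform — for
counts the average Poisson CDF with rates x_k + 0.5, for continuous data the
average Gaussian CDF with bandwidth sd/4 (floored at 1e-6 for constant
genes) — then ranks (average on ties; remaining order ties broken by gene
index for determinism), then a running sum that gains rank^α (normalized
over members) at members and loses 1/(G−m) at non-members, integrated over
all positions. α = 0.25, the published default. With `normalize` the score
matrix is divided by its max−min range. Without the kernel, scores depend on
ranks only and are invariant under strictly monotone per-sample transforms.
A set equal to the whole universe has an undefined miss decrement and is
rejected. Kernel choice follows the declared data type; rank-only behavior
(`use_kernel=False`) reproduces the classical single-sample procedure, and
both behaviors are exposed because upstream implementations differ in
whether the kernel step precedes single-sample scoring.

## Comparison and discordance

Per-dataset results are outer-joined on pathway id; BH FDR is recomputed
within each dataset over its own tested pathways (different datasets cover
different pathway subsets after mapping, so pooling would bias the
correction). Missing (pathway, dataset) combinations are explicit NaN, never
zero. A pathway is discordant between two datasets when FDR < threshold
(default 0.1) in both *and* the mean member log2 fold-changes have strictly
opposite signs; an exactly-zero mean fold-change counts as neither
direction. Direction comes from the mean member fold-change, not the test
statistic, and single-sample score matrices carry no direction — discordance
detection refuses them. The discordant set is by construction a subset of
the both-significant set, detection is symmetric in the two datasets, and
tightening the threshold never grows any of the sets.

## Single-cell scoring

Cluster profiles are the arithmetic per-gene mean over the cluster's cells,
taken on the matrix as provided: the engine does not guess whether the input
is raw or log-normalized, but warns when the maximum value is below 50
(typical of log-scale data). Pseudo-bulk conserves the size-weighted global
mean per gene. Scores are per-cluster single-sample scores; z-scoring is
per pathway across clusters with the sample (n−1) standard deviation
convention, constant rows mapping to zeros, and at least two clusters
required.

## Synthetic data

`simulate_bulk` draws negative-binomial counts with log-normal baseline
abundances (median ≈ 150 counts), 3-fold library-size variation, and
gene-wise dispersions log-normal around 0.1 — the mean-variance structure
the precision-weight step is designed for. Spiked sets shift their members'
expected counts by a stated log2 effect in the comparison group; remaining
sets are random. `simulate_gaussian` provides the calibration surface for
the test batteries: independent N(0,1) genes where a planted shift of 1.0 is
exactly one standard deviation and null sets are genuinely null.
`simulate_sc` draws Poisson counts with one active pathway per cluster
(rate × 5); its default is six clusters of 30 cells — a deliberately
scaled-down version of the ~10-cluster structure real cell typings produce,
and the smallest configuration in which "the active pathway ranks first in
its cluster's z-scored column" is identifiable (with two or three clusters
the per-pathway z-score saturates at ±(k−1)/√k regardless of effect size).
`simulate_mapping` controls the fan-out distribution to exercise the
one-to-many resolution rule. All simulators are pure functions of their
parameters and seed.

What passing these batteries shows: the statistics are implemented
correctly (oracle agreement), hold their nominal level under independence,
and recover effects of realistic size under the stated noise models. What
they do not show: robustness to batch structure, outlier samples,
compositional extremes, or the correlation patterns of real transcriptomes
— the generators model none of these.

## Problem sizes and resolution

The test batteries use 2000 genes, 200 sets of 20, and 5–10 samples per
group; these sizes make every battery run in minutes on one core while
keeping the set-level multiplicity realistic. One consequence worth noting:
a permutation p-value's floor is 1/(n_perm+1), so reaching BH FDR < 0.05
among 200 sets requires n_perm ≈ 4000 at minimum; the recovery battery runs
the permutation test at n_perm = 9999 (p floor 1e-4, BH floor 0.02), while
500 permutations remain the default for exploratory use.

## Determinism

One request seed drives everything: stage k of a fit derives its seed from
the master seed through an independent seed-sequence spawn key, so adding or
reordering datasets never silently changes another dataset's permutation
stream. All floating-point TSV output is written at 6 significant digits,
making byte-identity of repeated runs a meaningful (and tested) contract.

## Known limitations

- Only two-group contrasts are fitted; no multi-factor designs, no
  continuous covariates, no batch correction.
- The competitive test uses the documented mean-residual-correlation VIF
  formulation, not a QR-decomposition-based estimator; on strongly
  structured correlation the two can differ.
- The permutation test's label permutations are unrestricted within group
  sizes (no balancing heuristics).
- The empirical-Bayes prior fit assumes a common residual df across genes
  (true here by construction, as no missing values are modeled).
- GMT descriptions are preserved but not interpreted; pathway hierarchies
  and overlaps beyond membership counts are not modeled.
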