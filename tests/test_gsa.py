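"""The three pathway test methods against hand-built and brute-force oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats as sps

from multigsa import (
    AnalysisError,
    DataType,
    GeneSet,
    GeneSetCollection,
    bh_fdr,
    camera_test,
    dispatch,
    fit_gene_models,
    kernel_cdf_transform,
    padog_test,
    ssgsea_scores,
)
from multigsa.gsa import padog_gene_weights

from conftest import make_dataset


# ---------------------------------------------------------------------------
# brute-force PADOG oracle: exhaustive label splits, statistics recomputed
# from the documented formulas with plain loops
# ---------------------------------------------------------------------------

def _oracle_moderated_t(y, z):
    """Moderated t per gene for one 0/1 assignment (unit weights)."""
    n1 = int(z.sum())
    n0 = len(z) - n1
    g = y.shape[0]
    df = y.shape[1] - 2
    fc = np.empty(g)
    s2 = np.empty(g)
    for i in range(g):
        a = y[i, z == 1]
        b = y[i, z == 0]
        fc[i] = a.mean() - b.mean()
        s2[i] = (
            ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        ) / df
    # moments of log variances -> scaled inverse-chi-square prior
    zlog = np.log(s2[s2 > 0])
    e = zlog - special.digamma(df / 2) + np.log(df / 2)
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2)
    if e_var > 0:
        # invert trigamma by bisection (deliberately different from the
        # package's Newton iteration)
        lo, hi = 1e-6, 1e8
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if special.polygamma(1, mid) > e_var:
                lo = mid
            else:
                hi = mid
        d0 = 2 * np.sqrt(lo * hi)
        s0 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        d0 = 1e6
        s0 = np.exp(e.mean())
    post = np.where(s2 > 0, (d0 * s0 + df * s2) / (d0 + df), s0)
    se = np.sqrt(1.0 / n1 + 1.0 / n0)
    return fc / (np.sqrt(post) * se)


def padog_oracle(y, z_obs, sets, membership_count):
    """Exhaustive-permutation PADOG p-values on a small two-group toy."""
    genes = list(range(y.shape[0]))
    f = np.array([membership_count[g] for g in genes], float)
    fmax, fmin = f.max(), f.min()
    if fmax == fmin:
        w = np.ones_like(f)
    else:
        w = 1 + np.sqrt((fmax - f) / (fmax - fmin))

    n = y.shape[1]
    n1 = int(z_obs.sum())
    splits = []
    if 2 * n1 == n:
        for rest in combinations(range(1, n), n1 - 1):
            z = np.zeros(n)
            z[[0, *rest]] = 1
            splits.append(z)
    else:
        for chosen in combinations(range(n), n1):
            z = np.zeros(n)
            z[list(chosen)] = 1
            splits.append(z)

    def set_scores(z):
        t_abs = np.abs(_oracle_moderated_t(y, z))
        raw = np.array(
            [np.mean([t_abs[g] * w[g] for g in members]) for members in sets]
        )
        if len(raw) >= 2 and raw.std(ddof=1) > 0:
            return (raw - raw.mean()) / raw.std(ddof=1)
        return raw

    obs = set_scores(z_obs)
    counts = np.zeros(len(sets))
    for z in splits:
        # same tie-guard convention as the engine: an exceedance within
        # 1e-9 of the observed standardized score counts
        counts += set_scores(z) >= obs - 1e-9
    return counts / len(splits)


@pytest.fixture
def padog_toy():
    rng = np.random.default_rng(17)
    y = rng.normal(size=(6, 8))
    y[0:3, 4:] += 1.2  # genes of the first set respond
    ds = make_dataset(y, DataType.MICROARRAY_INTENSITY, "padog_toy")
    coll = GeneSetCollection(
        [
            GeneSet("S1", "responding", frozenset({"g0", "g1", "g2"})),
            GeneSet("S2", "flat", frozenset({"g3", "g4", "g5"})),
        ]
    )
    return ds, coll


class TestPadog:
    def test_weight_endpoints(self):
        w = padog_gene_weights({"a": 5, "b": 1, "c": 3}, ["a", "b", "c"])
        assert w["a"] == pytest.approx(1.0)  # most frequently annotated
        assert w["b"] == pytest.approx(2.0)  # least frequently annotated
        assert 1.0 < w["c"] < 2.0

    def test_equal_membership_means_unit_weights(self):
        w = padog_gene_weights({"a": 2, "b": 2}, ["a", "b"])
        assert (w == 1.0).all()

    def test_exhaustive_p_equals_brute_force_oracle(self, padog_toy):
        ds, coll = padog_toy
        norm = dispatch(ds, "padog", continuous_method="none")
        res = padog_test(norm, None, coll, n_perm=100, seed=0)
        # 2x4 samples -> C(8,4)/2 = 35 distinct splits; n_perm=100 >= 35
        # triggers exact enumeration
        y = norm.matrix.to_numpy()
        z = norm.design.group_vector(list(norm.matrix.columns))
        sets = [[0, 1, 2], [3, 4, 5]]
        mc = {i: 1 for i in range(6)}
        expected = padog_oracle(y, z, sets, mc)
        assert res.table.loc["S1", "p"] == expected[0]
        assert res.table.loc["S2", "p"] == expected[1]
        assert 0 < res.table.loc["S1", "p"] <= 1

    def test_exact_p_is_seed_invariant(self, padog_toy):
        ds, coll = padog_toy
        norm = dispatch(ds, "padog", continuous_method="none")
        p1 = padog_test(norm, None, coll, n_perm=500, seed=1).table["p"]
        p2 = padog_test(norm, None, coll, n_perm=500, seed=999).table["p"]
        pd.testing.assert_series_equal(p1, p2)

    def test_direction_follows_mean_member_fold_change(self, padog_toy):
        ds, coll = padog_toy
        norm = dispatch(ds, "padog", continuous_method="none")
        res = padog_test(norm, None, coll, n_perm=100, seed=0)
        assert res.table.loc["S1", "direction"] == "up"

    def test_pathway_order_permutation_permutes_results(self, padog_toy):
        ds, coll = padog_toy
        norm = dispatch(ds, "padog", continuous_method="none")
        res = padog_test(norm, None, coll, n_perm=100, seed=0)
        rev = GeneSetCollection(list(coll)[::-1])
        res2 = padog_test(norm, None, rev, n_perm=100, seed=0)
        pd.testing.assert_frame_equal(
            res.table.sort_index(), res2.table.sort_index()
        )


class TestCamera:
    def _stats(self, matrix):
        ds = make_dataset(matrix, DataType.MICROARRAY_INTENSITY)
        norm = dispatch(ds, "camera", continuous_method="none")
        return fit_gene_models(norm)

    def test_singleton_set_has_unit_vif_and_is_testable(self):
        rng = np.random.default_rng(8)
        st = self._stats(rng.normal(size=(50, 8)))
        coll = GeneSetCollection([GeneSet("ONE", "d", frozenset({"g0"}))])
        res = camera_test(st, coll, min_set_size=1)
        assert res.table.loc["ONE", "p"] > 0  # VIF floor keeps it defined

    def test_spiked_set_detected_with_direction_up(self):
        rng = np.random.default_rng(9)
        m = rng.normal(size=(200, 12))
        m[:10, 6:] += 1.5
        st = self._stats(m)
        coll = GeneSetCollection(
            [
                GeneSet("SPIKE", "d", frozenset(f"g{i}" for i in range(10))),
                GeneSet("NULL", "d", frozenset(f"g{i}" for i in range(20, 30))),
            ]
        )
        res = camera_test(st, coll)
        assert res.table.loc["SPIKE", "p"] < 1e-4
        assert res.table.loc["SPIKE", "direction"] == "up"
        assert res.table.loc["NULL", "p"] > 0.01

    def test_correlated_set_is_penalized_by_vif(self):
        # the same mean shift is less significant when members are correlated
        rng = np.random.default_rng(10)
        base = rng.normal(size=(300, 20))
        shared = rng.normal(size=20) * 2.0
        correlated = base.copy()
        correlated[:15] = base[:15] * 0.3 + shared[None, :]
        for m in (base, correlated):
            m[:15, 10:] += 0.8
        coll = GeneSetCollection(
            [GeneSet("S", "d", frozenset(f"g{i}" for i in range(15)))]
        )
        p_indep = camera_test(self._stats(base), coll).table.loc["S", "p"]
        p_corr = camera_test(self._stats(correlated), coll).table.loc["S", "p"]
        assert p_corr > p_indep

    def test_small_sets_skipped_and_logged(self):
        rng = np.random.default_rng(11)
        st = self._stats(rng.normal(size=(50, 8)))
        coll = GeneSetCollection(
            [GeneSet("TINY", "d", frozenset({"g0", "g1"}))]
        )
        res = camera_test(st, coll, min_set_size=3)
        assert "TINY" in res.skipped
        assert len(res.table) == 0


class TestKernelCdf:
    def test_single_sample_gaussian_is_half(self):
        m = pd.DataFrame({"s1": [3.0, -1.0, 7.5]})
        out = kernel_cdf_transform(m, "gaussian")
        np.testing.assert_allclose(out.to_numpy(), 0.5)

    def test_monotone_in_the_observed_values(self):
        m = pd.DataFrame([[1.0, 4.0, 9.0, 16.0]])
        out = kernel_cdf_transform(m, "gaussian").to_numpy()[0]
        assert (np.diff(out) > 0).all()
        c = pd.DataFrame([[0.0, 3.0, 8.0, 20.0]])
        outp = kernel_cdf_transform(c, "poisson").to_numpy()[0]
        assert (np.diff(outp) > 0).all()

    def test_poisson_matches_direct_summation_oracle(self):
        counts = [0.0, 5.0, 10.0]
        m = pd.DataFrame([counts])
        out = kernel_cdf_transform(m, "poisson", rate_prior=0.5).to_numpy()[0]
        for j, x in enumerate(counts):
            expected = np.mean(
                [sps.poisson.cdf(x, mu=xk + 0.5) for xk in counts]
            )
            assert out[j] == pytest.approx(expected, abs=1e-10)

    def test_poisson_kernel_rejects_non_integers(self):
        m = pd.DataFrame([[0.5, 1.2, 3.0]])
        with pytest.raises(AnalysisError, match="integer"):
            kernel_cdf_transform(m, "poisson")

    def test_output_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.poisson(5, size=(10, 6)).astype(float))
        out = kernel_cdf_transform(m, "poisson").to_numpy()
        assert ((out > 0) & (out < 1)).all()


class TestSsgsea:
    def test_hand_computed_telescoping_sum_alpha_zero(self):
        # 4 genes, set = the top-ranked gene, alpha = 0: running sum is
        # [1, 2/3, 1/3, 0] -> integrated score 2
        m = pd.DataFrame(
            {"s": [10.0, 7.0, 5.0, 1.0]}, index=["a", "b", "c", "d"]
        )
        coll = GeneSetCollection([GeneSet("TOP", "d", frozenset({"a"}))])
        out = ssgsea_scores(m, coll, alpha=0.0, normalize=False)
        assert out.loc["TOP", "s"] == pytest.approx(2.0, abs=1e-10)

    def test_hand_computed_weighted_sum_alpha_one(self):
        # ranks: a=4, b=3, c=2, d=1; set {a, c}, alpha=1:
        # hit increments 4/6 at position 1 and 2/6 at position 3;
        # miss decrement 1/2 at positions 2 and 4
        # running: [2/3, 2/3-1/2, 2/3-1/2+1/3, 0] = [2/3, 1/6, 1/2, 0]
        m = pd.DataFrame(
            {"s": [10.0, 7.0, 5.0, 1.0]}, index=["a", "b", "c", "d"]
        )
        coll = GeneSetCollection([GeneSet("AC", "d", frozenset({"a", "c"}))])
        out = ssgsea_scores(m, coll, alpha=1.0, normalize=False)
        assert out.loc["AC", "s"] == pytest.approx(
            2 / 3 + 1 / 6 + 1 / 2 + 0, abs=1e-10
        )

    def test_identical_samples_get_identical_scores(self, toy_collection):
        rng = np.random.default_rng(13)
        col = rng.normal(size=20)
        m = pd.DataFrame(
            {"s1": col, "s2": col}, index=[f"g{i}" for i in range(20)]
        )
        out = ssgsea_scores(m, toy_collection)
        np.testing.assert_allclose(out["s1"], out["s2"])

    def test_top_ranked_set_beats_bottom_ranked_set_everywhere(self):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(
            np.sort(rng.normal(size=(20, 5)), axis=0)[::-1],
            index=[f"g{i}" for i in range(20)],
        )
        coll = GeneSetCollection(
            [
                GeneSet("TOP", "d", frozenset(f"g{i}" for i in range(4))),
                GeneSet("BOT", "d", frozenset(f"g{i}" for i in range(16, 20))),
            ]
        )
        out = ssgsea_scores(m, coll, normalize=False)
        assert (out.loc["TOP"] > out.loc["BOT"]).all()

    def test_rank_only_scores_invariant_under_monotone_transform(
        self, toy_collection
    ):
        rng = np.random.default_rng(15)
        m = pd.DataFrame(
            rng.normal(size=(20, 4)), index=[f"g{i}" for i in range(20)]
        )
        a = ssgsea_scores(m, toy_collection, use_kernel=False)
        b = ssgsea_scores(
            np.exp(m) + 3.0, toy_collection, use_kernel=False
        )
        pd.testing.assert_frame_equal(a, b)

    def test_whole_universe_set_is_an_error(self):
        m = pd.DataFrame(
            np.arange(8, dtype=float).reshape(4, 2),
            index=["a", "b", "c", "d"],
        )
        coll = GeneSetCollection(
            [GeneSet("ALL", "d", frozenset({"a", "b", "c", "d"}))]
        )
        with pytest.raises(AnalysisError, match="universe"):
            ssgsea_scores(m, coll)


class TestBhFdr:
    def test_single_p_passes_through(self):
        np.testing.assert_allclose(bh_fdr([0.05]), [0.05])

    def test_hand_step_up_computation(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all()
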