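"""Blomberg's K, Pagel's λ, Moran's I and Mantel tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phycosignal as ps

# ---------------------------------------------------------------------------
# frozen cross-package oracle: a fixed 10-tip branch-jittered Yule tree and a
# BM trait vector, with statistics independently computed by the R packages
# picante (Kcalc), phytools (phylosig) and ape (mantel.test)

ORACLE_NEWICK = (
    "(((s01:0.05416399208465267,s02:0.06173139601836081):0.6223502385930837,"
    "s03:0.5543710509404646):0.503536330560854,(((s04:0.4787312522127929,"
    "(s05:0.24041677307094517,s06:0.22294656947573757):0.41776415201280587)"
    ":0.17334646767454354,(s07:0.4101069823428279,s08:0.5096807571164901)"
    ":0.2752545130980746):0.5969761440290802,(s09:0.8654132364236614,"
    "s10:0.5612267591973599):0.12305927857384191):0.03041835050096186);"
)
ORACLE_TRAITS = {
    "s01": 1.3819882254214848, "s02": 0.9701670494310335,
    "s03": -0.19759318267580306, "s04": 0.8416451975201449,
    "s05": -0.10102532913552698, "s06": -0.9146730131311971,
    "s07": 0.6177163771093234, "s08": 0.4345271242782721,
    "s09": 0.8375028780231943, "s10": -0.08124757255563202,
}
ORACLE_K_PICANTE = 0.559619          # picante::Kcalc
ORACLE_LAMBDA_PHYTOOLS = 7.33e-05    # phytools::phylosig(method="lambda")$lambda
ORACLE_LOGL_PHYTOOLS = -9.775692     # ...$logL at that lambda
ORACLE_MANTEL_Z_APE = 72.16          # ape::mantel.test z.stat


@pytest.fixture
def oracle_case():
    tree = ps.parse_newick(ORACLE_NEWICK)
    x = pd.Series(ORACLE_TRAITS)
    return tree, x


class TestBlombergK:
    def test_equal_branch_star_gives_exactly_one(self, star_tree):
        x = [0.3, -1.2, 2.0, 0.7, -0.4]
        assert ps.blomberg_k(star_tree, x) == pytest.approx(1.0, abs=1e-12)

    def test_three_tip_hand_linear_algebra(self, three_tip_tree):
        x = np.array([1.0, 1.0, -2.0])
        # oracle: explicit dense evaluation of the K formula on the known C
        c = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        cinv = np.linalg.inv(c)
        one = np.ones(3)
        ahat = one @ cinv @ x / (one @ cinv @ one)
        dev = x - ahat
        ratio = (dev @ dev) / (dev @ cinv @ dev)
        expected_ratio = (np.trace(c) - 3 / (one @ cinv @ one)) / 2
        k_oracle = ratio / expected_ratio
        xs = pd.Series(x, index=["A", "B", "C"])
        assert ps.blomberg_k(three_tip_tree, xs) == pytest.approx(k_oracle, rel=1e-12)

    def test_matches_picante(self, oracle_case):
        tree, x = oracle_case
        assert ps.blomberg_k(tree, x) == pytest.approx(ORACLE_K_PICANTE, abs=5e-7)

    def test_bm_expectation_near_one(self, yule59):
        ks = [
            ps.blomberg_k(yule59, ps.simulate_traits(yule59, model="BM", seed=s))
            for s in range(500)
        ]
        assert 0.85 <= np.mean(ks) <= 1.15

    def test_constant_trait_rejected(self, star_tree):
        with pytest.raises(ValueError):
            ps.blomberg_k(star_tree, [1.0] * 5)


class TestBlombergKPvalue:
    def test_strong_signal_detected(self, yule59):
        hits = 0
        for s in range(100):
            x = ps.simulate_traits(yule59, model="BM", seed=1000 + s)
            _, p = ps.blomberg_k_pvalue(yule59, x, n_rand=199, seed=s)
            hits += p <= 0.05
        assert hits >= 90

    def test_null_p_super_uniform(self, star_tree):
        # iid data on a star tree: P(p <= a) must not exceed a (plus MC noise)
        big_star = ps.parse_newick(
            "(" + ",".join(f"t{i}:1" for i in range(20)) + ");")
        rng = np.random.default_rng(0)
        pvals = []
        for s in range(200):
            x = rng.standard_normal(20)
            _, p = ps.blomberg_k_pvalue(big_star, x, n_rand=199, seed=s)
            pvals.append(p)
        pvals = np.array(pvals)
        for a in (0.05, 0.25, 0.5):
            assert np.mean(pvals <= a) <= a + 3 * np.sqrt(a * (1 - a) / 200)

    def test_seed_reproducibility(self, yule59):
        x = ps.simulate_traits(yule59, model="BM", seed=5)
        r1 = ps.blomberg_k_pvalue(yule59, x, n_rand=99, seed=42)
        r2 = ps.blomberg_k_pvalue(yule59, x, n_rand=99, seed=42)
        assert r1 == r2

    def test_invalid_n_rand(self, yule59):
        x = ps.simulate_traits(yule59, model="BM", seed=5)
        with pytest.raises(ValueError):
            ps.blomberg_k_pvalue(yule59, x, n_rand=0)


class TestPagelLambda:
    def test_matches_dense_grid_search(self, yule50):
        from phycosignal.models import gls_profile_loglik
        from phycosignal.trees import transform_covariance

        x = ps.simulate_traits(yule50, model="BM", seed=21)
        lam_hat, ll_hat, _ = ps.pagel_lambda_ml(yule50, x)
        c = yule50.covariance()
        v = x.reindex(yule50.tip_labels).to_numpy()
        grid = np.linspace(0, 1, 1001)
        lls = [gls_profile_loglik(v, transform_covariance(c, "lambda", g).to_numpy())[0]
               for g in grid]
        assert lam_hat == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)
        assert ll_hat >= max(lls) - 1e-9

    def test_matches_phytools(self, oracle_case):
        tree, x = oracle_case
        lam_hat, ll_hat, _ = ps.pagel_lambda_ml(tree, x)
        assert lam_hat == pytest.approx(ORACLE_LAMBDA_PHYTOOLS, abs=1e-3)
        # our maximised likelihood must not fall below the phytools optimum
        assert ll_hat >= ORACLE_LOGL_PHYTOOLS - 1e-4

    def test_iid_data_lambda_near_zero(self):
        # deep balanced tree: strong shared history that iid data contradicts
        nw = "((((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1):1," \
             "(((i:1,j:1):1,(k:1,l:1):1):1,((m:1,n:1):1,(o:1,p:1):1):1):1);"
        tree = ps.parse_newick(nw)
        rng = np.random.default_rng(1)
        lams = []
        for _ in range(200):
            x = pd.Series(rng.standard_normal(16), index=tree.tip_labels)
            lams.append(ps.pagel_lambda_ml(tree, x)[0])
        assert np.median(lams) < 0.2

    def test_loglik_at_optimum_not_below_null(self, yule50):
        from phycosignal.models import shape_loglik

        for s in range(10):
            x = ps.simulate_traits(yule50, model="WN", seed=s)
            lam_hat, ll_hat, p = ps.pagel_lambda_ml(yule50, x)
            assert ll_hat >= shape_loglik(yule50, x, "lambda", 0.0) - 1e-9
            assert 0 < p <= 1


class TestMoranI:
    def test_two_tips_always_minus_one(self):
        tree = ps.parse_newick("(A:1,B:2);")
        from phycosignal.signal import _moran_stat

        # any symmetric positive weights, any non-constant x: deviations are
        # ±z so the cross product is exactly -z², giving I = -1
        for x in ([0.0, 1.0], [5.0, -3.0]):
            w = np.array([[0.0, 0.7], [0.7, 0.0]])
            assert _moran_stat(np.array(x), w) == pytest.approx(-1.0, abs=1e-12)

    def test_permutation_mean_matches_expectation(self, three_tip_tree):
        # exhaustive permutation oracle: mean of I over all 3! relabelings
        from phycosignal.signal import _moran_stat

        d = three_tip_tree.cophenetic_distances().to_numpy()
        w = np.where(d > 0, 1.0 / np.where(d > 0, d, 1), 0.0)
        x = np.array([0.1, 1.7, -0.9])
        vals = [_moran_stat(x[list(p)], w) for p in itertools.permutations(range(3))]
        assert np.mean(vals) == pytest.approx(-1 / 2, rel=1e-10)

    def test_seed_reproducibility(self, yule50):
        x = ps.simulate_traits(yule50, model="BM", seed=3)
        assert ps.moran_i(yule50, x, n_rand=99, seed=7) == \
            ps.moran_i(yule50, x, n_rand=99, seed=7)

    def test_zero_distance_rejected(self):
        tree = ps.parse_newick("((A:0,B:0):1,C:2);")
        with pytest.raises(ValueError):
            ps.moran_i(tree, pd.Series({"A": 1.0, "B": 2.0, "C": 3.0}), n_rand=9)


class TestTraitDistance:
    def test_hand_values(self):
        d = ps.euclidean_trait_distance(pd.Series([0.0, 3.0, 4.0],
                                                  index=["a", "b", "c"]))
        assert d.loc["a", "b"] == 3 and d.loc["a", "c"] == 4 and d.loc["b", "c"] == 1
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.all(np.diag(d.to_numpy()) == 0)

    @given(shift=st.floats(min_value=-50, max_value=50))
    def test_translation_invariance(self, shift):
        x = pd.Series([0.5, -1.0, 2.0, 0.0], index=list("abcd"))
        d1 = ps.euclidean_trait_distance(x)
        d2 = ps.euclidean_trait_distance(x + shift)
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-9)


class TestMantel:
    def test_zero_matrix_gives_zero_statistic(self):
        labels = list("abcd")
        m1 = pd.DataFrame(np.random.default_rng(0).random((4, 4)),
                          index=labels, columns=labels)
        m1 = (m1 + m1.T) / 2
        np.fill_diagonal(m1.values, 0)
        m2 = pd.DataFrame(np.zeros((4, 4)), index=labels, columns=labels)
        assert ps.mantel_test(m1, m2, n_perm=9, seed=0).z_stat == 0.0

    def test_exhaustive_four_species_p(self):
        # m1 = m2 with all-distinct entries: the identity permutation is the
        # unique maximiser of the cross-product (rearrangement inequality),
        # so with all 24 relabelings the exact one-tailed p is 1/24
        labels = list("abcd")
        a = np.zeros((4, 4))
        vals = iter([1.0, 2.0, 3.0, 4.5, 5.5, 7.0])
        for i in range(4):
            for j in range(i + 1, 4):
                a[i, j] = a[j, i] = next(vals)
        m = pd.DataFrame(a, index=labels, columns=labels)
        iu = np.triu_indices(4, 1)
        z_obs = float(a[iu] @ a[iu])
        z_perm = []
        for p in itertools.permutations(range(4)):
            ap = a[np.ix_(p, p)]
            z_perm.append(float(a[iu] @ ap[iu]))
        assert sum(z >= z_obs for z in z_perm) == 1  # unique maximum
        res = ps.mantel_test(m, m, n_perm=4999, seed=11)
        assert res.p == pytest.approx(1 / 24, abs=0.015)

    def test_matches_ape_statistic(self, oracle_case):
        tree, x = oracle_case
        pdm = tree.cophenetic_distances()
        td = ps.euclidean_trait_distance(x.reindex(tree.tip_labels))
        res = ps.mantel_test(pdm, td, n_perm=9, seed=0)
        assert res.z_stat == pytest.approx(ORACLE_MANTEL_Z_APE, abs=5e-3)

    def test_seed_reproducibility_and_label_check(self):
        labels = list("abcde")
        rng = np.random.default_rng(3)
        a = rng.random((5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        m1 = pd.DataFrame(a, index=labels, columns=labels)
        m2 = m1 * 2
        assert ps.mantel_test(m1, m2, seed=9) == ps.mantel_test(m1, m2, seed=9)
        m3 = m2.rename(index={"a": "z"}, columns={"a": "z"})
        with pytest.raises(ValueError):
            ps.mantel_test(m1, m3)


class TestAffineInvariance:
    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_signal_statistics_affine_invariant(self, a, b):
        tree = ps.generate_tree(15, seed=77)
        x = ps.simulate_traits(tree, model="BM", seed=8)
        y = a * x + b
        assert ps.blomberg_k(tree, y) == pytest.approx(ps.blomberg_k(tree, x),
                                                       rel=1e-8)
        assert ps.pagel_lambda_ml(tree, y)[0] == pytest.approx(
            ps.pagel_lambda_ml(tree, x)[0], abs=1e-5)
        i1, _ = ps.moran_i(tree, y, n_rand=1, seed=0)
        i0, _ = ps.moran_i(tree, x, n_rand=1, seed=0)
        assert i1 == pytest.approx(i0, rel=1e-8)
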