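import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mstscan import (DegenerateTraitSetError, UntestableSNPError,
                     genotype_dummies, mst, pillai_df, ust)
from mstscan.scale_tests import ust_from_sscp


def random_instance(rng, n, K, maf=0.3):
    """Random (D, dummies, L) with a polymorphic genotype vector."""
    while True:
        g = rng.binomial(2, maf, n).astype(float)
        if np.unique(g).size >= 2:
            break
    dummies, L = genotype_dummies(g)
    D = rng.gamma(shape=1.5, scale=1.0, size=(n, K))
    return g, D, dummies, L


class TestGenotypeDummies:
    def test_three_group_coding(self):
        dummies, L = genotype_dummies(np.array([0.0, 1.0, 2.0]))
        assert L == 3
        np.testing.assert_array_equal(dummies, [[0, 0], [1, 0], [0, 1]])

    def test_two_group_single_dummy(self):
        dummies, L = genotype_dummies(np.array([0.0, 0.0, 1.0, 1.0]))
        assert L == 2
        np.testing.assert_array_equal(dummies[:, 0], [0, 0, 1, 1])

    def test_monomorphic_untestable(self):
        with pytest.raises(UntestableSNPError):
            genotype_dummies(np.array([2.0, 2.0, 2.0]))

    def test_reference_is_lowest_observed_without_homref(self):
        dummies, L = genotype_dummies(np.array([1.0, 2.0, 2.0, 1.0]))
        assert L == 2
        np.testing.assert_array_equal(dummies[:, 0], [0, 1, 1, 0])


class TestPillaiDf:
    def test_single_trait_three_groups(self):
        s, t, u, df1, df2 = pillai_df(K=1, L=3, n=100)
        assert (s, df1, df2) == (1, 2, 97)  # df2 == n - L, the univariate df4

    def test_four_traits_three_groups(self):
        s, t, u, df1, df2 = pillai_df(K=4, L=3, n=1000)
        assert s == 2 and t == 0.5
        assert df1 == 8
        assert df2 == 2 * (2 * u + 3) and u == (1000 - 3 - 4 - 1) / 2

    def test_s_is_min_of_K_and_groups(self):
        assert pillai_df(K=3, L=2, n=50)[0] == 1

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError):
            pillai_df(K=3, L=3, n=7)


class TestMST:
    def test_matches_hand_coded_sscp_oracle(self, rng):
        # independent oracle: explicit group-mean predictions and loops
        n, K = 12, 2
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2], dtype=float)
        dummies, L = genotype_dummies(g)
        D = rng.gamma(2.0, 1.0, size=(n, K))

        grand = D.mean(axis=0)
        S0 = np.zeros((K, K))
        S1 = np.zeros((K, K))
        for i in range(n):
            r0 = D[i] - grand
            r1 = D[i] - D[g == g[i]].mean(axis=0)
            S0 += np.outer(r0, r0)
            S1 += np.outer(r1, r1)
        V = np.trace((S0 - S1) @ np.linalg.inv(S0))
        s, t, u, df1, df2 = pillai_df(K, L, n)
        F = (V / (s - V)) * (df2 / df1)
        p = stats.f.sf(F, df1, df2)

        res = mst(D, dummies, L, n)
        assert res.V == pytest.approx(V, rel=1e-10)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)
        np.testing.assert_allclose(res.Sigma0, S0, rtol=1e-10)
        np.testing.assert_allclose(res.Sigma1, S1, rtol=1e-10)

    def test_manova_oracle_equivalence(self, rng):
        from statsmodels.multivariate.manova import MANOVA
        for _ in range(12):
            n = int(rng.integers(40, 200))
            K = int(rng.integers(2, 5))
            g, D, dummies, L = random_instance(rng, n, K)
            res = mst(D, dummies, L, n)
            df = pd.DataFrame(D, columns=[f"d{k}" for k in range(K)])
            df["g"] = g
            lhs = " + ".join(df.columns[:-1])
            tab = MANOVA.from_formula(f"{lhs} ~ C(g)", data=df).mv_test()
            row = tab.results["C(g)"]["stat"].loc["Pillai's trace"]
            assert res.V == pytest.approx(float(row["Value"]), rel=1e-8)
            assert res.F == pytest.approx(float(row["F Value"]), rel=1e-8)
            assert res.df1 == pytest.approx(float(row["Num DF"]), rel=1e-12)
            assert res.df2 == pytest.approx(float(row["Den DF"]), rel=1e-12)
            assert res.p == pytest.approx(float(row["Pr > F"]), abs=1e-10)

    def test_identical_group_multisets_give_no_signal(self, rng):
        block = rng.gamma(2.0, 1.0, size=(5, 3))
        D = np.vstack([block, block, block])  # same multiset in each group
        g = np.repeat([0.0, 1.0, 2.0], 5)
        dummies, L = genotype_dummies(g)
        res = mst(D, dummies, L, 15)
        assert res.V == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-8)

    def test_sigma0_minus_sigma1_positive_semidefinite(self, rng):
        for _ in range(10):
            g, D, dummies, L = random_instance(rng, 60, 3)
            res = mst(D, dummies, L, 60)
            eig = np.linalg.eigvalsh(res.Sigma0 - res.Sigma1)
            assert eig.min() > -1e-8 * np.abs(eig).max()
            assert 0 <= res.V <= res.s

    def test_duplicated_trait_degenerate(self, rng):
        g, D, dummies, L = random_instance(rng, 50, 2)
        D2 = np.column_stack([D[:, 0], D[:, 0]])
        with pytest.raises(DegenerateTraitSetError):
            mst(D2, dummies, L, 50)

    def test_scale_invariance(self, rng):
        g, D, dummies, L = random_instance(rng, 80, 3)
        base = mst(D, dummies, L, 80)
        for c in (1e-6, 3.7, 1e6):
            scaled = mst(c * D, dummies, L, 80)
            assert scaled.V == pytest.approx(base.V, rel=1e-9)
            assert scaled.F == pytest.approx(base.F, rel=1e-9)
            assert scaled.p == pytest.approx(base.p, rel=1e-9)

    def test_null_type_one_error_calibrated(self, rng):
        # Gaussian-squared dispersion surrogate with no group effect
        reps, n, K, alpha = 2000, 90, 3, 0.05
        hits = 0
        for _ in range(reps):
            g, _, dummies, L = random_instance(rng, n, K)
            D = rng.standard_normal((n, K)) ** 2
            if mst(D, dummies, L, n).p < alpha:
                hits += 1
        ci = 2.576 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(hits / reps - alpha) < ci

    def test_monotone_evidence_in_effect_size(self, rng):
        # stronger genotype-dependent variance never lowers the median V
        n = 300
        multipliers = [1.0, 1.5, 2.5]
        medians = []
        for mult in multipliers:
            Vs = []
            for _ in range(300):
                g = rng.binomial(2, 0.3, n).astype(float)
                if np.unique(g).size < 2:
                    continue
                dummies, L = genotype_dummies(g)
                sd = 1.0 + (mult - 1.0) * g / 2.0
                e = rng.standard_normal((n, 2)) * sd[:, None]
                D = (e - np.median(e, axis=0)) ** 2
                Vs.append(mst(D, dummies, L, n).V)
            medians.append(np.median(Vs))
        assert medians[0] <= medians[1] <= medians[2]


class TestUST:
    def test_equals_anova_oracle(self, rng):
        for _ in range(10):
            g, D, dummies, L = random_instance(rng, 30, 1)
            d = D[:, 0]
            res = ust(d, dummies, L, 30)
            groups = [d[g == lvl] for lvl in np.unique(g)]
            f_ref, p_ref = stats.f_oneway(*groups)
            assert res.F == pytest.approx(f_ref, rel=1e-10)
            assert res.p == pytest.approx(p_ref, rel=1e-8)
            assert res.df3 == L - 1 and res.df4 == 30 - L

    def test_constant_dispersion_no_evidence(self):
        g = np.repeat([0.0, 1.0, 2.0], 4)
        dummies, L = genotype_dummies(g)
        res = ust(np.full(12, 3.0), dummies, L, 12)
        assert res.F == 0.0 and res.p == 1.0

    def test_zero_within_group_ss_degenerate(self):
        g = np.repeat([0.0, 1.0, 2.0], 4)
        dummies, L = genotype_dummies(g)
        res = ust(g.copy(), dummies, L, 12)  # dispersion == group indicator
        assert res.degenerate and res.p == 0.0

    def test_from_sscp_matches_standalone(self, rng):
        g, D, dummies, L = random_instance(rng, 70, 3)
        m = mst(D, dummies, L, 70)
        for k, via_sscp in enumerate(ust_from_sscp(m)):
            direct = ust(D[:, k], dummies, L, 70, trait_index=k)
            assert via_sscp.F == pytest.approx(direct.F, rel=1e-10)
            assert via_sscp.p == pytest.approx(direct.p, rel=1e-10)


class TestSingleTraitReduction:
    def test_mst_equals_ust_when_K_is_one(self, rng):
        # algebraic identity: V/(s-V) == (S0-S1)/S1 when K == 1
        for _ in range(25):
            n = int(rng.integers(20, 500))
            g, D, dummies, L = random_instance(rng, n, 1)
            m = mst(D, dummies, L, n)
            u = ust(D[:, 0], dummies, L, n)
            assert m.F == pytest.approx(u.F, rel=1e-10)
            assert m.p == pytest.approx(u.p, rel=1e-10)
            assert m.df1 == u.df3
            assert m.df2 == u.df4
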