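"""TMM, iDEGES, exact NB test, BH, Hoeffding's D, correlation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from onecell_dge.stats import (bh_fdr, call_degs, correlation_tests,
                               hoeffding_d, ideges_normalize, nb_exact_test,
                               tmm_factors)
from onecell_dge.stats import _exact_p_one


def _df(array, prefix="s"):
    array = np.asarray(array)
    return pd.DataFrame(array, index=[f"g{i:03d}" for i in range(array.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(array.shape[1])])


class TestTmm:
    def test_identical_columns_unit_factors(self):
        counts = _df(np.tile(np.arange(1, 21)[:, None], (1, 2)))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_unit_factors(self):
        col = np.arange(1, 31)
        counts = _df(np.column_stack([col, 3 * col]))
        assert np.allclose(tmm_factors(counts), 1.0, atol=1e-12)

    def test_matches_edger_on_inflated_fixture(self):
        """Fixture with two genes inflated in one sample; expected factors
        computed independently with Bioconductor edgeR::calcNormFactors
        (method="TMM") and frozen here."""
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.3, size=(20, 4)),
                              index=[f"g{i:02d}" for i in range(20)],
                              columns=list("ABCD"))
        counts.iloc[0, 1] *= 30
        counts.iloc[1, 1] *= 25
        expected = [1.377154, 0.452838, 1.286440, 1.246478]
        assert np.allclose(tmm_factors(counts).values, expected, atol=1e-6)

    def test_product_constraint(self, nb_counts):
        f = tmm_factors(nb_counts)
        assert np.prod(f.values) == pytest.approx(1.0)
        assert (f > 0).all()

    def test_degenerate_sample_raises(self):
        counts = _df([[0, 1], [0, 2]])
        with pytest.raises(ValueError):
            tmm_factors(counts)


class TestExactTest:
    def test_symmetric_counts_give_p_one(self):
        p = nb_exact_test(np.array([[5, 5]]), np.array([[5, 5]]),
                          dispersion=0.1,
                          lib_sizes_a=np.array([100.0, 100.0]),
                          lib_sizes_b=np.array([100.0, 100.0]))
        assert p[0] == pytest.approx(1.0)

    def test_poisson_limit_matches_binomial_enumeration(self):
        # (10,0) vs (0,10) with phi=0: conditional Binomial(20, 1/2)
        from scipy.stats import binom
        p = _exact_p_one(10, 10, 1, 1, 0.0)
        pm = binom.pmf(np.arange(21), 20, 0.5)
        expect = pm[pm <= pm[10] * (1 + 1e-12)].sum()
        assert p == pytest.approx(expect, abs=1e-12)
        p2 = _exact_p_one(10, 0, 1, 1, 0.0)
        expect2 = binom.pmf(np.arange(11), 10, 0.5)
        expect2 = expect2[expect2 <= expect2[10] * (1 + 1e-12)].sum()
        assert p2 == pytest.approx(expect2, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.3])
    def test_matches_conditional_enumeration_oracle(self, phi):
        """Brute-force oracle: enumerate the full conditional distribution of
        the group-A total for every split of small sums."""
        n_a, n_b = 3, 2
        for s in range(0, 21, 4):
            if phi == 0:
                from scipy.stats import binom
                pr = binom.pmf(np.arange(s + 1), s, n_a / (n_a + n_b))
            else:
                r_a, r_b = n_a / phi, n_b / phi
                k = np.arange(s + 1)
                lp = (gammaln(k + r_a) - gammaln(k + 1)
                      + gammaln(s - k + r_b) - gammaln(s - k + 1))
                pr = np.exp(lp - lp.max())
                pr /= pr.sum()
            for sa in range(s + 1):
                want = pr[pr <= pr[sa] * (1 + 1e-12)].sum()
                got = _exact_p_one(sa, s - sa, n_a, n_b, phi)
                assert got == pytest.approx(min(1.0, want), abs=1e-10)

    def test_null_pvalues_superuniform(self, rng):
        phi, mu, r = 0.1, 60, 10.0
        A = rng.negative_binomial(1 / phi, (1 / phi) / (1 / phi + mu), (2000, 3))
        B = rng.negative_binomial(1 / phi, (1 / phi) / (1 / phi + mu), (2000, 3))
        lib = np.full(3, 1e5)
        p = nb_exact_test(A, B, phi, lib, lib)
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(np.array([[1]]), np.array([[1]]), dispersion=-0.1)


class TestBH:
    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.04, 0.04, 0.04]), 0.04)

    def test_hand_stepup(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestIdeges:
    def test_zero_iterations_is_plain_tmm(self, nb_counts):
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=nb_counts.columns)
        res = ideges_normalize(nb_counts, groups, iterations=0)
        assert np.allclose(res.factors.values, tmm_factors(nb_counts).values)
        assert res.excluded == []

    def test_null_simulation_close_to_plain_tmm(self, nb_counts):
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=nb_counts.columns)
        res = ideges_normalize(nb_counts, groups, iterations=3)
        plain = tmm_factors(nb_counts)
        assert np.allclose(res.factors.values, plain.values, atol=0.05)
        assert len(res.excluded) == 3

    @staticmethod
    def _spiked(rng, n_genes=500, frac_deg=0.2, fold=4.0, depth_ratio=1.6):
        """Two groups, one-sided DEGs in group b, known depth difference."""
        phi = 0.1
        r = 1 / phi
        mu = rng.lognormal(3.0, 1.0, size=n_genes)
        n_deg = int(frac_deg * n_genes)
        fold_vec = np.ones(n_genes)
        fold_vec[:n_deg] = fold
        A = np.column_stack([rng.negative_binomial(r, r / (r + mu))
                             for _ in range(3)])
        B = np.column_stack([rng.negative_binomial(
            r, r / (r + mu * fold_vec * depth_ratio)) for _ in range(3)])
        counts = _df(np.column_stack([A, B]))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        return counts, groups, n_deg

    def test_recovers_depth_better_than_plain_tmm(self, rng):
        """With 20% one-sided DEGs plain TMM is biased; DEG exclusion should
        land closer to the true depth ratio in most runs."""
        wins = 0
        runs = 20
        for _ in range(runs):
            counts, groups, _ = self._spiked(rng)
            lib = counts.sum(axis=0)
            # truth: non-DEG genes have equal expression, so ideal effective
            # sizes are proportional within groups; compare factor ratios on
            # the non-DEG majority
            truth = counts.iloc[100:].sum(axis=0) / lib
            truth /= np.exp(np.mean(np.log(truth)))
            plain = tmm_factors(counts)
            ideges = ideges_normalize(counts, groups, iterations=3).factors
            err_p = np.abs(np.log(plain.values) - np.log(truth.values)).mean()
            err_i = np.abs(np.log(ideges.values) - np.log(truth.values)).mean()
            wins += err_i <= err_p
        assert wins >= 0.8 * runs

    def test_requires_two_groups(self, nb_counts):
        groups = pd.Series(["a"] * 6, index=nb_counts.columns)
        with pytest.raises(ValueError):
            ideges_normalize(nb_counts, groups)


class TestCallDegs:
    def test_null_simulation_controls_fdr(self, nb_counts):
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=nb_counts.columns)
        res = call_degs(nb_counts, groups, fdr=0.01)
        assert res.n_total <= max(3, 0.05 * len(nb_counts))

    def test_all_zero_gene_reported_na(self, nb_counts):
        counts = nb_counts.copy()
        counts.iloc[5] = 0
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        res = call_degs(counts, groups)
        assert res.table.iloc[5][["p_value", "q_value", "rank"]].isna().all()

    def test_spiked_simulation_sensitivity(self, rng):
        counts, groups, n_deg = TestIdeges._spiked(rng, depth_ratio=1.0)
        norm = ideges_normalize(counts, groups, iterations=3)
        res = call_degs(counts, groups, norm, fdr=0.01)
        sig = res.table["q_value"] < 0.01
        sens = sig.iloc[:n_deg].mean()
        assert sens > 0.8
        assert res.n_up[str(groups.iloc[-1])] >= 0.9 * res.n_total
        # ranking is a total order by significance
        ranked = res.table.dropna().sort_values("rank")
        assert ranked["q_value"].is_monotonic_increasing


class TestHoeffding:
    @staticmethod
    def brute_D(x, y):
        """Definition-level sums over index pairs with tie weights 1/2, 1/4."""
        n = len(x)

        def c(a, b):
            return 1.0 if a < b else (0.5 if a == b else 0.0)

        R = [1 + sum(c(x[j], x[i]) for j in range(n) if j != i) for i in range(n)]
        S = [1 + sum(c(y[j], y[i]) for j in range(n) if j != i) for i in range(n)]
        Q = [1 + sum(c(x[j], x[i]) * c(y[j], y[i]) for j in range(n) if j != i)
             for i in range(n)]
        D1 = sum((q - 1) * (q - 2) for q in Q)
        D2 = sum((r - 1) * (r - 2) * (s - 1) * (s - 2) for r, s in zip(R, S))
        D3 = sum((r - 2) * (s - 2) * (q - 1) for r, s, q in zip(R, S, Q))
        den = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
        return 30.0 * ((n - 2) * (n - 3) * D1 + D2 - 2 * (n - 2) * D3) / den

    def test_matches_bruteforce_oracle_with_ties(self, rng):
        for _ in range(60):
            n = int(rng.integers(5, 13))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            got = hoeffding_d(x, y, n_perm=5, seed=0).D
            assert got == pytest.approx(self.brute_D(x, y), abs=1e-12)

    def test_monotone_data_reaches_maximum(self):
        x = np.arange(10.0)
        assert hoeffding_d(x, x ** 3, n_perm=5).D == pytest.approx(1.0)

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        d0 = hoeffding_d(x, y, n_perm=5, seed=0).D
        d1 = hoeffding_d(np.exp(x), y ** 3 + 5, n_perm=5, seed=0).D
        assert d1 == pytest.approx(d0, abs=1e-12)

    def test_null_permutation_p_roughly_uniform(self, rng):
        ps = [hoeffding_d(rng.normal(size=20), rng.normal(size=20),
                          n_perm=199, seed=k).p_value for k in range(60)]
        assert 0.25 <= np.mean(ps) <= 0.75
        assert np.mean(np.abs(np.array(ps) - 0.5)) > 0.05

    def test_asymptotic_p_agrees_with_permutation(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60) * 2.0  # mild dependence
        perm = hoeffding_d(x, y, n_perm=4000, seed=1).p_value
        asym = hoeffding_d(x, y, p_via="asymptotic").p_value
        assert asym == pytest.approx(perm, abs=0.05)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            hoeffding_d([1, 2, 3, 4], [1, 2, 3, 4])


class TestCorrelationTests:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        r = correlation_tests(x, x)
        assert r["spearman_rho"] == pytest.approx(1.0)
        assert r["pearson_r"] == pytest.approx(1.0)
        assert correlation_tests(x, -x)["spearman_rho"] == pytest.approx(-1.0)

    def test_five_point_fixture_hand_ranks(self):
        # x ranks: 1..5; y = (10, 30, 20, 50, 40) → ranks (1, 3, 2, 5, 4)
        # Spearman rho = 1 - 6·Σd²/(n(n²-1)) with Σd² = 0+1+1+1+1 = 4 → 0.8
        r = correlation_tests([1, 2, 3, 4, 5], [10, 30, 20, 50, 40])
        assert r["spearman_rho"] == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_tests([1, 1, 1], [1, 2, 3])
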