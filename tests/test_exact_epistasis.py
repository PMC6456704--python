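import math

import numpy as np
import pytest
from scipy.stats import chi2

from episcan import exact_epistasis as ee
from episcan.pair_screen import encode_bit_planes, pair_table, status_planes

from conftest import make_cohort, make_genotypes, null_two_snp_cohort


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        X = np.ones((100, 1))
        fit = ee.logistic_fit(X, y)
        assert fit.beta[0] == pytest.approx(math.log(30 / 70), abs=1e-8)
        assert fit.loglik == pytest.approx(30 * math.log(0.3) + 70 * math.log(0.7),
                                           abs=1e-8)

    def test_degenerate_outcome_raises(self):
        with pytest.raises(ee.FitError, match="degenerate"):
            ee.logistic_fit(np.ones((10, 1)), np.zeros(10))

    def test_nesting_improves_loglik(self, rng):
        n = 500
        x = rng.standard_normal(n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-x))).astype(float)
        small = ee.logistic_fit(np.ones((n, 1)), y)
        big = ee.logistic_fit(np.column_stack([np.ones(n), x]), y)
        assert big.loglik >= small.loglik - 1e-10

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        eta = X @ np.array([-0.3, 0.5, -0.2, 0.1])
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = ee.logistic_fit(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, rel=1e-9)

    def test_separation_flagged(self):
        x = np.concatenate([-np.ones(20), np.ones(20)])
        y = (x > 0).astype(float)
        fit = ee.logistic_fit(np.column_stack([np.ones(40), x]), y)
        assert fit.separated


class TestDropCollinear:
    def test_keeps_earlier_column(self, rng):
        a = rng.standard_normal(50)
        X = np.column_stack([np.ones(50), a, 2 * a])
        _, kept, dropped = ee.drop_collinear_columns(X, ["i", "a", "2a"])
        assert kept == [0, 1] and dropped == ["2a"]

    def test_full_rank_untouched(self, rng):
        X = rng.standard_normal((30, 4))
        _, kept, dropped = ee.drop_collinear_columns(X)
        assert len(kept) == 4 and not dropped


class TestInteractionLrt:
    def test_main_effects_only_null_statistic_small(self, rng):
        gm, cohort = null_two_snp_cohort(rng, n=3000)
        res = ee.interaction_lrt(gm, cohort, ("s1", "s2"))
        assert res.df == 4
        assert res.p > 1e-4  # no planted interaction

    def test_homogeneous_table_statistic_zero(self):
        # counts generated exactly from a main-effects model: expand a
        # product-form table into unit rows
        P = np.array([1, 2, 3])      # control counts factor per g1
        Q = np.array([2, 1, 1])      # control counts factor per g2
        o1 = np.array([1, 2, 4])     # per-g1 odds multiplier
        o2 = np.array([1, 3, 9])     # per-g2 odds multiplier
        n0 = 10 * np.outer(P, Q)
        n1 = n0 * np.outer(o1, o2)
        counts = np.stack([n0, n1])  # exactly odds-multiplicative: no interaction
        rows, ys = [], []
        for y in range(2):
            for g1 in range(3):
                for g2 in range(3):
                    rows += [[g1, g2]] * counts[y, g1, g2]
                    ys += [y] * counts[y, g1, g2]
        gm = make_genotypes(np.array(rows, dtype=np.int8))
        cohort = make_cohort(np.array(ys))
        res = ee.interaction_lrt(gm, cohort, ("m1", "m2"))
        assert res.statistic < 1e-4
        assert res.p > 0.999

    def test_matches_ipf_oracle_no_covariates(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            probs = r.dirichlet(np.ones(18))
            tab = r.multinomial(1500, probs).reshape(2, 3, 3)
            rows, ys = [], []
            for y in range(2):
                for g1 in range(3):
                    for g2 in range(3):
                        rows += [[g1, g2]] * tab[y, g1, g2]
                        ys += [y] * tab[y, g1, g2]
            gm = make_genotypes(np.array(rows, dtype=np.int8))
            cohort = make_cohort(np.array(ys))
            res = ee.interaction_lrt(gm, cohort, ("m1", "m2"))
            _, ll_hom = ee.ipf_homogeneous_fit(tab)
            oracle = 2.0 * (ee.saturated_loglik(tab) - ll_hom)
            assert res.statistic == pytest.approx(oracle, rel=1e-6)

    def test_chi2_tail_value(self):
        assert float(chi2.sf(9.488, 4)) == pytest.approx(0.0500, abs=5e-5)

    def test_swap_invariance(self, rng):
        gm, cohort = null_two_snp_cohort(rng, n=2000)
        a = ee.interaction_lrt(gm, cohort, ("s1", "s2"))
        b = ee.interaction_lrt(gm, cohort, ("s2", "s1"))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-6)

    def test_background_excludes_pair_members(self, rng):
        gm, cohort = null_two_snp_cohort(rng, n=2000)
        with_bg = ee.interaction_lrt(gm, cohort, ("s1", "s2"),
                                     extra_covariates=["s1", "s2"])
        without = ee.interaction_lrt(gm, cohort, ("s1", "s2"))
        assert with_bg.statistic == pytest.approx(without.statistic, abs=1e-8)

    def test_absent_class_reduces_df(self, rng):
        n = 1000
        g1 = rng.binomial(1, 0.3, n).astype(np.int8)  # never homozygous
        g2 = rng.binomial(2, 0.4, n).astype(np.int8)
        y = rng.integers(0, 2, n)
        gm = make_genotypes(np.column_stack([g1, g2]))
        res = ee.interaction_lrt(gm, make_cohort(y), ("m1", "m2"))
        assert res.df == 2
        assert not res.standard_df

    def test_tiny_p_no_underflow(self):
        assert ee.interaction_logp(250.0, 4) < -45


class TestIpf:
    def test_fixed_point_on_homogeneous_table(self):
        # product-form table satisfies the model exactly
        a = np.array([1.0, 2.0])
        b = np.array([1.0, 0.5, 0.25])
        c = np.array([2.0, 1.0, 0.5])
        tab = a[:, None, None] * b[None, :, None] * c[None, None, :] * 10
        fit, _ = ee.ipf_homogeneous_fit(tab)
        np.testing.assert_allclose(fit, tab, rtol=1e-8)

    def test_margins_preserved(self, rng):
        tab = rng.multinomial(2000, np.ones(18) / 18).reshape(2, 3, 3).astype(float)
        fit, _ = ee.ipf_homogeneous_fit(tab)
        assert np.abs(fit.sum(axis=0) - tab.sum(axis=0)).max() < 1e-8
        assert np.abs(fit.sum(axis=1) - tab.sum(axis=1)).max() < 1e-8
        assert np.abs(fit.sum(axis=2) - tab.sum(axis=2)).max() < 1e-8

    def test_structural_zero_margin(self):
        tab = np.zeros((2, 3, 3))
        tab[:, :2, :2] = [[[30, 10], [10, 30]], [[10, 30], [30, 10]]]
        fit, ll = ee.ipf_homogeneous_fit(tab)
        assert math.isfinite(ll)
        assert fit[:, 2, :].sum() == 0 and fit[:, :, 2].sum() == 0


class TestSignificanceAndReplication:
    def _result(self, cond_p):
        return ee.EpistasisResult("a", "b", 50.0, 1e-9, 50.0, cond_p, 4, 4,
                                  1000, True, False)

    def test_printed_value_genome_and_chip_wide(self):
        call = ee.call_significance([self._result(3.12e-21)])[0]
        assert call.genome_wide and call.chip_wide

    def test_printed_value_chip_wide_only(self):
        call = ee.call_significance([self._result(3.32e-9)])[0]
        assert not call.genome_wide and call.chip_wide

    def test_above_chip_wide_neither(self):
        call = ee.call_significance([self._result(2e-8)])[0]
        assert not call.genome_wide and not call.chip_wide

    def test_genome_wide_implies_chip_wide(self, rng):
        for p in 10.0 ** -rng.uniform(5, 25, size=50):
            call = ee.call_significance([self._result(p)])[0]
            assert (not call.genome_wide) or call.chip_wide

    def test_replication_threshold_printed_values(self, rng):
        # 1.05e-1 fails, 4.07e-5 passes the replication rule
        assert not (1.05e-1 < ee.REPLICATION_P)
        assert 4.07e-5 < ee.REPLICATION_P

    def test_replicate_on_simulated_cohort(self, rng):
        n = 4000
        g1 = rng.binomial(2, 0.5, n).astype(np.int8)
        g2 = rng.binomial(2, 0.5, n).astype(np.int8)
        sign = np.array([[1, -1, 1], [-1, 1, -1], [1, -1, 1]])
        eta = 0.7 * sign[g1, g2]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(np.int8)
        gm = make_genotypes(np.column_stack([g1, g2]))
        cohort = make_cohort(y)
        (res, flag), = ee.replicate([("m1", "m2")], gm, cohort, [])
        assert flag and res.cond_p < 0.05

    def test_untestable_pair_not_replicated(self, rng):
        gm = make_genotypes(np.column_stack([
            np.zeros(200, dtype=np.int8), rng.binomial(2, 0.4, 200).astype(np.int8)
        ]))
        cohort = make_cohort(rng.integers(0, 2, 200))
        (res, flag), = ee.replicate([("m1", "m2")], gm, cohort, [])
        assert not flag
        assert res.note != ""
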