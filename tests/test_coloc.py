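"""Approximate Bayes factors, pairwise/three-trait colocalisation,
stepwise conditional analysis and PWCoCo."""

import numpy as np
import pandas as pd
import pytest
from conftest import ld_from_r
from oracles import enumerate_moloc, enumerate_pairwise, wakefield_log_abf

from cismr import coloc
from cismr.simulate import ar1_corr


def window_from_z(z1, z2, se=0.01, **kw):
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    m = z1.size
    keys = [f"1:{i}" for i in range(m)]
    return coloc.ColocWindow(
        keys, z1 * se, np.full(m, se), z2 * se, np.full(m, se), **kw
    )


class TestLogAbf:
    def test_null_z_equal_prior_closed_form(self):
        # z = 0, W = V: log ABF = 0.5 ln(1/2)
        got = coloc.log_abf(0.0, 0.1, 0.1)
        assert got == pytest.approx(0.5 * np.log(0.5))
        assert got == pytest.approx(-0.34657, abs=1e-5)

    def test_strong_signal_closed_form(self):
        got = coloc.log_abf(0.5, 0.1, 0.2)
        assert got == pytest.approx(0.5 * np.log(0.2) + 25 * 0.8 / 2)
        assert got == pytest.approx(9.1953, abs=1e-4)

    def test_vanishing_prior_limit(self):
        assert coloc.log_abf(0.5, 0.1, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_abs_z(self):
        zs = np.linspace(0, 10, 50)
        vals = coloc.log_abf(zs * 0.1, 0.1, 0.2)
        assert np.all(np.diff(vals) > 0)

    def test_numerical_integration_cross_check(self):
        # ABF approximates the Bayes factor of beta_hat ~ N(b, V) with
        # b ~ N(0, W) against b = 0
        from scipy import integrate, stats

        beta, se, w = 0.25, 0.1, 0.2
        num, _ = integrate.quad(
            lambda b: stats.norm.pdf(beta, b, se) * stats.norm.pdf(b, 0, w),
            -3, 3,
        )
        bf = num / stats.norm.pdf(beta, 0, se)
        assert coloc.log_abf(beta, se, w) == pytest.approx(np.log(bf), abs=1e-6)


class TestColocPairwise:
    def test_shared_dominant_variant_high_pph4(self):
        rng = np.random.default_rng(0)
        z1 = rng.normal(0, 1, 100)
        z2 = rng.normal(0, 1, 100)
        z1[40] = 12.0
        z2[40] = 12.0
        res = coloc.coloc_pairwise(window_from_z(z1, z2))
        assert res.pph4 > 0.95

    def test_all_null_gives_pph0(self):
        res = coloc.coloc_pairwise(window_from_z(np.zeros(50), np.zeros(50)))
        assert res.pph0 > 0.99

    def test_distinct_variants_give_pph3(self):
        z1 = np.zeros(60)
        z2 = np.zeros(60)
        z1[10] = 10.0
        z2[50] = 10.0
        res = coloc.coloc_pairwise(window_from_z(z1, z2))
        assert res.pph3 > 0.9

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            m = rng.integers(2, 13)
            z1 = rng.normal(0, 2, m)
            z2 = rng.normal(0, 2, m)
            se = 0.01
            win = window_from_z(z1, z2, se)
            res = coloc.coloc_pairwise(win)
            lab1 = [wakefield_log_abf(z * se, se, 0.2) for z in z1]
            lab2 = [wakefield_log_abf(z * se, se, 0.15) for z in z2]
            expected = enumerate_pairwise(lab1, lab2, 1e-4, 1e-4, 1e-5)
            np.testing.assert_allclose(res.pph, expected, atol=1e-8)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(2)
        res = coloc.coloc_pairwise(
            window_from_z(rng.normal(0, 3, 30), rng.normal(0, 3, 30))
        )
        assert np.sum(res.pph) == pytest.approx(1.0, abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        z1 = rng.normal(0, 3, 20)
        z2 = rng.normal(0, 3, 20)
        perm = rng.permutation(20)
        a = coloc.coloc_pairwise(window_from_z(z1, z2))
        b = coloc.coloc_pairwise(window_from_z(z1[perm], z2[perm]))
        np.testing.assert_allclose(a.pph, b.pph, atol=1e-12)

    def test_single_variant_fatal(self):
        with pytest.raises(ValueError, match="two variants"):
            coloc.coloc_pairwise(window_from_z([1.0], [1.0]))

    def test_nan_fatal(self):
        with pytest.raises(ValueError, match="NaN"):
            window = window_from_z([1.0, np.nan], [1.0, 1.0])


class TestStepwiseConditional:
    def _stats(self, z, se=0.01):
        z = np.asarray(z, dtype=float)
        return pd.DataFrame({"beta": z * se, "se": np.full(z.size, se)})

    def test_independent_signals_keep_marginal_z(self):
        z = np.array([8.0, 7.0])
        signals = coloc.stepwise_conditional(
            self._stats(z), ld_from_r([1, 2], np.eye(2))
        )
        assert len(signals) == 2
        s2 = next(s for s in signals if s.index == 1)
        assert s2.conditional["z"].iloc[1] == pytest.approx(7.0)

    def test_conditional_z_formula(self):
        # z = (5, 4), r = 0.5: z2|1 = (4 - 0.5*5)/sqrt(1 - 0.25)
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = np.array([5.0, 4.0])
        zc, ok = coloc._conditional_z(z, r, [0])
        assert zc[1] == pytest.approx(1.5 / np.sqrt(0.75))
        assert zc[1] == pytest.approx(1.732, abs=1e-3)

    def test_conditional_z_matches_regression_on_individual_data(self):
        # joint OLS on simulated standardised predictors reproduces the
        # z-space conditional statistic
        rng = np.random.default_rng(11)
        n = 200_000
        x1 = rng.standard_normal(n)
        x2 = 0.5 * x1 + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        y = 0.02 * x1 + 0.015 * x2 + rng.standard_normal(n)
        X = np.column_stack([x1, x2])
        Xs = (X - X.mean(0)) / X.std(0)
        z_marg = np.array(
            [Xs[:, j] @ (y - y.mean()) / (np.sqrt(n) * y.std()) for j in (0, 1)]
        ) * np.sqrt(n) / np.sqrt(n)
        z_marg = np.array([
            float(np.corrcoef(Xs[:, j], y)[0, 1]) * np.sqrt(n) for j in (0, 1)
        ])
        R = np.corrcoef(Xs, rowvar=False)
        zc, _ = coloc._conditional_z(z_marg, R, [0])
        # joint regression t-statistic for x2
        import statsmodels.api as sm

        fit = sm.OLS(y, sm.add_constant(Xs)).fit()
        assert zc[1] == pytest.approx(fit.tvalues[2], rel=0.02)

    def test_single_signal_region(self):
        m = 20
        z = np.zeros(m)
        z[7] = 9.0
        R = ar1_corr(m, 0.6)
        z = R @ z  # LD-smeared marginal signal
        signals = coloc.stepwise_conditional(
            self._stats(z), ld_from_r(range(m), R)
        )
        assert len(signals) == 1
        assert signals[0].index == 7

    def test_collinear_variant_skipped(self):
        R = np.array([[1.0, 1.0 - 1e-9], [1.0 - 1e-9, 1.0]])
        z = np.array([10.0, 10.0])
        zc, ok = coloc._conditional_z(z, R, [0])
        assert not ok[1]
        assert zc[1] == 0.0


class TestPwcoco:
    def test_single_signal_reduces_to_marginal_coloc(self):
        rng = np.random.default_rng(5)
        m = 40
        R = ar1_corr(m, 0.5)
        z = R @ np.where(np.arange(m) == 20, 10.0, 0.0)
        win = window_from_z(z, z + rng.normal(0, 0.3, m))
        res = coloc.pwcoco(win, ld_from_r(range(m), R))
        assert len(res.grid) == 1
        marginal = coloc.coloc_pairwise(win)
        np.testing.assert_allclose(res.best.pph, marginal.pph, atol=1e-12)

    def test_secondary_shared_signal_found_by_conditioning(self):
        # trait 1 has two causal variants; trait 2 shares only the secondary.
        # conditioning trait 1 on its primary signal exposes the shared one.
        m = 60
        R = ar1_corr(m, 0.7)
        e1 = np.zeros(m)
        e1[15] = 14.0
        e1[45] = 8.0
        e2 = np.zeros(m)
        e2[45] = 8.0
        z1 = R @ e1
        z2 = R @ e2
        win = window_from_z(z1, z2)
        res = coloc.pwcoco(win, ld_from_r(range(m), R))
        marginal = coloc.coloc_pairwise(win)
        assert res.best.pph4 > 0.7
        assert res.best.pph4 > marginal.pph4
        assert "signal" in res.best.conditional_context

    def test_grid_size_with_two_signals_each(self):
        m = 60
        R = ar1_corr(m, 0.3)
        e = np.zeros(m)
        e[10] = 12.0
        e[50] = 12.0
        z = R @ e
        win = window_from_z(z, z)
        res = coloc.pwcoco(win, ld_from_r(range(m), R))
        assert len(res.grid) == 9  # (marginal + 2 signals)^2


class TestMolocThree:
    def _stats(self, z, se=0.01):
        z = np.asarray(z, dtype=float)
        return pd.DataFrame({"beta": z * se, "se": np.full(z.size, se)})

    def test_posteriors_sum_to_one_and_cover_15_configs(self):
        rng = np.random.default_rng(6)
        res = coloc.moloc_three(
            [self._stats(rng.normal(0, 2, 20)) for _ in range(3)]
        )
        assert len(res.posteriors) == 15
        assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-12)

    def test_shared_dominant_variant_high_posterior_abc(self):
        z = np.zeros(80)
        z[30] = 12.0
        res = coloc.moloc_three([self._stats(z)] * 3)
        assert res.posterior_abc > 0.9

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        types = ("quantitative", "quantitative", "case_control")
        for _ in range(15):
            m = int(rng.integers(2, 11))
            zs = [rng.normal(0, 2.5, m) for _ in range(3)]
            stats_ = [self._stats(z) for z in zs]
            res = coloc.moloc_three(stats_, types)
            labs = [
                np.array([
                    wakefield_log_abf(z * 0.01, 0.01, coloc.PRIOR_SD[t])
                    for z in zvec
                ])
                for zvec, t in zip(zs, types)
            ]
            expected = enumerate_moloc(
                labs, coloc.DEFAULT_MOLOC_PRIORS, coloc.MOLOC_CONFIGS
            )
            for name, val in expected.items():
                assert res.posteriors[name] == pytest.approx(val, abs=1e-8)

    def test_null_third_trait_collapses_to_pairwise_margin(self):
        # with trait 3 flat, the a/b sharing split should mirror pairwise
        # coloc of traits 1-2
        z = np.zeros(50)
        z[20] = 10.0
        res = coloc.moloc_three(
            [self._stats(z), self._stats(z), self._stats(np.zeros(50))],
            trait_types=("quantitative", "quantitative", "quantitative"),
        )
        shared = res.posteriors["ab"] + res.posteriors["abc"] + \
            res.posteriors["ab.c"]
        distinct = res.posteriors["a.b"] + res.posteriors["a.c"] + \
            res.posteriors["b.c"] + res.posteriors["a.b.c"]
        assert shared > 0.9
        assert shared > distinct
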