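"""Beta-regression estimation, quadrature, LRTs and contrasts against
independent oracles (grid search, statsmodels, brute-force integration,
direct Wald computation)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import expit, logit

from riskgrid.betareg import (
    SingularDesignError,
    build_design,
    fit_beta,
    fit_beta_mixed,
    lrt,
    lsmeans_contrasts,
    squeeze,
)
from riskgrid.betareg._fit import _group_index, _mixed_negloglik


class TestSqueeze:
    @pytest.mark.parametrize(
        "y,n,expected",
        [(0.0, 100, 0.005), (1.0, 100, 0.995), (0.5, 7, 0.5), (0.5, 1000, 0.5)],
    )
    def test_formula(self, y, n, expected):
        assert squeeze(np.array([y]), n)[0] == pytest.approx(expected)

    def test_order_preserving_and_open_interval(self, rng):
        y = np.sort(rng.uniform(0, 1, 50))
        y[0], y[-1] = 0.0, 1.0
        z = squeeze(y, 50)
        assert np.all(np.diff(z) >= 0)
        assert z.min() > 0 and z.max() < 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            squeeze(np.array([1.2]), 10)


def grid_search_intercept_ml(y, rounds=9, k=41):
    """Independent 2-D grid-search ML over (mu, phi) for an intercept-only
    beta regression, by successive range refinement."""
    mu_lo, mu_hi = 1e-3, 1 - 1e-3
    lp_lo, lp_hi = np.log(0.1), np.log(1e4)
    best = None
    for _ in range(rounds):
        mus = np.linspace(mu_lo, mu_hi, k)
        lps = np.linspace(lp_lo, lp_hi, k)
        ll = np.array(
            [
                [stats.beta.logpdf(y, m * np.exp(lp), (1 - m) * np.exp(lp)).sum()
                 for lp in lps]
                for m in mus
            ]
        )
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (mus[i], np.exp(lps[j]), ll[i, j])
        dm = (mu_hi - mu_lo) / (k - 1)
        dl = (lp_hi - lp_lo) / (k - 1)
        mu_lo, mu_hi = max(1e-6, mus[i] - dm), min(1 - 1e-6, mus[i] + dm)
        lp_lo, lp_hi = lps[j] - dl, lps[j] + dl
    return best


class TestFitBeta:
    def test_intercept_only_matches_grid_search(self, rng):
        y = squeeze(rng.beta(2.0, 2.0, size=120), 120)
        fit = fit_beta(y, np.ones((120, 1)))
        mu_hat = expit(fit.coefficients[0])
        mu_grid, phi_grid, ll_grid = grid_search_intercept_ml(y)
        assert mu_hat == pytest.approx(mu_grid, abs=1e-6)
        assert fit.phi == pytest.approx(phi_grid, rel=1e-4)
        assert fit.loglik >= ll_grid - 1e-6

    def test_matches_independent_implementation(self, rng):
        from statsmodels.othermod.betareg import BetaModel

        n = 300
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        mu = expit(0.3 + 0.8 * x)
        y = rng.beta(mu * 15, (1 - mu) * 15)
        fit = fit_beta(y, X)
        sm = BetaModel(y, X).fit(disp=0)
        assert fit.coefficients == pytest.approx(sm.params[:2], abs=1e-5)
        assert fit.phi == pytest.approx(np.exp(sm.params[2]), rel=1e-4)
        assert fit.loglik == pytest.approx(sm.llf, abs=1e-6)

    def test_parameter_recovery_within_3se(self, rng):
        n = 400
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        mu = expit(0.5 - 1.0 * x)
        y = rng.beta(mu * 20, (1 - mu) * 20)
        fit = fit_beta(y, X)
        se = np.sqrt(np.diag(fit.vcov))
        assert abs(fit.coefficients[0] - 0.5) < 3 * se[0]
        assert abs(fit.coefficients[1] + 1.0) < 3 * se[1]
        assert abs(fit.phi - 20) < 3 * fit.phi_se

    def test_loglik_matches_direct_density_sum(self, rng):
        n = 150
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = squeeze(rng.uniform(0, 1, n), n)
        fit = fit_beta(y, X)
        mu = expit(X @ fit.coefficients)
        direct = stats.beta.logpdf(y, mu * fit.phi, (1 - mu) * fit.phi).sum()
        assert fit.loglik == pytest.approx(direct, abs=1e-8)

    def test_exact_zero_response_rejected(self):
        y = np.array([0.0, 0.5, 0.7, 0.2, 0.9])
        with pytest.raises(ValueError, match="squeeze"):
            fit_beta(y, np.ones((5, 1)))

    def test_rank_deficient_design_rejected(self, rng):
        y = squeeze(rng.uniform(0, 1, 30), 30)
        X = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_beta(y, X)

    def test_covariate_shift_moves_intercept_only(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = squeeze(rng.beta(3, 2, size=n), n)
        f0 = fit_beta(y, np.column_stack([np.ones(n), x]))
        f1 = fit_beta(y, np.column_stack([np.ones(n), x + 5.0]))
        assert f1.coefficients[1] == pytest.approx(f0.coefficients[1], abs=1e-6)
        assert f1.coefficients[0] == pytest.approx(
            f0.coefficients[0] - 5.0 * f0.coefficients[1], abs=1e-5
        )
        assert f1.loglik == pytest.approx(f0.loglik, abs=1e-7)


class TestMixed:
    def test_reduces_to_fixed_for_singleton_groups(self, rng):
        n = 150
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        mu = expit(0.2 + 0.5 * x)
        y = rng.beta(mu * 10, (1 - mu) * 10)
        fixed = fit_beta(y, X)
        # sigma_u fixed at zero: the marginal model collapses to the fixed fit
        mixed = fit_beta_mixed(y, X, np.arange(n), fix_sigma=0.0)
        assert mixed.boundary
        assert mixed.sigma_u == 0.0
        assert mixed.coefficients == pytest.approx(fixed.coefficients, abs=1e-6)
        assert mixed.loglik == pytest.approx(fixed.loglik, abs=1e-8)
        # freely estimated sigma on singleton groups still brackets the
        # fixed-effects likelihood from above
        free = fit_beta_mixed(y, X, np.arange(n))
        assert free.loglik >= fixed.loglik - 1e-4

    def _paired_data(self, rng, G=120, sigma=0.8, phi=15.0):
        u = rng.normal(0, sigma, G)
        gid = np.repeat(np.arange(G), 2)
        mu = expit(0.4 + u[gid])
        y = rng.beta(mu * phi, (1 - mu) * phi)
        return y, np.ones((2 * G, 1)), gid

    def test_sigma_recovery(self, rng):
        errs = []
        for _ in range(8):
            y, X, gid = self._paired_data(rng)
            fit = fit_beta_mixed(y, X, gid)
            errs.append(abs(fit.sigma_u - 0.8))
        assert np.median(errs) < 0.25

    def test_quadrature_converged_at_21_nodes(self, rng):
        from numpy.polynomial.hermite_e import hermegauss

        y, X, gid = self._paired_data(rng)
        fit = fit_beta_mixed(y, X, gid, n_nodes=21)
        theta = np.concatenate(
            [fit.coefficients, [np.log(fit.phi)], [np.log(max(fit.sigma_u, 1e-4))]]
        )
        gidx, G = _group_index(gid)
        args = (y, X, logit(y), np.log(y), np.log1p(-y), gidx, G)
        ll21 = -_mixed_negloglik(theta, *args, *hermegauss(21))[0]
        ll41 = -_mixed_negloglik(theta, *args, *hermegauss(41))[0]
        assert abs(ll21 - ll41) < 1e-5

    def test_marginal_likelihood_matches_quad_oracle(self, rng):
        y, X, gid = self._paired_data(rng, G=40)
        fit = fit_beta_mixed(y, X, gid)
        b0, phi, sig = fit.coefficients[0], fit.phi, fit.sigma_u
        total = 0.0
        for g in range(40):
            ys = y[gid == g]

            def dens(u):
                m = expit(b0 + u)
                return np.prod(stats.beta.pdf(ys, m * phi, (1 - m) * phi)) * stats.norm.pdf(
                    u, 0, sig
                )

            v, _ = quad(dens, -8 * sig, 8 * sig, limit=200)
            total += np.log(v)
        assert fit.loglik == pytest.approx(total, abs=1e-5)

    def test_mixed_nests_fixed(self, rng):
        y, X, gid = self._paired_data(rng)
        assert fit_beta_mixed(y, X, gid).loglik >= fit_beta(y, X).loglik - 1e-6


class TestLRT:
    def test_worked_chi2_p_value(self):
        # chi-square survival: chi2 = 2.8 on 1 df
        assert stats.chi2.sf(2.8, 1) == pytest.approx(0.094, abs=5e-4)

    def test_identical_models_give_p_one(self, rng):
        y = squeeze(rng.uniform(0, 1, 50), 50)
        f = fit_beta(y, np.ones((50, 1)), names=["intercept"])
        res = lrt(f, f)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_nested_lrt_statistic(self, rng):
        n = 200
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        mu = expit(0.2 + 0.6 * x)
        y = rng.beta(mu * 12, (1 - mu) * 12)
        full = fit_beta(y, X, names=["intercept", "x"])
        red = fit_beta(y, X[:, :1], names=["intercept"])
        res = lrt(full, red)
        assert res.df == 1
        assert res.chi2 == pytest.approx(2 * (full.loglik - red.loglik))
        assert res.p == pytest.approx(stats.chi2.sf(res.chi2, 1))

    def test_non_nested_rejected(self, rng):
        y = squeeze(rng.uniform(0, 1, 50), 50)
        f1 = fit_beta(y, np.ones((50, 1)), names=["intercept"])
        f2 = fit_beta(y, np.ones((50, 1)), names=["other"])
        with pytest.raises(ValueError, match="nested"):
            lrt(f1, f2)

    def test_different_responses_rejected(self, rng):
        y1 = squeeze(rng.uniform(0, 1, 50), 50)
        y2 = squeeze(rng.uniform(0, 1, 50), 50)
        f1 = fit_beta(y1, np.ones((50, 1)), names=["intercept"])
        f2 = fit_beta(y2, np.ones((50, 1)), names=["intercept"])
        with pytest.raises(ValueError, match="response"):
            lrt(f1, f2)

    def test_invariant_to_factor_recoding(self, rng):
        n = 240
        df = pd.DataFrame({"f": rng.choice(list("abc"), n)})
        mu = expit(np.array([{"a": -0.5, "b": 0.3, "c": 0.8}[v] for v in df["f"]]))
        y = rng.beta(mu * 10, (1 - mu) * 10)
        chis = []
        for order in (["a", "b", "c"], ["c", "a", "b"]):
            d, X = build_design(df, {"f": order})
            full = fit_beta(y, X, names=d.columns)
            red = fit_beta(y, X[:, :1], names=["intercept"])
            chis.append(lrt(full, red).chi2)
        assert chis[0] == pytest.approx(chis[1], abs=1e-5)


def _factor_fit(rng, level_means, n_per=150, phi=40.0):
    levels = list(level_means)
    df = pd.DataFrame({"f": np.repeat(levels, n_per)})
    mu = expit(np.repeat([level_means[lv] for lv in levels], n_per))
    y = rng.beta(mu * phi, (1 - mu) * phi)
    d, X = build_design(df, {"f": levels})
    return fit_beta(y, X, names=d.columns, design_info=d), y


class TestContrasts:
    def test_unadjusted_p_matches_direct_wald(self, rng):
        fit, _ = _factor_fit(rng, {"a": -0.3, "b": 0.1, "c": 0.6})
        ct = lsmeans_contrasts(fit, "f", adjust="none")
        # direct Wald oracle from the coefficient vector/vcov: with one
        # factor, level means are intercept (+ level effect)
        L = {"a": np.array([1.0, 0, 0]), "b": np.array([1.0, 1, 0]),
             "c": np.array([1.0, 0, 1])}
        for _, r in ct.contrasts.iterrows():
            c = L[r.level_a] - L[r.level_b]
            est = c @ fit.coefficients
            se = np.sqrt(c @ fit.vcov @ c)
            assert r.estimate == pytest.approx(est, abs=1e-12)
            assert r.p == pytest.approx(2 * stats.norm.sf(abs(est / se)), abs=1e-12)
            assert r.p_adjusted == r.p

    def test_identical_levels_give_zero_contrast(self, rng):
        # two levels with identical response multisets: the ML fit is
        # symmetric, so their contrast is 0 with p_adjusted 1
        yblock = squeeze(rng.uniform(0, 1, 80), 80)
        df = pd.DataFrame({"f": np.repeat(["a", "b"], 80)})
        y = np.concatenate([yblock, yblock])
        d, X = build_design(df, {"f": ["a", "b"]})
        fit = fit_beta(y, X, names=d.columns, design_info=d)
        ct = lsmeans_contrasts(fit, "f")
        assert abs(ct.contrasts.loc[0, "estimate"]) < 1e-6
        assert ct.contrasts.loc[0, "p_adjusted"] > 0.999
        assert ct.letters["a"] == ct.letters["b"]

    def test_tukey_adjustment_never_below_unadjusted(self, rng):
        fit, _ = _factor_fit(rng, {"a": -0.2, "b": 0.0, "c": 0.2, "d": 0.4}, n_per=60)
        ct = lsmeans_contrasts(fit, "f", adjust="tukey")
        assert (ct.contrasts["p_adjusted"] >= ct.contrasts["p"] - 1e-12).all()

    def test_outlier_level_gets_unique_letter(self, rng):
        fit, _ = _factor_fit(rng, {"a": 0.0, "b": 0.0, "c": 0.0, "d": 2.0}, n_per=200)
        ct = lsmeans_contrasts(fit, "f")
        d_letter = ct.letters["d"]
        assert all(
            set(d_letter).isdisjoint(ct.letters[lv]) for lv in "abc"
        )
        shared = set(ct.letters["a"]) & set(ct.letters["b"]) & set(ct.letters["c"])
        assert shared

    def test_single_level_factor_rejected(self, rng):
        df = pd.DataFrame({"f": ["a"] * 30})
        y = squeeze(rng.uniform(0, 1, 30), 30)
        d, X = build_design(df, {"f": ["a"]})
        fit = fit_beta(y, X, names=d.columns, design_info=d)
        with pytest.raises(ValueError, match="single level"):
            lsmeans_contrasts(fit, "f")


class TestDesign:
    def test_aliased_columns_detected(self, rng):
        df = pd.DataFrame({"f": ["a", "b"] * 20, "g": ["x", "y"] * 20})
        with pytest.raises(SingularDesignError, match="g"):
            build_design(df, {"f": None, "g": None})
        d, X = build_design(df, {"f": None, "g": None}, drop_aliased=True)
        assert d.dropped_columns == ["g[y]"]
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_unobserved_levels_dropped_with_warning(self, caplog):
        df = pd.DataFrame({"f": ["a", "b"] * 10})
        with caplog.at_level("WARNING"):
            d, X = build_design(df, {"f": ["a", "b", "ghost"]})
        assert d.factors["f"] == ["a", "b"]
        assert "ghost" in caplog.text
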