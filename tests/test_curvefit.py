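"""Model-engine contracts: noiseless identifiability, closed-form BMD
inversion, likelihood-ratio identities, profile-BMDL behavior, and the
dose-scale / response-shift invariances."""

import numpy as np
import pytest
from scipy import stats

from txpod import curvefit as cf
from txpod.curvefit import ModelSpec, mean_function, prob_function

DOSES = np.array([0.0, 2.5, 5.0, 10.0, 25.0, 75.0])


def _replicate(spec, sigma, rng, doses=DOSES, n_reps=6):
    mu = mean_function(spec)(doses)
    return mu[:, None] + rng.normal(0, sigma, size=(len(doses), n_reps))


class TestFitContinuous:
    def test_noiseless_linear_identifiability(self):
        y = [[2 + 0.3 * d] * 3 for d in DOSES]
        fit = cf.fit(DOSES, y, "linear")
        np.testing.assert_allclose(fit.spec.params, [2.0, 0.3], rtol=1e-6)
        assert fit.sigma == pytest.approx(0.0, abs=1e-8)

    def test_hill_parameter_recovery(self, rng):
        true = ModelSpec("hill", [5.0, 1.5, 10.0, 2.0])
        y = _replicate(true, 0.05, rng, n_reps=10)
        fit = cf.fit(DOSES, y, "hill")
        assert fit.converged
        for name in ("g", "v", "k", "n"):
            assert fit.spec[name] == pytest.approx(true[name], rel=0.10)

    def test_power_exponent_restriction(self, rng):
        # concave data (exponent < 1) must fit at the delta = 1 boundary
        true = ModelSpec("power", [1.0, 0.8, 0.5])
        y = _replicate(ModelSpec("power", [1.0, 0.8, 1.0]), 0.0, rng)
        fit = cf.fit(DOSES, y, "power", restrict_power=True)
        assert fit.spec["delta"] >= 1.0

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            cf.fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "linear")

    def test_aic_identity(self, rng):
        for fam in ("linear", "poly2", "hill", "power"):
            y = _replicate(ModelSpec("linear", [3.0, 0.1]), 0.2, rng)
            fit = cf.fit(DOSES, y, fam)
            assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_nested_likelihood_monotonicity(self, rng):
        y = _replicate(ModelSpec("linear", [3.0, 0.05]), 0.3, rng)
        ll = {f: cf.fit(DOSES, y, f).loglik for f in ("linear", "poly2", "poly3")}
        assert ll["poly2"] >= ll["linear"] - 1e-6
        assert ll["poly3"] >= ll["poly2"] - 1e-6


class TestFitDichotomous:
    def test_logistic_large_n_recovery(self, rng):
        doses = np.array([0.0, 10.0, 50.0, 100.0, 200.0])
        true = ModelSpec("logistic", [-3.0, 0.02])
        p = prob_function(true)(doses)
        n = np.full(5, 1000)
        affected = rng.binomial(1000, p)
        fit = cf.fit_dichotomous(doses, affected, n, "logistic")
        assert fit.converged
        np.testing.assert_allclose(fit.predict(doses), p, atol=0.02)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            cf.fit_dichotomous([0, 1, 2], [5, 20, 5], [10, 10, 10], "logistic")


class TestGoodnessOfFit:
    def test_saturated_model_p_is_one(self):
        # quadratic through 3 group means: zero residual df, exact fit
        doses = np.array([0.0, 1.0, 2.0])
        y = [[1.0, 1.2], [2.0, 2.2], [2.5, 2.7]]
        fit = cf.fit(doses, y, "poly2")
        assert cf.goodness_of_fit(fit) == pytest.approx(1.0)

    def test_linear_rejected_on_sigmoidal_means(self, rng):
        # group means deviate strongly from any line at tiny residual noise
        spec = ModelSpec("hill", [0.0, 4.0, 10.0, 6.0])
        y = _replicate(spec, 0.05, rng, n_reps=6)
        fit = cf.fit(DOSES, y, "linear")
        assert cf.goodness_of_fit(fit) < 0.1

    def test_statistic_is_brute_force_lr(self, rng):
        y = _replicate(ModelSpec("linear", [2.0, 0.1]), 0.2, rng)
        fit = cf.fit(DOSES, y, "linear")
        x, yy = fit.doses, fit.responses
        n = len(yy)
        # brute-force saturated log-likelihood
        rss_sat = sum(
            float(np.sum((yy[x == g] - yy[x == g].mean()) ** 2)) for g in np.unique(x)
        )
        ll_sat = -0.5 * n * (np.log(2 * np.pi * rss_sat / n) + 1)
        lr = 2 * (ll_sat - fit.loglik)
        df = 6 - 2
        assert cf.goodness_of_fit(fit) == pytest.approx(stats.chi2.sf(lr, df), rel=1e-9)


class TestBmdInversion:
    def test_linear_closed_form(self, rng):
        y = _replicate(ModelSpec("linear", [2.0, 0.5]), 0.2, rng)
        fit = cf.fit(DOSES, y, "linear")
        expected = 1.349 * fit.sigma / abs(fit.spec["b1"])
        assert cf.bmd_from_fit(fit, 1.349) == pytest.approx(expected, rel=1e-6)

    def test_hill_closed_form_value(self):
        fit = cf.FitResult(
            spec=ModelSpec("hill", [0.0, 1.0, 2.0, 1.0]),
            loglik=0.0, aic=0.0, n_params=5, converged=True, sigma=0.1,
            doses=DOSES, responses=np.zeros(6),
        )
        assert cf.bmd_from_fit(fit, 1.349) == pytest.approx(0.3119, abs=5e-5)

    def test_flat_curve_has_no_bmd(self):
        y = [[5.0, 5.0, 5.0]] * 6
        fit = cf.fit(DOSES, y, "linear")
        assert cf.bmd_from_fit(fit, 1.349) is None

    def test_root_finding_matches_closed_form_for_poly(self, rng):
        # poly2 BMD has no closed form in the engine; cross-check numerically
        spec = ModelSpec("poly2", [1.0, 0.02, 0.001])
        y = _replicate(spec, 0.1, rng, n_reps=8)
        fit = cf.fit(DOSES, y, "poly2")
        bmd = cf.bmd_from_fit(fit, 1.349)
        mu = mean_function(fit.spec)
        assert abs(mu(bmd) - mu(0.0)) == pytest.approx(1.349 * fit.sigma, rel=1e-6)


class TestBmdlProfile:
    def test_bmdl_below_bmd_across_fits(self, rng):
        for i in range(10):
            y = _replicate(ModelSpec("linear", [2.0, 0.05 * (i + 1)]), 0.2, rng)
            fit = cf.fit(DOSES, y, "linear")
            bmd = cf.bmd_from_fit(fit, 1.349)
            bmdl = cf.bmdl_profile(fit, 1.349)
            assert bmdl is not None
            assert 0 < bmdl <= bmd

    def test_profile_close_to_delta_method_at_large_n(self, rng):
        # large n: profile and Wald lower bounds agree for the linear model
        spec = ModelSpec("linear", [2.0, 0.3])
        y = _replicate(spec, 0.3, rng, n_reps=100)
        fit = cf.fit(DOSES, y, "linear")
        bmd = cf.bmd_from_fit(fit, 1.349)
        bmdl = cf.bmdl_profile(fit, 1.349)
        # delta method on g = bmr*sigma/|b1| with independent hat(b1), hat(sigma)
        x, yy = fit.doses, fit.responses
        n = len(yy)
        sxx = float(np.sum((x - x.mean()) ** 2))
        var_b1 = fit.sigma**2 / sxx
        var_sigma = fit.sigma**2 / (2 * n)
        g = bmd
        var_g = g**2 * (var_b1 / fit.spec["b1"] ** 2 + var_sigma / fit.sigma**2)
        wald_lower = g - 1.6449 * np.sqrt(var_g)
        assert bmdl == pytest.approx(wald_lower, rel=0.05)

    def test_unbounded_profile_reports_none(self):
        # flat data: no BMD at all, hence no BMDL
        y = [[5.0, 5.0, 5.0]] * 6
        fit = cf.fit(DOSES, y, "linear")
        assert cf.bmdl_profile(fit, 1.349) is None


class TestNestedSelection:
    def test_exact_quadratic_selects_poly2(self):
        y = [[1 + 0.1 * d + 0.02 * d * d + e for e in (-0.01, 0.0, 0.01)] for d in DOSES]
        fits = {f: cf.fit(DOSES, y, f) for f in ("linear", "poly2", "poly3")}
        chosen = cf.nested_lr_select(fits["linear"], fits["poly2"], fits["poly3"])
        assert chosen.family == "poly2"

    def test_linear_data_mostly_selects_linear(self):
        rng = np.random.default_rng(77)
        wins = 0
        for _ in range(40):
            y = _replicate(ModelSpec("linear", [2.0, 0.1]), 0.2, rng)
            fits = {f: cf.fit(DOSES, y, f) for f in ("linear", "poly2", "poly3")}
            chosen = cf.nested_lr_select(fits["linear"], fits["poly2"], fits["poly3"])
            wins += chosen.family == "linear"
        assert wins >= 32  # ~alpha=0.05 per step

    def test_lr_statistic_is_twice_loglik_gap(self, rng):
        y = _replicate(ModelSpec("linear", [2.0, 0.1]), 0.2, rng)
        lin = cf.fit(DOSES, y, "linear")
        p2 = cf.fit(DOSES, y, "poly2")
        stat, p = cf.lr_test(lin, p2)
        assert stat == pytest.approx(2 * (p2.loglik - lin.loglik), abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(stat, 1))


class TestInvariances:
    @pytest.mark.parametrize("family", ["linear", "power", "hill"])
    def test_dose_scale_equivariance(self, family, rng):
        spec = {
            "linear": ModelSpec("linear", [2.0, 0.2]),
            "power": ModelSpec("power", [2.0, 0.05, 1.5]),
            "hill": ModelSpec("hill", [2.0, 1.5, 10.0, 2.0]),
        }[family]
        y = _replicate(spec, 0.1, rng, n_reps=8)
        c = 10.0
        f1 = cf.fit(DOSES, y, family, seed=3)
        f2 = cf.fit(DOSES * c, y, family, seed=3)
        b1 = cf.bmd_from_fit(f1, 1.349)
        b2 = cf.bmd_from_fit(f2, 1.349)
        assert b2 == pytest.approx(c * b1, rel=1e-3)

    def test_response_shift_invariance(self, rng):
        y = np.asarray(_replicate(ModelSpec("linear", [2.0, 0.2]), 0.1, rng))
        f1 = cf.fit(DOSES, y, "linear")
        f2 = cf.fit(DOSES, y + 100.0, "linear")
        assert cf.bmd_from_fit(f2, 1.349) == pytest.approx(
            cf.bmd_from_fit(f1, 1.349), rel=1e-9
        )
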