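import numpy as np
import pytest
from scipy import stats

from sbm import synthetic, trajectories
from sbm.trajectories import (
    age_subset_analysis,
    bic,
    fit_component,
    fit_polynomial,
    se_from_ci,
    t_from_beta_ci,
    t_from_r2,
    two_sided_p,
)
from sbm.volume import ConfigurationError


class TestBic:
    def test_closed_form_unit_variance(self):
        assert bic(100.0, 100, 1) == pytest.approx(2 * np.log(100), abs=1e-10)

    def test_equal_rss_penalty_difference(self):
        n = 250
        assert bic(5.0, n, 2) - bic(5.0, n, 1) == pytest.approx(np.log(n))

    def test_zero_rss_sentinel(self):
        assert bic(0.0, 50, 1) == -np.inf


class TestFitPolynomial:
    def test_exact_linear_fit(self):
        ages = np.linspace(20, 80, 30)
        y = 3.0 - 0.2 * ages
        fit = fit_polynomial(y, ages, 1)
        assert fit.coefficients == pytest.approx((3.0, -0.2), abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.r2 == pytest.approx(1.0)

    def test_saturated_cubic_interpolates(self):
        ages = np.array([20.0, 40.0, 60.0, 80.0])
        rng = np.random.default_rng(0)
        y = rng.standard_normal(4)
        fit = fit_polynomial(y, ages, 3)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)
        assert np.isnan(fit.se_high)

    def test_collinear_design_raises(self):
        ages = np.array([20.0, 20.0, 60.0, 60.0])
        with pytest.raises(np.linalg.LinAlgError):
            fit_polynomial(np.arange(4.0), ages, 2)

    def test_all_equal_ages_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_polynomial(np.arange(5.0), np.full(5, 30.0), 1)

    def test_raw_basis_coefficients_reproduce_fit(self):
        """Back-transformed raw-age coefficients predict the fitted values."""
        rng = np.random.default_rng(1)
        ages = rng.uniform(20, 86, 80)
        y = 0.5 + 0.03 * ages - 4e-4 * ages**2 + rng.normal(0, 0.05, 80)
        fit = fit_polynomial(y, ages, 2)
        pred = sum(c * ages**k for k, c in enumerate(fit.coefficients))
        resid = y - pred
        assert float(resid @ resid) == pytest.approx(fit.rss, rel=1e-8)

    def test_r2_nesting_in_order(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(20, 86, 120)
        y = rng.standard_normal(120)
        r2s = [fit_polynomial(y, ages, o).r2 for o in (1, 2, 3)]
        assert r2s[0] <= r2s[1] <= r2s[2]

    @pytest.mark.parametrize("seed", range(4))
    def test_linear_t_r2_identity(self, seed):
        """t^2 = R^2 (n-2)/(1-R^2) holds on every linear fit."""
        rng = np.random.default_rng(seed)
        ages = rng.uniform(20, 86, 100)
        y = -0.01 * ages + rng.normal(0, 0.3, 100)
        fit = fit_polynomial(y, ages, 1)
        t = fit.beta_high / fit.se_high
        assert abs(t) == pytest.approx(t_from_r2(fit.r2, fit.n), rel=1e-8)

    def test_null_type_one_error_calibrated(self):
        """Slope test on pure noise rejects at ~5% (Monte-Carlo, n=500)."""
        rng = np.random.default_rng(5)
        ages = rng.uniform(20, 86, 500)
        rej = 0
        for _ in range(200):
            y = rng.standard_normal(500)
            fit = fit_polynomial(y, ages, 1)
            rej += two_sided_p(fit.beta_high / fit.se_high, fit.df) < 0.05
        assert 0.03 <= rej / 200 <= 0.07


class TestSelectAndTest:
    def test_bonferroni_threshold_value(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(20, 86, 60)
        y = 1.0 - 0.01 * ages + rng.normal(0, 0.05, 60)
        tf = fit_component(y, ages, alpha=0.05, m=20)
        assert tf.alpha / tf.m == pytest.approx(2.50e-03, abs=1e-15)

    def test_t_zero_gives_p_one(self):
        assert two_sided_p(0.0, 534) == 1.0

    def test_ci_roundtrip_bitwise(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(20, 86, 90)
        y = -0.005 * ages + rng.normal(0, 0.1, 90)
        tf = fit_component(y, ages)
        se = se_from_ci(tf.ci95[0], tf.ci95[1], tf.df)
        assert se == pytest.approx(tf.se, rel=1e-12)

    def test_quadratic_selection_consistency(self):
        """At SNR >= 3 and n = 500, BIC picks the quadratic >= 90% of runs."""
        spec = synthetic.LoadingSpec(2, (0.5, 0.040, -0.00040), 0.03)
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            ages = rng.uniform(20, 86, 500)
            w = spec.evaluate(ages) + rng.normal(0, spec.noise_sd, 500)
            hits += fit_component(w, ages).selected_order == 2
        assert hits >= 18

    def test_tie_breaks_to_lower_order(self):
        fits = {
            o: trajectories.PolyFit(order=o, coefficients=(0.0,) * (o + 1),
                                    rss=1.0, r2=0.5, bic=-10.0, beta_high=-1.0,
                                    se_high=0.5, n=50, df=50 - o - 1, age_mean=50.0)
            for o in (1, 2, 3)
        }
        tf = trajectories.select_and_test(fits, np.linspace(20, 80, 50))
        assert tf.selected_order == 1


class TestPrintedTableIdentities:
    @pytest.mark.parametrize(
        "r2, expected", [(0.306, 15.34), (0.280, 14.41)]
    )
    def test_t_from_r2_published_rows(self, r2, expected):
        assert round(t_from_r2(r2, 536), 2) == pytest.approx(expected)

    def test_t_from_r2_bounds(self):
        assert t_from_r2(0.0, 100) == 0.0
        assert t_from_r2(1.0, 100) == np.inf
        with pytest.raises(ValueError):
            t_from_r2(1.2, 100)

    def test_t_from_beta_ci_published_row(self):
        t = t_from_beta_ci(-3.92e-04, -4.85e-04, -2.98e-04, 534)
        assert t == pytest.approx(-8.24, abs=0.03)

    def test_symmetric_null_ci(self):
        se = se_from_ci(-1.0, 1.0, 100000)
        assert se == pytest.approx(1 / 1.9600, abs=1e-4)
        assert t_from_beta_ci(0.0, -1.0, 1.0, 100000) == 0.0

    def test_ci_order_enforced(self):
        with pytest.raises(ValueError):
            se_from_ci(1.0, -1.0, 10)

    @pytest.mark.parametrize(
        "t, df, expected",
        [(-22.17, 534, 1.11e-77), (-13.19, 534, 1.36e-34)],
    )
    def test_extreme_p_values_not_flushed(self, t, df, expected):
        p = two_sided_p(t, df)
        assert p == pytest.approx(expected, rel=0.10)
        assert p > 0.0


class TestAgeSubsets:
    def test_max_bound_is_noop(self):
        rng = np.random.default_rng(6)
        cohort = synthetic.sample_cohort(synthetic.scaled_age_bins(200), seed=6)
        ages = cohort["age"].to_numpy()
        w = (1.5 - 0.01 * ages + rng.normal(0, 0.04, 200))[:, None]
        tab = age_subset_analysis(w, cohort, upper_bounds=(float(ages.max()),))
        full, again = tab.iloc[0], tab.iloc[1]
        assert full["n"] == again["n"] == 200
        assert full["t"] == pytest.approx(again["t"], rel=1e-12)

    def test_linear_components_stay_linear_in_subsets(self):
        spec = synthetic.LoadingSpec(1, (1.6, -0.012), 0.04)
        for s in range(5):
            rng = np.random.default_rng(2000 + s)
            cohort = synthetic.sample_cohort(seed=2000 + s)
            ages = cohort["age"].to_numpy()
            w = (spec.evaluate(ages) + rng.normal(0, spec.noise_sd, len(ages)))
            tab = age_subset_analysis(w[:, None], cohort, (80.0, 70.0, 60.0))
            assert (tab["selected_order"] == 1).all()

    def test_subset_sizes_strictly_decrease(self):
        cohort = synthetic.sample_cohort(seed=7)
        w = np.ones((536, 1)) * np.linspace(0, 1, 536)[:, None]
        tab = age_subset_analysis(w, cohort, (80.0, 70.0, 60.0))
        ns = tab.groupby("age_max")["n"].first().sort_index(ascending=False)
        assert (np.diff(ns.to_numpy()) < 0).all()

    def test_quadratic_power_loss_under_range_restriction(self):
        """Restricting to age <= 60 shrinks the vertex-50 quadratic's |t|
        in >= 80% of seeds."""
        spec = synthetic.LoadingSpec(2, (0.5, 0.040, -0.00040), 0.03)
        shrunk = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            cohort = synthetic.sample_cohort(seed=1000 + s)
            ages = cohort["age"].to_numpy()
            w = spec.evaluate(ages) + rng.normal(0, spec.noise_sd, len(ages))
            full = fit_polynomial(w, ages, 2)
            keep = ages <= 60
            sub = fit_polynomial(w[keep], ages[keep], 2)
            shrunk += abs(sub.beta_high / sub.se_high) < abs(
                full.beta_high / full.se_high
            )
        assert shrunk >= 16

    def test_tiny_subset_skipped_with_warning(self):
        cohort = synthetic.sample_cohort(synthetic.scaled_age_bins(30), seed=8)
        w = np.ones((30, 1)) + np.arange(30)[:, None] * 0.01
        with pytest.warns(UserWarning, match="skipped"):
            tab = age_subset_analysis(w, cohort, upper_bounds=(20.5,))
        assert (tab["age_max"] > 20.5).all()
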