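import numpy as np
import pandas as pd
import pytest

from netsurv.fpm import FlexibleParametricModel, fpm_standardize, rcs_basis
from netsurv.standardize import icss_weights


def _weibull_cohort(rng, n=20_000, shape=0.8, scale=7.0, cens=15.0, age=70.0):
    t = scale * rng.weibull(shape, n)
    return pd.DataFrame(
        {
            "time_years": np.minimum(t, cens),
            "event": (t < cens).astype(int),
            "age_diag": np.full(n, age),
            "sex": np.ones(n, dtype=int),
            "year_diag": np.full(n, 1995.0),
        }
    )


class TestSplineBasis:
    def test_three_knots_give_two_columns(self):
        x = np.linspace(-1, 2, 10)
        assert rcs_basis(x, [0.0, 0.5, 1.0]).shape == (10, 2)

    def test_nonincreasing_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.zeros(3), [0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            rcs_basis(np.zeros(3), [0.0, 1.0])

    def test_linear_beyond_boundary_knots(self):
        knots = [0.0, 0.3, 0.7, 1.0]
        for x0 in (-2.0, 3.0):
            h = 1e-4
            b = rcs_basis(np.array([x0 - h, x0, x0 + h]), knots)
            second = (b[0] - 2 * b[1] + b[2]) / h**2
            np.testing.assert_allclose(second, 0.0, atol=1e-5)

    def test_continuity_of_value_and_derivatives_at_knots(self):
        knots = np.array([-1.0, 0.2, 0.9, 2.0])
        eps = 1e-6
        for k in knots:
            left = rcs_basis(np.array([k - eps]), knots)[0]
            right = rcs_basis(np.array([k + eps]), knots)[0]
            dl = rcs_basis(np.array([k - eps]), knots, derivative=True)[0]
            dr = rcs_basis(np.array([k + eps]), knots, derivative=True)[0]
            # value jump bounded by derivative * 2 eps; derivative jump by f'' * 2 eps
            np.testing.assert_allclose(left, right, atol=2 * eps * (np.abs(dl).max() + 1))
            np.testing.assert_allclose(dl, dr, atol=1e-4)

    def test_derivative_matches_finite_difference(self):
        knots = np.array([-1.0, 0.0, 1.0, 2.5])
        x = np.linspace(-2, 3, 31)
        h = 1e-6
        fd = (rcs_basis(x + h, knots) - rcs_basis(x - h, knots)) / (2 * h)
        np.testing.assert_allclose(rcs_basis(x, knots, derivative=True), fd, atol=1e-5)


class TestAllCauseRecovery:
    def test_weibull_log_cumhaz_recovered(self):
        """With zero expected hazard the model is an ordinary parametric
        survival model; averaged over replicate datasets the fitted log
        cumulative hazard tracks the Weibull truth across the central
        event-time range."""
        shape, scale = 0.8, 7.0
        errs = []
        for r in range(10):
            rng = np.random.default_rng(np.random.SeedSequence((42, r)))
            coh = _weibull_cohort(rng, shape=shape, scale=scale)
            m = FlexibleParametricModel(df_baseline=5, age="none", df_time=0).fit(coh)
            qs = np.quantile(coh.loc[coh.event == 1, "time_years"],
                             np.linspace(0.05, 0.95, 19))
            fitted = np.log(m.cumulative_excess_hazard([70.0], qs)[0])
            errs.append(fitted - (shape * np.log(qs) - shape * np.log(scale)))
        assert np.abs(np.mean(errs, axis=0)).max() < 0.02

    def test_loglik_is_a_local_optimum(self):
        rng = np.random.default_rng(0)
        coh = _weibull_cohort(rng, n=4000)
        m = FlexibleParametricModel(df_baseline=3, age="none", df_time=0).fit(coh)
        t = coh["time_years"].to_numpy()
        d = coh["event"].to_numpy(dtype=float)
        Z, U = m.design_.matrices(np.log(t), coh["age_diag"].to_numpy())
        nll = m._make_negloglik(Z, U, t, d, np.zeros_like(t))
        base = nll(m.coef_)[0]
        for _ in range(100):
            probe = m.coef_ + rng.normal(scale=0.05, size=len(m.coef_))
            assert nll(probe)[0] >= base - 1e-6

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(1)
        coh = _weibull_cohort(rng, n=3000)
        m1 = FlexibleParametricModel(df_baseline=4, age="none", df_time=0).fit(coh)
        m2 = FlexibleParametricModel(df_baseline=4, age="none", df_time=0).fit(coh)
        np.testing.assert_allclose(m1.coef_, m2.coef_, atol=1e-8)


class TestPrediction:
    def test_relative_survival_approaches_one_at_early_times(self, spec2, rt_gompertz):
        from netsurv.simulate import generate_cohort

        coh = generate_cohort(spec2, rt_gompertz, np.random.default_rng(3), n=4000)
        m = FlexibleParametricModel(age="grouped").fit(coh, rate_table=rt_gompertz)
        r = m.predict_relative_survival([55.0], [1e-8])
        assert r[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_prediction_time_rejected(self, spec2, rt_gompertz):
        from netsurv.simulate import generate_cohort

        coh = generate_cohort(spec2, rt_gompertz, np.random.default_rng(3), n=2000)
        m = FlexibleParametricModel(age="grouped").fit(coh, rate_table=rt_gompertz)
        with pytest.raises(ValueError):
            m.predict_relative_survival([55.0], [0.0])

    def test_grouped_age_gives_identical_curves_within_group(self, spec2, rt_gompertz):
        from netsurv.simulate import generate_cohort

        coh = generate_cohort(spec2, rt_gompertz, np.random.default_rng(4), n=4000)
        m = FlexibleParametricModel(age="grouped").fit(coh, rate_table=rt_gompertz)
        r = m.predict_relative_survival([66.0, 70.0, 74.9], [2.0, 8.0])
        np.testing.assert_allclose(r[0], r[1], atol=1e-12)
        np.testing.assert_allclose(r[0], r[2], atol=1e-12)

    def test_homogeneous_age_predictions_match_pohar_perme(self, spec2, rt_gompertz):
        """On a single-age cohort the model-based curve and the Pohar Perme
        lifetable estimate are two routes to the same quantity."""
        from dataclasses import replace

        from netsurv.estimators import pohar_perme
        from netsurv.intervals import split_monthly
        from netsurv.simulate import generate_cohort

        spec = replace(spec2, age_mean=72.0, age_sd=1e-9, age_range=(72.0, 72.0000001))
        coh = generate_cohort(spec, rt_gompertz, np.random.default_rng(19), n=20_000)
        m = FlexibleParametricModel(age="continuous").fit(coh, rate_table=rt_gompertz,
                                                          max_years=15.0)
        pp = pohar_perme(split_monthly(coh, rt_gompertz))
        times = np.quantile(coh.loc[coh.event == 1, "time_years"], [0.25, 0.5, 0.75, 0.9])
        model_curve = m.predict_relative_survival([72.0], times)[0]
        np.testing.assert_allclose(model_curve, pp.rel_surv_at(times), atol=0.015)


class TestStandardization:
    def test_single_subject_returns_own_curve(self, spec2, rt_gompertz):
        from netsurv.simulate import generate_cohort

        coh = generate_cohort(spec2, rt_gompertz, np.random.default_rng(5), n=3000)
        m = FlexibleParametricModel(age="grouped").fit(coh, rate_table=rt_gompertz)
        times = np.array([2.0, 6.0])
        fc = m.standardized_survival(np.array([68.0]), times, n_boot=0)
        np.testing.assert_allclose(
            fc.rel_surv, m.predict_relative_survival([68.0], times)[0], atol=1e-12
        )

    def test_internal_external_agree_at_reference_proportions(self, spec2, rt_gompertz):
        from netsurv.simulate import generate_cohort

        coh = generate_cohort(spec2, rt_gompertz, np.random.default_rng(6), n=3000)
        m = FlexibleParametricModel(age="grouped").fit(coh, rate_table=rt_gompertz)
        ages = np.concatenate([np.full(c, a) for c, a in
                               zip([7, 12, 23, 29, 29], [40.0, 50.0, 60.0, 70.0, 80.0])])
        times = np.array([3.0, 9.0])
        internal = m.standardized_survival(ages, times, mode="internal", n_boot=0)
        external = m.standardized_survival(ages, times, mode="external",
                                           weights=icss_weights(1), n_boot=0)
        np.testing.assert_allclose(internal.rel_surv, external.rel_surv, atol=1e-12)

    def test_bootstrap_ci_width_shrinks_with_sample_size(self, spec2, rt_gompertz):
        from netsurv.simulate import generate_cohort

        widths = []
        for i, n in enumerate((2000, 8000, 32_000)):
            coh = generate_cohort(spec2, rt_gompertz,
                                  np.random.default_rng(np.random.SeedSequence((30, i))), n=n)
            m = FlexibleParametricModel(age="grouped").fit(coh, rate_table=rt_gompertz)
            fc = fpm_standardize(m, coh, [5.0], n_boot=200,
                                 rng=np.random.default_rng(100 + i))
            widths.append(float(fc.ci_high[0] - fc.ci_low[0]))
        assert widths[0] > widths[1] > widths[2]
        for a, b in zip(widths, widths[1:]):
            assert 1.2 < a / b < 3.5  # roughly 1/sqrt(n) per 4x n

    def test_grouped_age_more_biased_than_continuous_under_persistent_effect(
            self, spec2, rt_gompertz):
        """Grouping age in the model leaves residual confounding when the
        age effect persists over follow-up: the grouped fit's standardized
        estimate overshoots while the continuous fit stays near the truth
        at 10 and 15 years."""
        from netsurv.scenarios import true_standardized
        from netsurv.simulate import generate_cohort

        times = np.array([10.0, 15.0])
        err = {"grouped": [], "continuous": []}
        for r in range(5):
            coh = generate_cohort(spec2, rt_gompertz,
                                  np.random.default_rng(np.random.SeedSequence((55, r))))
            ages = coh["age_diag"].to_numpy()
            truth = true_standardized(spec2, times, "internal", ages=ages)
            for coding in ("grouped", "continuous"):
                m = FlexibleParametricModel(age=coding).fit(coh, rate_table=rt_gompertz,
                                                            max_years=15.0)
                fc = m.standardized_survival(ages, times, n_boot=0)
                err[coding].append((fc.rel_surv - truth) * 100)
        grouped = np.mean(err["grouped"], axis=0)
        continuous = np.mean(err["continuous"], axis=0)
        assert np.all(grouped > 0)  # grouped overshoots
        assert np.all(np.abs(grouped) > np.abs(continuous))


def test_model_json_roundtrip(spec2, rt_gompertz):
    from netsurv.simulate import generate_cohort

    coh = generate_cohort(spec2, rt_gompertz, np.random.default_rng(7), n=2000)
    m = FlexibleParametricModel(age="continuous").fit(coh, rate_table=rt_gompertz)
    clone = FlexibleParametricModel.from_dict(m.to_dict())
    times = np.array([1.0, 5.0, 12.0])
    np.testing.assert_allclose(
        clone.predict_relative_survival([60.0, 85.0], times),
        m.predict_relative_survival([60.0, 85.0], times),
        atol=1e-12,
    )
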