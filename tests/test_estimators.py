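import numpy as np
import pytest

from netsurv.estimators import (
    Brenner,
    EdererII,
    PoharPerme,
    brenner,
    brenner_weights,
    curve_variance,
    ederer2,
    pohar_perme,
)
from netsurv.intervals import IntervalTable, split_monthly
from netsurv.standardize import StandardWeights, icss_weights

from conftest import make_cohort


def _table(breaks, y, d, rate, s_star=None, ages=None):
    """Hand-built IntervalTable from dense arrays."""
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=np.int64)
    rate = np.broadcast_to(np.asarray(rate, dtype=float), y.shape)
    at_risk = y > 0
    if s_star is None:
        s_star = np.ones_like(y)
    return IntervalTable(
        breaks=np.asarray(breaks, dtype=float), y=y, d=d,
        p_star=np.exp(-rate), d_star=rate * y, s_star=np.asarray(s_star, dtype=float),
        at_risk=at_risk, ages=np.full(y.shape[0], 70.0) if ages is None else np.asarray(ages),
    )


class TestEdererII:
    def test_hand_computed_single_interval(self):
        """10 subjects, one 1-year interval, 2 deaths at mid-interval,
        p* = exp(-0.1): lambda = (2 - 0.9)/9, R = exp(-lambda)."""
        y = np.array([[1.0]] * 8 + [[0.5]] * 2)
        d = np.array([[0]] * 8 + [[1]] * 2)
        curve = ederer2(_table([0.0, 1.0], y, d, 0.1))
        assert curve.lam[0] == pytest.approx(1.1 / 9, abs=1e-12)
        assert curve.rel_surv[0] == pytest.approx(np.exp(-1.1 / 9), abs=1e-12)
        assert curve.rel_surv[0] == pytest.approx(0.88495, abs=5e-6)

    def test_zero_expected_rates_reduce_to_all_cause_lifetable(self, rt_zero):
        coh = make_cohort([0.4, 1.1, 2.5, 6.0, 9.9, 15.0], [1, 1, 0, 1, 0, 0])
        it = split_monthly(coh, rt_zero)
        curve = ederer2(it)
        # independent occurrence/exposure cumulative hazard on the same grid
        lam = np.where(it.y.sum(0) > 0, it.d.sum(0) / np.where(it.y.sum(0) > 0,
                                                               it.y.sum(0), 1.0), 0.0)
        np.testing.assert_allclose(curve.cumhaz, np.cumsum(lam * it.widths), atol=1e-12)

    def test_balanced_observed_and_expected_deaths_give_unit_relative_survival(self):
        y = np.ones((4, 2))
        d = np.array([[1, 0], [0, 1], [0, 0], [0, 0]])
        rate = np.full((4, 2), 0.25)  # sum d* = 1 = sum d per interval
        curve = ederer2(_table([0.0, 1.0, 2.0], y, d, rate))
        np.testing.assert_allclose(curve.lam, 0.0, atol=1e-14)
        np.testing.assert_allclose(curve.rel_surv, 1.0, atol=1e-14)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ederer2(_table([0.0, 1.0], np.empty((0, 1)), np.empty((0, 1), dtype=int), 0.0))

    def test_zero_persontime_intervals_flagged_and_curve_continues(self, rt_const):
        it = split_monthly(make_cohort([0.5, 0.6], [1, 1]), rt_const, max_years=1.0)
        curve = ederer2(it)
        assert curve.zero_risk[-1]
        assert np.isfinite(curve.rel_surv).all()
        # hazard frozen at zero after everyone has died
        assert curve.cumhaz[-1] == curve.cumhaz[8]


class TestPoharPerme:
    def test_hand_computed_two_subject_toy(self):
        """Subject A (S* = 0.5, weight 2) alone at risk with one death in a
        monthly interval: lambda = (2 - 2*0.01/12)/(2/12) per year."""
        y = np.array([[1 / 12], [0.0]])
        d = np.array([[1], [0]])
        rate = np.full((2, 1), 0.01)
        s_star = np.array([[0.5], [1.0]])
        curve = pohar_perme(_table([0.0, 1 / 12], y, d, rate, s_star=s_star))
        expect = (2.0 - 2.0 * 0.01 / 12) / (2.0 / 12)
        assert curve.lam[0] == pytest.approx(expect, abs=1e-12)
        assert curve.lam[0] == pytest.approx(11.99, abs=1e-6)

    def test_identical_to_ederer2_under_homogeneous_expected_survival(self, rt_gompertz):
        # one shared age/sex/year: weights cancel exactly
        coh = make_cohort([0.7, 2.2, 5.5, 9.1, 15.0, 12.3], [1, 1, 0, 1, 0, 1],
                          age=71.4, sex=2, year=1997.1)
        it = split_monthly(coh, rt_gompertz)
        np.testing.assert_allclose(pohar_perme(it).lam, ederer2(it).lam,
                                   rtol=1e-13, atol=1e-14)

    def test_equals_ederer2_with_zero_rate_table(self, rt_zero):
        coh = make_cohort([1.0, 3.0, 8.0], [1, 0, 1], age=[50.0, 70.0, 90.0])
        it = split_monthly(coh, rt_zero)
        np.testing.assert_array_equal(pohar_perme(it).lam, ederer2(it).lam)


class TestBrenner:
    def test_unit_weights_reduce_to_ederer2(self, rt_gompertz):
        coh = make_cohort([1.0, 4.0, 9.0], [1, 1, 0], age=[40.0, 60.0, 80.0])
        it = split_monthly(coh, rt_gompertz)
        np.testing.assert_array_equal(brenner(it, np.ones(3)).lam, ederer2(it).lam)

    def test_weight_scale_invariance(self, rt_gompertz):
        coh = make_cohort([1.0, 4.0, 9.0], [1, 1, 0], age=[40.0, 60.0, 80.0])
        it = split_monthly(coh, rt_gompertz)
        w = np.array([0.5, 1.5, 2.0])
        np.testing.assert_allclose(brenner(it, w).lam, brenner(it, 2 * w).lam, atol=1e-12)

    def test_nonpositive_weights_rejected(self, rt_gompertz):
        it = split_monthly(make_cohort([1.0], [1]), rt_gompertz)
        with pytest.raises(ValueError):
            brenner(it, np.array([0.0]))

    def test_weights_are_reference_over_observed_proportions(self):
        w = StandardWeights(weights=np.array([0.29, 0.71]), edges=(15.0, 65.0))
        ages = np.array([40.0] * 58 + [70.0] * 42)
        got = brenner_weights(ages, w)
        assert got[0] == pytest.approx(0.29 / 0.58)
        assert got[-1] == pytest.approx(0.71 / 0.42)

    def test_cohort_matching_reference_gets_unit_weights(self):
        ages = np.concatenate([np.full(c, a) for c, a in
                               zip([7, 12, 23, 29, 29], [40, 50, 60, 70, 80])])
        np.testing.assert_allclose(brenner_weights(ages, icss_weights(1)), 1.0)

    def test_empty_weighted_group_raises(self):
        ages = np.full(10, 40.0)  # nobody aged 75+
        with pytest.raises(ValueError, match="empty"):
            brenner_weights(ages, icss_weights(1))


class TestVariance:
    def test_no_deaths_degenerate_interval_free_ci(self, rt_const):
        it = split_monthly(make_cohort([2.0, 3.0], [0, 0]), rt_const, max_years=2.0)
        curve = ederer2(it)
        assert np.all(curve.var_cumhaz == 0.0)
        np.testing.assert_allclose(curve.ci_low, curve.rel_surv)
        np.testing.assert_allclose(curve.ci_high, curve.rel_surv)

    def test_single_death_poisson_variance(self):
        # one death, weight 1, total person-time 10, interval length 1
        y = np.vstack([np.ones((9, 1)), [[0.5]], [[0.5]]])
        d = np.zeros((11, 1), dtype=int)
        d[9, 0] = 1
        it = _table([0.0, 1.0], y, d, 0.0)
        assert it.y.sum() == pytest.approx(10.0)
        assert curve_variance(it)[0] == pytest.approx(0.01, abs=1e-14)

    def test_variance_nondecreasing_in_time(self, rt_gompertz, spec1):
        from netsurv.simulate import generate_cohort

        coh = generate_cohort(spec1, rt_gompertz, np.random.default_rng(8), n=400)
        it = split_monthly(coh, rt_gompertz)
        for curve in (ederer2(it), pohar_perme(it)):
            assert np.all(np.diff(curve.var_cumhaz) >= -1e-18)


class TestSubdivisionInvariance:
    def test_constant_conditions_make_width_irrelevant(self, rt_gompertz):
        """Halving the interval width leaves the curve unchanged at shared
        grid points when no event/censoring/rate change is interior."""
        # events and age/year crossings all on multiples of 1/6 year
        coh = make_cohort([1 / 6, 3 / 6, 5 / 6, 1.0, 1.0], [1, 1, 0, 1, 0],
                          age=70.5, year=1995.5)
        coarse = split_monthly(coh, rt_gompertz, max_years=1.0, width=1 / 6)
        fine = split_monthly(coh, rt_gompertz, max_years=1.0, width=1 / 12)
        shared = np.arange(1, 7) / 6
        for est in (ederer2, pohar_perme):
            np.testing.assert_allclose(
                est(coarse).rel_surv_at(shared), est(fine).rel_surv_at(shared), atol=1e-12
            )


class TestSklearnInterface:
    def test_estimator_classes_agree_with_functions(self, rt_gompertz, spec1):
        from netsurv.simulate import generate_cohort

        coh = generate_cohort(spec1, rt_gompertz, np.random.default_rng(13), n=500)
        it = split_monthly(coh, rt_gompertz)
        for cls, fn in ((EdererII, ederer2), (PoharPerme, pohar_perme)):
            model = cls().fit(coh, rate_table=rt_gompertz)
            np.testing.assert_allclose(model.curve_.rel_surv, fn(it).rel_surv)
        bren = Brenner(reference=1).fit(coh, rate_table=rt_gompertz)
        expect = brenner(it, brenner_weights(it.ages, icss_weights(1)))
        np.testing.assert_allclose(bren.curve_.rel_surv, expect.rel_surv)

    def test_get_set_params_roundtrip(self):
        est = PoharPerme(interval_width=0.25, max_years=10.0)
        params = est.get_params()
        assert params["interval_width"] == 0.25
        est2 = PoharPerme().set_params(**params)
        assert est2.max_years == 10.0


class TestConsistency:
    @pytest.mark.parametrize("estimator", [ederer2, pohar_perme])
    def test_single_age_estimates_recover_truth(self, estimator, spec1, rt_gompertz):
        """On a large single-age cohort both estimators agree with the
        analytic net survival within Monte-Carlo error."""
        from dataclasses import replace

        from netsurv.simulate import generate_cohort

        spec = replace(spec1, age_mean=70.0, age_sd=1e-9, age_range=(70.0, 70.0000001))
        coh = generate_cohort(spec, rt_gompertz, np.random.default_rng(17), n=50_000)
        it = split_monthly(coh, rt_gompertz)
        curve = estimator(it)
        for t in (5.0, 10.0, 15.0):
            truth = float(spec.net_survival(70.0, t))
            est = float(curve.rel_surv_at([t])[0])
            se = float(np.sqrt(curve.var_cumhaz_at([t])[0])) * est
            assert abs(est - truth) < 3 * se, (t, est, truth, se)
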