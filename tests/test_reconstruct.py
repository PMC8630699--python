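"""KM curve inversion and censored maximum-likelihood fitting."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter, LogLogisticFitter

from melcea import (
    DigitizedCurve,
    ParametricFit,
    PseudoIPD,
    SimulationRecipe,
    SurvivalSpec,
    digitize,
    fit_all,
    fit_parametric,
    km_estimate,
    reconstruct_ipd,
    select_best,
    simulate_ipd,
)


class TestReconstructIpd:
    def test_flat_curve_all_censored(self):
        curve = DigitizedCurve(
            times=[0.0, 8.0],
            survival=[1.0, 1.0],
            risk_times=[0.0, 8.0],
            n_risk=[10, 10],
            n_total=10,
        )
        ipd = reconstruct_ipd(curve)
        assert len(ipd) == 10
        assert ipd.n_events == 0
        assert np.all(ipd.times == 8.0)

    def test_single_drop_exact_inversion(self):
        # 1.0 -> 0.5 with 10 at risk and no censoring: exactly 5 events
        curve = DigitizedCurve(
            times=[0.0, 5.0],
            survival=[1.0, 0.5],
            risk_times=[0.0, 5.0],
            n_risk=[10, 10],
            n_total=10,
        )
        ipd = reconstruct_ipd(curve)
        assert len(ipd) == 10
        assert ipd.n_events == 5
        assert np.all(ipd.times[ipd.events == 1] == 5.0)

    def test_round_trip_against_synthetic_km(self, pfs_spec):
        recipe = SimulationRecipe(
            spec=pfs_spec, n_subjects=200, seed=7, accrual_months=12, cutoff_months=30
        )
        ipd = simulate_ipd(recipe)
        curve = digitize(ipd, n_points=40)
        rec = reconstruct_ipd(curve)
        assert len(rec) == curve.n_total
        kmf = KaplanMeierFitter().fit(rec.times, event_observed=rec.events)
        km_at_grid = kmf.predict(curve.times).to_numpy()
        assert np.max(np.abs(km_at_grid - curve.survival)) <= 0.02

    def test_inconsistent_risk_table_rejected(self):
        with pytest.raises(ValueError):
            DigitizedCurve(
                times=[0.0, 5.0],
                survival=[1.0, 0.5],
                risk_times=[0.0, 5.0],
                n_risk=[20, 10],
                n_total=10,
            )

    def test_curve_csv_round_trip(self, tmp_path, pfs_spec):
        ipd = simulate_ipd(
            SimulationRecipe(pfs_spec, n_subjects=50, seed=1, cutoff_months=24)
        )
        curve = digitize(ipd, n_points=20)
        curve.to_csv(tmp_path / "c.csv", tmp_path / "r.csv")
        back = DigitizedCurve.from_csv(tmp_path / "c.csv", tmp_path / "r.csv", 50)
        np.testing.assert_allclose(back.survival, curve.survival)
        np.testing.assert_array_equal(back.n_risk, curve.n_risk)


class TestFitParametric:
    def test_exponential_mle_matches_closed_form(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1 / 0.12, size=400)
        cens = t > 20
        ipd = PseudoIPD(np.where(cens, 20.0, t), (~cens).astype(int))
        fit = fit_parametric(ipd, "exponential")
        closed_form = ipd.n_events / ipd.times.sum()
        assert fit.spec.params[0] == pytest.approx(closed_form, rel=1e-8)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)

    def test_loglogistic_parameter_recovery(self):
        truth = SurvivalSpec("loglogistic", (0.0392, 1.525))
        ipd = simulate_ipd(
            SimulationRecipe(truth, n_subjects=1000, seed=11, accrual_months=0)
        )
        fit = fit_parametric(ipd, "loglogistic")
        theta, kappa = fit.spec.params
        assert theta == pytest.approx(0.0392, rel=0.15)
        assert kappa == pytest.approx(1.525, rel=0.15)

    def test_weibull_shape_near_one_on_exponential_data(self):
        truth = SurvivalSpec("exponential", (0.1,))
        ipd = simulate_ipd(
            SimulationRecipe(truth, n_subjects=1000, seed=5, accrual_months=0)
        )
        fit = fit_parametric(ipd, "weibull")
        assert abs(fit.spec.params[0] - 1.0) < 0.1

    def test_loglik_matches_lifelines(self, pfs_spec):
        # independent censored-likelihood oracle for the log-logistic family
        ipd = simulate_ipd(
            SimulationRecipe(pfs_spec, n_subjects=300, seed=2, cutoff_months=24)
        )
        fit = fit_parametric(ipd, "loglogistic")
        llf = LogLogisticFitter().fit(ipd.times, event_observed=ipd.events)
        # lifelines parameterizes S(t) = 1/(1 + (t/alpha)^beta)
        theta_ll = llf.alpha_ ** -llf.beta_
        assert fit.spec.params[0] == pytest.approx(theta_ll, rel=1e-3)
        assert fit.spec.params[1] == pytest.approx(llf.beta_, rel=1e-3)
        assert fit.loglik == pytest.approx(llf.log_likelihood_, abs=1e-3)

    def test_requires_events_and_size(self):
        with pytest.raises(ValueError):
            fit_parametric(PseudoIPD(np.arange(1, 20.0), np.zeros(19, int)), "weibull")
        with pytest.raises(ValueError):
            fit_parametric(PseudoIPD(np.array([1.0]), np.array([1])), "weibull")


class TestSelectBest:
    def _fit(self, family, loglik, k):
        spec = {
            "exponential": SurvivalSpec("exponential", (0.1,)),
            "weibull": SurvivalSpec("weibull", (1.0, 10.0)),
            "generalized_gamma": SurvivalSpec("generalized_gamma", (2.0, 1.0, 0.5)),
        }[family]
        return ParametricFit(spec=spec, loglik=loglik, n_params=k)

    def test_single_fit(self):
        fit = self._fit("weibull", -50.0, 2)
        assert select_best([fit]) is fit

    def test_argmin_aic(self):
        fits = [
            self._fit("weibull", -48.0, 2),  # aic 100
            self._fit("exponential", -48.25, 1),  # aic 98.5
            self._fit("generalized_gamma", -47.6, 3),  # aic 101.2
        ]
        assert select_best(fits).aic == pytest.approx(98.5)

    def test_tie_broken_by_fewer_parameters(self):
        fits = [
            self._fit("weibull", -48.0, 2),  # aic 100
            self._fit("exponential", -49.0, 1),  # aic 100
        ]
        assert select_best(fits).family == "exponential"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])

    @pytest.mark.parametrize("seed", [17, 18, 19])
    def test_exponential_data_selects_nested_family(self, seed):
        # the selected family must nest the constant-hazard truth, and its
        # AIC advantage over the truth family is bounded by the chi-square
        # fluctuation of the extra parameters (2*df at the 95% level)
        truth = SurvivalSpec("exponential", (0.09,))
        ipd = simulate_ipd(
            SimulationRecipe(truth, n_subjects=2000, seed=seed, accrual_months=0)
        )
        fits = fit_all(ipd)
        best = select_best(fits)
        nests_exponential = {"exponential", "weibull", "gompertz", "generalized_gamma"}
        assert best.family in nests_exponential
        aic_exp = next(f.aic for f in fits if f.family == "exponential")
        assert best.aic <= aic_exp
        extra_df = best.n_params - 1
        from scipy.stats import chi2

        bound = chi2.ppf(0.95, max(extra_df, 1)) - 2 * extra_df
        assert aic_exp - best.aic <= max(2.0, bound) + 0.5
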