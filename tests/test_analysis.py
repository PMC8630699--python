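"""Incremental analysis, parameter sampling, PSA and subgroups."""

import numpy as np
import pandas as pd
import pytest

from melcea import (
    ModelConfig,
    net_monetary_benefit,
    one_way_sa,
    run_base_case,
    run_psa,
    run_subgroups,
    sample_parameters,
)
from melcea.analysis import _evaluate_arms


@pytest.fixture(scope="module")
def fast_cfg():
    # coarse horizon keeps the sampling-behaviour tests quick; the full
    # calibrated configuration is exercised in the acceptance suite
    return ModelConfig(horizon_months=240)


class TestBaseCase:
    def test_identical_arms_have_undefined_icer(self, pset, fast_cfg):
        neutral = (
            pset.replace_parameter("hr_os", baseline=1.0, low=1.0, high=1.0)
            .replace_parameter("hr_pfs", baseline=1.0, low=1.0, high=1.0)
            .replace_parameter(
                "response_share_combination", baseline=0.13, low=0.13, high=0.13
            )
        )
        res = _evaluate_arms(neutral, neutral.baseline_values(), fast_cfg)
        assert float(res.d_qalys) == pytest.approx(0.0, abs=1e-12)
        # arms still differ in drug cost, but the effect increment is zero
        assert np.isnan(res.icer_per_qaly)

    def test_icer_is_ratio_of_unrounded_increments(self, pset, cfg):
        res = run_base_case(pset, cfg)
        assert float(res.icer_per_qaly) == pytest.approx(
            float(res.d_cost) / float(res.d_qalys), rel=1e-14
        )
        # rounding the increments first gives a visibly different number
        rounded = round(float(res.d_cost)) / round(float(res.d_qalys), 2)
        assert abs(rounded - float(res.icer_per_qaly)) > 100

    def test_summary_table_shape(self, pset, fast_cfg):
        table = run_base_case(pset, fast_cfg).summary()
        assert list(table["strategy"]) == ["ipilimumab", "combination", "incremental"]


class TestNmb:
    def test_linear_values(self):
        assert net_monetary_benefit(100_000, 1.0, 150_000) == 50_000
        assert net_monetary_benefit(77_000, 0.5, 0.0) == -77_000

    def test_rejects_negative_wtp(self):
        with pytest.raises(ValueError):
            net_monetary_benefit(0.0, 1.0, -1.0)

    def test_decision_rule_equivalence_with_icer_threshold(self):
        # for two strategies, max-NMB choice == (ICER < WTP) whenever the
        # comparator adds QALYs; checked over a random grid
        rng = np.random.default_rng(42)
        for _ in range(200):
            c0, c1 = rng.uniform(0, 3e5, 2)
            q0 = rng.uniform(0.1, 3)
            q1 = q0 + rng.uniform(0.01, 2)
            wtp = rng.uniform(0, 2e5)
            prefers_1 = net_monetary_benefit(c1, q1, wtp) > net_monetary_benefit(c0, q0, wtp)
            icer = (c1 - c0) / (q1 - q0)
            assert prefers_1 == (icer < wtp)


class TestOneWaySa:
    def test_degenerate_parameter_has_zero_span(self, pset, fast_cfg):
        frozen = pset.replace_parameter("cost_bsc", low=4492.0, high=4492.0)
        table = one_way_sa(frozen, fast_cfg).set_index("parameter")
        assert table.loc["cost_bsc", "span"] == pytest.approx(0.0, abs=1e-9)

    def test_sorted_by_span_descending(self, pset, fast_cfg):
        table = one_way_sa(pset, fast_cfg)
        assert np.all(np.diff(table["span"]) <= 1e-12)

    def test_span_invariant_to_parameter_order(self, pset, fast_cfg):
        reversed_pset = type(pset)(
            pset.survival,
            dict(reversed(list(pset.parameters.items()))),
            pset.settings,
        )
        a = one_way_sa(pset, fast_cfg).set_index("parameter")["span"]
        b = one_way_sa(reversed_pset, fast_cfg).set_index("parameter")["span"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


class TestSampleParameters:
    def test_gamma_moment_matching(self, pset):
        rng = np.random.default_rng(0)
        draws = sample_parameters(pset, rng, 10_000)
        x = draws["cost_ipilimumab_per_mg"]
        assert x.mean() == pytest.approx(166.0, rel=0.01)
        sd = (199 - 133) / 3.92
        assert x.std() == pytest.approx(sd, rel=0.05)
        # implied gamma shape/scale from the moment match
        assert (166 / sd) ** 2 == pytest.approx(97.2, abs=0.5)
        assert sd**2 / 166 == pytest.approx(1.708, abs=0.01)  # shape*scale = mean

    def test_lognormal_hr_quantiles_recover_ci(self, pset):
        rng = np.random.default_rng(1)
        x = sample_parameters(pset, rng, 50_000)["hr_os"]
        lo, hi = np.percentile(x, [2.5, 97.5])
        assert lo == pytest.approx(0.38, abs=0.01)
        assert hi == pytest.approx(0.66, abs=0.015)

    def test_beta_draws_in_unit_interval(self, pset):
        rng = np.random.default_rng(2)
        draws = sample_parameters(pset, rng, 5_000)
        for name in ("u_response", "u_stable", "u_progressed", "response_share_combination"):
            assert np.all((draws[name] >= 0) & (draws[name] <= 1))
            p = pset[name]
            assert draws[name].mean() == pytest.approx(p.baseline, abs=0.01)

    def test_degenerate_parameter_stays_constant(self, pset):
        frozen = pset.replace_parameter("cost_bsc", low=4492.0, high=4492.0)
        draws = sample_parameters(frozen, np.random.default_rng(3), 100)
        assert np.all(draws["cost_bsc"] == 4492.0)


class TestPsa:
    def test_same_seed_bit_reproducible(self, pset, fast_cfg):
        a = run_psa(pset, fast_cfg, n_draws=300, seed=11)
        b = run_psa(pset, fast_cfg, n_draws=300, seed=11)
        np.testing.assert_array_equal(a.result.d_cost, b.result.d_cost)
        np.testing.assert_array_equal(a.result.d_qalys, b.result.d_qalys)

    def test_wtp_limits(self, pset, fast_cfg):
        psa = run_psa(pset, fast_cfg, n_draws=500, seed=4)
        at_zero = psa.probability_cost_effective(0.0)
        assert at_zero == pytest.approx(np.mean(psa.result.d_cost < 0))
        huge = psa.probability_cost_effective(1e12)
        assert huge == pytest.approx(np.mean(psa.result.d_qalys > 0))

    def test_ceac_frame_on_grid(self, pset, fast_cfg):
        psa = run_psa(pset, fast_cfg, n_draws=200, seed=5)
        ceac = psa.ceac
        assert len(ceac) == len(psa.wtp_grid)
        assert ceac["probability_cost_effective"].between(0, 1).all()

    def test_rejects_empty_run(self, pset, fast_cfg):
        with pytest.raises(ValueError):
            run_psa(pset, fast_cfg, n_draws=0, seed=1)

    def test_ceac_stable_across_seeds(self, pset, cfg):
        # at 10,000 draws the acceptability estimates are Monte Carlo
        # stable to well under 2 percentage points
        wtps = np.array([50_000.0, 100_000.0, 150_000.0])
        probs = [
            run_psa(pset, cfg, n_draws=10_000, seed=s).probability_cost_effective(wtps)
            for s in (101, 202)
        ]
        assert np.max(np.abs(probs[0] - probs[1])) < 0.02


class TestSubgroups:
    def test_base_case_hrs_reproduce_base_icer(self, pset, fast_cfg):
        table = pd.DataFrame(
            [
                {
                    "subgroup": "base",
                    "pfs_hr": 0.69,
                    "pfs_ci_low": 0.55,
                    "pfs_ci_high": 0.87,
                    "os_hr": 0.50,
                    "os_ci_low": 0.38,
                    "os_ci_high": 0.66,
                }
            ]
        )
        out = run_subgroups(pset, table, fast_cfg, n_draws=50, seed=1)
        base = run_base_case(pset, fast_cfg)
        assert out.loc[0, "icer_per_qaly"] == pytest.approx(
            float(base.icer_per_qaly), rel=1e-12
        )

    def test_icer_monotone_in_os_hr(self, pset, fast_cfg):
        icers = []
        for hr in (0.35, 0.50, 0.65, 0.80):
            sub = pset.replace_parameter("hr_os", baseline=hr, low=hr, high=hr)
            icers.append(float(run_base_case(sub, fast_cfg).icer_per_qaly))
        assert np.all(np.diff(icers) > 0)
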