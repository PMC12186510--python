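"""Cohort solver, discounting, microsimulation, and their mutual agreement."""
import numpy as np
import pytest

import mibcsim as m
from mibcsim.engine import ModelValidationError

from conftest import random_chain_model, two_state_model, two_state_params


class TestDiscountFactor:
    def test_zero_rate_is_one(self):
        assert m.discount_factor(7.3, 0.0) == 1.0

    def test_one_year_at_three_percent(self):
        assert m.discount_factor(1.0, 0.03) == pytest.approx(1 / 1.03, abs=1e-12)

    def test_quarterly_compounding_matches_annual(self):
        quarterly = m.discount_factor(0.25, 0.03) ** 4
        assert quarterly == pytest.approx(m.discount_factor(1.0, 0.03), abs=1e-12)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            m.discount_factor(-1.0, 0.03)
        with pytest.raises(ValueError):
            m.discount_factor(1.0, -0.03)


def brute_force_expectation(p_die, cost, utility, discount, n_cycles, cycle_len=0.25):
    """Independent oracle: enumerate all alive/dead path prefixes."""
    total_cost = total_qaly = 0.0
    p_alive = 1.0
    for k in range(n_cycles):
        df = (1 + discount) ** (-(k * cycle_len))
        total_cost += df * p_alive * cost
        total_qaly += df * p_alive * utility * cycle_len
        p_alive *= 1 - p_die
    return total_cost, total_qaly


class TestCohortSolver:
    def test_identity_model_accrues_full_horizon(self):
        """Single always-alive state, utility 1, no discounting: 5.0 QALYs."""
        params = two_state_params(p_die=0.0, cost=0.0, utility=1.0,
                                  discount=0.0, horizon=5.0)
        res = m.evaluate_cohort(two_state_model(), params)
        assert res.total_cost == 0.0
        assert res.total_qaly == pytest.approx(5.0, abs=1e-12)

    def test_two_state_toy_expected_cost_oracle(self):
        """Half die each cycle, $100 at each cycle start while alive, 3 cycles:
        expected cost 175 = 100 * (1 + 0.5 + 0.25)."""
        params = two_state_params(p_die=0.5, cost=100.0, discount=0.0, horizon=0.75)
        res = m.evaluate_cohort(two_state_model(), params)
        assert res.total_cost == pytest.approx(175.0, abs=1e-12)
        oracle = brute_force_expectation(0.5, 100.0, 1.0, 0.0, 3)
        assert res.total_cost == pytest.approx(oracle[0], abs=1e-12)
        assert res.total_qaly == pytest.approx(oracle[1], abs=1e-12)

    @pytest.mark.parametrize("discount", [0.0, 0.03, 0.10])
    def test_matches_enumeration_with_discounting(self, discount):
        params = two_state_params(p_die=0.3, cost=250.0, utility=0.8,
                                  discount=discount, horizon=2.0)
        res = m.evaluate_cohort(two_state_model(), params)
        oc, oq = brute_force_expectation(0.3, 250.0, 0.8, discount, 8)
        assert res.total_cost == pytest.approx(oc, abs=1e-9)
        assert res.total_qaly == pytest.approx(oq, abs=1e-12)

    def test_occupancy_conserved_each_cycle(self, models, calibrated):
        for model in models:
            res = m.evaluate_cohort(model, calibrated)
            occ = res.trace[[c for c in res.trace.columns if c.startswith("occ_")]]
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
            assert (occ.to_numpy() >= -1e-15).all()

    def test_refuses_invalid_model(self, default_params, models):
        bad = default_params.with_overrides({"p_metastasis": 1.0, "p_rc_late_toxicity": 0.9})
        with pytest.raises(ModelValidationError):
            m.evaluate_cohort(models[0], bad)

    def test_qaly_bounded_by_horizon(self, models, calibrated):
        for model in models:
            for horizon in (5.0, 10.0):
                res = m.evaluate_cohort(model, calibrated.with_settings(horizon_years=horizon))
                assert 0 < res.total_qaly <= horizon

    def test_discounting_reduces_totals(self, models, calibrated):
        for model in models:
            disc = m.evaluate_cohort(model, calibrated)
            undisc = m.evaluate_cohort(model, calibrated.with_settings(discount_rate=0.0))
            assert disc.total_cost < undisc.total_cost
            assert disc.total_qaly < undisc.total_qaly

    def test_monotone_in_utility_cost_and_discount(self, models, calibrated):
        tmt = models[1]
        base = m.evaluate_cohort(tmt, calibrated, want_trace=False)
        up_u = calibrated.with_overrides({"u_nmibc_recurrence": 0.97})
        assert m.evaluate_cohort(tmt, up_u, want_trace=False).total_qaly >= base.total_qaly
        up_c = calibrated.with_overrides({"c_pembrolizumab": 40_000.0})
        res_c = m.evaluate_cohort(tmt, up_c, want_trace=False)
        assert res_c.total_cost >= base.total_cost
        assert res_c.total_qaly == pytest.approx(base.total_qaly, abs=1e-12)
        hi_d = calibrated.with_settings(discount_rate=0.06)
        res_d = m.evaluate_cohort(tmt, hi_d, want_trace=False)
        assert res_d.total_cost <= base.total_cost
        assert res_d.total_qaly <= base.total_qaly

    def test_ten_year_totals_exceed_five_year(self, models, calibrated):
        for model in models:
            r5 = m.evaluate_cohort(model, calibrated, want_trace=False)
            r10 = m.evaluate_cohort(
                model, calibrated.with_settings(horizon_years=10.0), want_trace=False
            )
            assert r10.total_cost > r5.total_cost
            assert r10.total_qaly > r5.total_qaly

    def test_half_cycle_correction_on_toy_oracle(self):
        """Averaging start/end occupancy: alive mass (1, .5, .25) with ends
        (.5, .25, .125) gives cost 100 * (0.75 + 0.375 + 0.1875) = 131.25."""
        params = two_state_params(p_die=0.5, cost=100.0, discount=0.0, horizon=0.75)
        hcc = m.evaluate_cohort(two_state_model(), params, half_cycle_correction=True)
        assert hcc.total_cost == pytest.approx(131.25, abs=1e-12)

    def test_half_cycle_correction_flag_changes_results(self, models, calibrated):
        res = m.evaluate_cohort(models[0], calibrated, want_trace=False)
        hcc = m.evaluate_cohort(models[0], calibrated, half_cycle_correction=True,
                                want_trace=False)
        # total living occupancy declines within a cycle, so QALYs shrink
        assert 0 < hcc.total_qaly < res.total_qaly
        assert hcc.total_cost != res.total_cost

    def test_trace_exports_tidy_csv(self, models, calibrated, tmp_path):
        res = m.evaluate_cohort(models[0], calibrated)
        path = tmp_path / "trace.csv"
        res.trace_to_csv(path)
        import pandas as pd

        tidy = pd.read_csv(path)
        assert {"cycle", "state", "occupancy"} <= set(tidy.columns)
        assert len(tidy) == calibrated.n_cycles * len(models[0].states)


class TestBatchSolver:
    def test_batch_matches_single_evaluation(self, models, calibrated):
        key_order = tuple(sorted(calibrated.keys()))
        base = np.array([calibrated.value(k) for k in key_order])
        values = np.vstack([base, base * 1.0])
        values[1, key_order.index("c_pembrolizumab")] *= 1.5
        for model in models:
            costs, qalys = m.evaluate_cohort_batch(model, calibrated, values, key_order)
            single = m.evaluate_cohort(model, calibrated, want_trace=False)
            assert costs[0] == pytest.approx(single.total_cost, abs=1e-9)
            assert qalys[0] == pytest.approx(single.total_qaly, abs=1e-12)
            over = m.evaluate_cohort(
                model,
                calibrated.with_overrides(
                    {"c_pembrolizumab": calibrated.value("c_pembrolizumab") * 1.5}
                ),
                want_trace=False,
            )
            assert costs[1] == pytest.approx(over.total_cost, abs=1e-9)

    def test_shape_validation(self, models, calibrated):
        with pytest.raises(ValueError, match="values must be"):
            m.evaluate_cohort_batch(models[0], calibrated, np.zeros((3, 2)))


class TestMicrosimulation:
    def test_deterministic_chain_has_zero_variance(self):
        params = two_state_params(p_die=1.0, cost=100.0, discount=0.0, horizon=0.75)
        res = m.simulate_individuals(two_state_model(), params, n=500, seed=1)
        assert np.ptp(res.costs) == 0.0
        assert np.ptp(res.qalys) == 0.0
        assert res.costs[0] == pytest.approx(100.0)  # one cycle alive

    def test_seeded_reproducibility(self, models, calibrated):
        a = m.simulate_individuals(models[1], calibrated, n=2_000, seed=9)
        b = m.simulate_individuals(models[1], calibrated, n=2_000, seed=9)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        c = m.simulate_individuals(models[1], calibrated, n=2_000, seed=10)
        assert not np.array_equal(a.costs, c.costs)

    @pytest.mark.parametrize("idx", [0, 1])
    def test_means_agree_with_cohort_solver(self, models, calibrated, idx):
        """Law of large numbers: microsimulation means within 3 SE of the
        cohort expected values for both outcomes."""
        model = models[idx]
        coh = m.evaluate_cohort(model, calibrated, want_trace=False)
        sim = m.simulate_individuals(model, calibrated, n=20_000, seed=123)
        assert abs(sim.mean_cost - coh.total_cost) < 3 * sim.se_cost
        assert abs(sim.mean_qaly - coh.total_qaly) < 3 * sim.se_qaly

    @pytest.mark.parametrize("model_seed", range(10))
    def test_random_models_cohort_microsim_agreement(self, model_seed):
        """Property: for random small models with tolls and windowed rules,
        the microsimulation mean at n = 50 000 matches the cohort value."""
        rng = np.random.default_rng(1000 + model_seed)
        model, params = random_chain_model(rng, n_states=int(rng.integers(2, 5)))
        assert m.validate_model(model, params) == []
        coh = m.evaluate_cohort(model, params, want_trace=False)
        sim = m.simulate_individuals(model, params, n=50_000, seed=model_seed)
        assert abs(sim.mean_cost - coh.total_cost) <= 3 * max(sim.se_cost, 1e-9)
        assert abs(sim.mean_qaly - coh.total_qaly) <= 3 * max(sim.se_qaly, 1e-12)
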