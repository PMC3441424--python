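"""Synthetic observations, rejection sampling, recovery, integration oracle."""

import numpy as np
import pytest

from lacflux.model import CellState
from lacflux.scenarios import Scenario
from lacflux.synthetic import (
    ParameterRanges,
    integration_oracle,
    recover_parameters,
    sample_parameters,
    simulate_observations,
)


def transport_scenarios(n, seed):
    rng = np.random.default_rng(seed)
    return [
        Scenario(f"cond{i}", multipliers={
            "v_max_MCT": float(rng.uniform(0.8, 1.8)),
            "L_e": float(rng.uniform(0.8, 1.8)),
            "v_max_glyco": float(rng.uniform(0.8, 1.5))})
        for i in range(n)
    ]


class TestSampling:
    def test_collapsed_ranges_return_reference_copies(self, params, env,
                                                      options, constraints):
        tiny = ParameterRanges.around(params, rel_width=1e-9,
                                      names=["k_shuttle"])
        sets = sample_parameters(tiny, constraints, 3, seed=1,
                                 reference=params, env=env, options=options)
        assert len(sets) == 3
        for s in sets:
            assert s.k_shuttle == pytest.approx(params.k_shuttle, rel=1e-8)

    def test_deterministic_under_fixed_seed(self, params, env, options,
                                            constraints):
        ranges = ParameterRanges.around(params, 0.25,
                                        ["k_shuttle", "v_max_PDH"])
        a = sample_parameters(ranges, constraints, 5, seed=42,
                              reference=params, env=env, options=options)
        b = sample_parameters(ranges, constraints, 5, seed=42,
                              reference=params, env=env, options=options)
        assert a == b

    def test_accepted_sets_pass_constraint_checker(self, params, env,
                                                   options, constraints):
        from lacflux.steady_state import check_constraints, solve_steady_state

        ranges = ParameterRanges.around(
            params, 0.3, ["k_shuttle", "v_max_PDH", "v_max_MCT"])
        sets = sample_parameters(ranges, constraints, 10, seed=3,
                                 reference=params, env=env, options=options)
        for s in sets:
            res = solve_steady_state(s, env, options)
            assert check_constraints(res, constraints).passed


class TestObservations:
    def test_zero_noise_reproduces_truth(self, params, env, options):
        scenarios = transport_scenarios(3, seed=0)
        obs = simulate_observations(params, env, options, scenarios,
                                    noise_cv=0.0, seed=5)
        from lacflux.scenarios import run_scenario

        for row, sc in zip(obs.itertuples(), scenarios):
            res = run_scenario(params, env, options, sc)
            assert row.J_PDH == pytest.approx(res.stimulated.fluxes.J_PDH)
            assert row.L_i == pytest.approx(res.stimulated.state.L_i)

    def test_same_seed_same_noise(self, params, env, options):
        scenarios = transport_scenarios(3, seed=0)
        a = simulate_observations(params, env, options, scenarios, 0.05, 7)
        b = simulate_observations(params, env, options, scenarios, 0.05, 7)
        assert a.equals(b)

    def test_noise_magnitude_matches_stated_cv(self, params, env, options):
        # many replicates of one condition: the sample CV of each observable
        # should sit near the nominal 2%
        scenario = transport_scenarios(1, seed=0)[0]
        obs = simulate_observations(params, env, options, [scenario] * 250,
                                    noise_cv=0.02, seed=11)
        for column in ("J_MCT", "J_PDH", "L_i", "P"):
            cv = obs[column].std() / abs(obs[column].mean())
            assert 0.015 < cv < 0.025


class TestRecovery:
    def test_zero_noise_recovers_truth(self, params, env, options):
        scenarios = transport_scenarios(6, seed=2)
        obs = simulate_observations(params, env, options, scenarios,
                                    noise_cv=0.0, seed=0)
        truth = {"k_shuttle": params.k_shuttle,
                 "v_max_PDH": params.v_max_PDH}
        fit = recover_parameters(
            obs, scenarios, ["k_shuttle", "v_max_PDH"], params, env, options,
            init={k: v * 1.5 for k, v in truth.items()}, truth=truth)
        assert fit.converged and fit.identifiable
        for err in fit.relative_errors.values():
            assert err < 1e-3

    def test_underdetermined_design_is_flagged(self, params, env, options):
        scenarios = transport_scenarios(1, seed=2)
        obs = simulate_observations(params, env, options, scenarios,
                                    noise_cv=0.0, seed=0)
        # one condition yields 4 observables; ask for 5 free parameters
        fit = recover_parameters(
            obs, scenarios,
            ["k_shuttle", "v_max_PDH", "v_max_MCT", "v_max_glyco", "K_PDH"],
            params, env, options)
        assert not fit.identifiable


class TestOracle:
    def test_steady_start_stays_put(self, params, env, options, basal):
        final = integration_oracle(params, env, options,
                                   initial=basal.state, t_end=1e4)
        assert np.allclose(final.as_array(), basal.state.as_array(),
                           atol=1e-8)

    def test_arbitrary_start_reaches_newton_solution(self, params, env,
                                                     options, basal):
        final = integration_oracle(params, env, options,
                                   initial=CellState(2.0, 0.3, 0.1),
                                   t_end=1e5)
        assert np.allclose(final.as_array(), basal.state.as_array(),
                           atol=1e-6)

    def test_pool_conservation_along_trajectory(self, params, env, options):
        # NAD+ is derived, never integrated: the pool identity is exact at
        # every sample of the trajectory
        _, _, y = integration_oracle(params, env, options,
                                     initial=CellState(0.2, 0.01, 0.002),
                                     t_end=100.0, return_trajectory=True)
        nadh = y[2]
        nad = params.N_tot - nadh
        assert np.max(np.abs(nadh + nad - params.N_tot)) < 1e-10
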