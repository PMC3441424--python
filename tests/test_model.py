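"""Flux laws and ODE right-hand side."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lacflux.model import (
    CellState,
    Environment,
    InvalidStateError,
    KineticParameters,
    MCTForm,
    ModelOptions,
    ConfigurationError,
    compute_fluxes,
    flux_glycolysis,
    flux_ldh,
    flux_mct,
    flux_pdh,
    flux_shuttle,
    rhs,
)
from lacflux.synthetic import integration_oracle


def zeroed(params, **overrides):
    fields = {name: getattr(params, name) for name in params._FIELDS}
    fields.update(overrides)
    return KineticParameters(**fields)


class TestMCT:
    def test_symmetric_carrier_vanishes_at_equal_gradients(self, params):
        env = Environment(L_e=0.8, H_i=5e-5, H_e=5e-5)
        state = CellState(L_i=0.8, P=0.05, NADH=0.01)
        assert flux_mct(state, params, env) == pytest.approx(0.0, abs=1e-15)

    def test_zero_capacity_gives_zero_flux(self, params, env):
        p = params.replace(v_max_MCT=0.0)
        state = CellState(L_i=0.2, P=0.02, NADH=0.01)
        assert flux_mct(state, p, env) == 0.0

    def test_increasing_in_external_decreasing_in_internal_lactate(
            self, params, env):
        state = CellState(L_i=0.5, P=0.02, NADH=0.01)
        base = flux_mct(state, params, env)
        richer = dataclasses.replace(env, L_e=env.L_e * 1.5)
        assert flux_mct(state, params, richer) > base
        fuller = CellState(L_i=0.8, P=0.02, NADH=0.01)
        assert flux_mct(fuller, params, env) < base

    def test_alternative_carrier_ignores_protons(self, params):
        opts = ModelOptions(mct_form=MCTForm.SIMPSON_ALTERNATIVE)
        state = CellState(L_i=0.5, P=0.02, NADH=0.01)
        env_acid = Environment(L_e=1.0, H_i=2e-4, H_e=4e-5)
        env_neutral = Environment(L_e=1.0, H_i=4e-5, H_e=4e-5)
        assert flux_mct(state, params, env_acid, opts) == pytest.approx(
            flux_mct(state, params, env_neutral, opts))

    def test_basal_supply_ratio_is_published_split(self, basal):
        # 43% lactate-derived vs 57% glycolysis-derived pyruvate
        assert basal.fluxes.J_MCT / basal.fluxes.J_glyco == pytest.approx(
            0.75, rel=0.02)


class TestLDH:
    def test_mass_action_equilibrium_is_a_zero(self, params):
        # P*NADH/(L_i*NAD+) = k_r/k_f  =>  no net flux
        nadh = 0.01
        nad = params.N_tot - nadh
        L_i = 0.5
        P = params.k_r_LDH * L_i * nad / (params.k_f_LDH * nadh)
        state = CellState(L_i=L_i, P=P, NADH=nadh)
        assert flux_ldh(state, params) == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("pool,factor", [(0.0, 0.0), (6.4, 2.0)])
    def test_linear_in_total_pool(self, params, pool, factor):
        state = CellState(L_i=0.5, P=0.05, NADH=0.02)
        base = flux_ldh(state, params)
        scaled = flux_ldh(state, params.replace(LDH_total=pool))
        assert scaled == pytest.approx(factor * base * params.LDH_total / 3.2
                                       if pool else 0.0)

    def test_overfull_pool_rejected(self, params):
        state = CellState(L_i=0.5, P=0.05, NADH=params.N_tot * 1.01)
        with pytest.raises(InvalidStateError):
            flux_ldh(state, params)


class TestGlycolysis:
    def test_fully_reduced_pool_stalls_glycolysis(self, params, env):
        state = CellState(L_i=0.5, P=0.05, NADH=params.N_tot)
        assert flux_glycolysis(state, params, env) == pytest.approx(0.0)

    def test_frozen_mode_clamps_flux(self, params, env):
        opts = ModelOptions(frozen_glycolysis=True, J_glyco_fixed=0.001)
        for nadh in (0.0, 0.02, params.N_tot):
            state = CellState(L_i=0.5, P=0.05, NADH=nadh)
            assert flux_glycolysis(state, params, env, opts) == 0.001

    def test_frozen_mode_requires_fixed_value(self):
        with pytest.raises(ConfigurationError):
            ModelOptions(frozen_glycolysis=True)

    def test_saturating_substrates_reach_capacity(self, params):
        env = Environment(L_e=1.0, Glc=1e6)
        big_pool = params.replace(N_tot=1e6, K_NAD_g=params.K_NAD_g)
        state = CellState(L_i=0.5, P=0.05, NADH=0.0)
        assert flux_glycolysis(state, big_pool, env) == pytest.approx(
            params.v_max_glyco, rel=1e-4)


class TestPDHAndShuttle:
    @pytest.mark.parametrize("p_over_k,expected_frac", [
        (0.0, 0.0), (1.0, 0.5), (1e6, 1.0)])
    def test_pdh_michaelis_menten(self, params, p_over_k, expected_frac):
        state = CellState(L_i=0.5, P=p_over_k * params.K_PDH, NADH=0.01)
        assert flux_pdh(state, params) == pytest.approx(
            expected_frac * params.v_max_PDH, rel=1e-4, abs=1e-15)

    def test_shuttle_linear_in_nadh(self, params):
        one = flux_shuttle(CellState(0.5, 0.05, 0.01), params)
        two = flux_shuttle(CellState(0.5, 0.05, 0.02), params)
        assert two == pytest.approx(2 * one)
        off = params.replace(k_shuttle=0.0)
        assert flux_shuttle(CellState(0.5, 0.05, 0.02), off) == 0.0


class TestRHS:
    def test_zero_capacities_give_zero_derivative(self, params, env):
        dead = zeroed(params, v_max_MCT=0.0, v_max_glyco=0.0, v_max_PDH=0.0,
                      k_shuttle=0.0, LDH_total=0.0)
        state = CellState(L_i=0.5, P=0.05, NADH=0.01)
        assert np.allclose(rhs(state, dead, env), 0.0)

    def test_steady_state_annihilates_rhs(self, params, env, basal):
        assert np.max(np.abs(rhs(basal.state, params, env))) < 1e-10

    def test_rhs_matches_trajectory_finite_difference(self, params, env,
                                                      options):
        # independent check: numerically differentiate the integrated
        # trajectory and compare with the analytic right-hand side
        start = CellState(L_i=0.2, P=0.01, NADH=0.002)
        _, t, y = integration_oracle(params, env, options, initial=start,
                                     t_end=5.0, return_trajectory=True)
        k = len(t) // 2
        dt = 1e-4
        _, _, y_fwd = integration_oracle(
            params, env, options,
            initial=CellState(*np.clip(y[:, k], 0, None)), t_end=dt,
            return_trajectory=True)
        fd = (y_fwd[:, -1] - y[:, k]) / dt
        analytic = rhs(CellState(*np.clip(y[:, k], 0, None)), params, env,
                       options)
        assert np.allclose(fd, analytic, rtol=1e-3, atol=1e-9)

    def test_flux_vector_shares_code_path_with_rhs(self, params, env):
        state = CellState(L_i=0.4, P=0.02, NADH=0.03)
        f = compute_fluxes(state, params, env)
        d = rhs(state, params, env)
        assert d[0] == pytest.approx(f.J_MCT + f.J_LDH)
        assert d[1] == pytest.approx(f.J_glyco - f.J_LDH - f.J_PDH)
        assert d[2] == pytest.approx(f.J_glyco - f.J_LDH - f.J_shuttle)

    def test_zero_capacity_flux_vector(self, params, env):
        dead = zeroed(params, v_max_MCT=0.0, v_max_glyco=0.0, v_max_PDH=0.0,
                      k_shuttle=0.0, LDH_total=0.0)
        f = compute_fluxes(CellState(0.5, 0.05, 0.01), dead, env)
        assert all(v == 0.0 for v in f.as_dict().values())


class TestValidation:
    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidStateError):
            CellState(L_i=-0.1, P=0.05, NADH=0.01)

    def test_nonpositive_environment_rejected(self):
        with pytest.raises(InvalidStateError):
            Environment(L_e=0.0)

    def test_out_of_window_ph_rejected_unless_overridden(self):
        with pytest.raises(InvalidStateError):
            Environment(H_i=1e-2)
        Environment(H_i=1e-2, validate_ph=False)  # explicit override


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    L_i=st.floats(0.01, 5.0),
    P=st.floats(0.001, 0.5),
    nadh_frac=st.floats(0.001, 0.999),
)
def test_fluxes_finite_and_signed_on_physical_states(L_i, P, nadh_frac):
    """Glycolysis, PDH and shuttle are non-negative on any physical state."""
    from lacflux.config import oxidative_reference

    cfg = oxidative_reference()
    state = CellState(L_i=L_i, P=P, NADH=nadh_frac * cfg.parameters.N_tot)
    f = compute_fluxes(state, cfg.parameters, cfg.environment)
    values = np.array(list(f.as_dict().values()))
    assert np.all(np.isfinite(values))
    assert f.J_glyco >= 0 and f.J_PDH >= 0 and f.J_shuttle >= 0
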