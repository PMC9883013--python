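"""Construction, integration and steady-state behaviour of the cycle model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from sertcycle import (
    CYCLE_STATES,
    InhibitorScheme,
    LigandConditions,
    RateConstantSet,
    TransportCycleModel,
    Transition,
    assemble_rate_matrix,
    build_sert_cycle,
    extend_with_inhibitor,
    integrate,
    steady_state,
    steady_state_flux,
    uptake_rate,
)
from sertcycle.pharm_fits import fit_hyperbola

from conftest import random_conditions, random_rate_set


class TestConstruction:
    def test_default_cycle_has_8_states_16_transitions(self, default_model):
        assert default_model.states == CYCLE_STATES
        assert len(default_model.transitions) == 16

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError, match="strictly positive"):
            RateConstantSet(kon_K=0.0)
        with pytest.raises(ValueError, match="strictly positive"):
            RateConstantSet(koff_S=-5.0)

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError, match="non-negative"):
            LigandConditions(Na_out=-1.0)

    def test_missing_ligand_concentration_is_an_error(self, default_model):
        bad = Transition("To", "ToNa", 1e6, ligand="Cl", side="out")
        model = TransportCycleModel(
            default_model.states,
            default_model.transitions[1:] + (bad,),
            default_model.rates,
            default_model.conditions,
        )
        with pytest.raises(ValueError, match="Cl_out"):
            assemble_rate_matrix(model)

    def test_published_defaults(self):
        r = RateConstantSet()
        assert (r.kon_K, r.koff_K) == (1e6, 5000.0)
        assert (r.kon_Na, r.koff_Na) == (1e6, 1000.0)
        assert (r.kon_S, r.koff_S) == (1e7, 500.0)
        assert (r.k_ToNaS_TiNaS, r.k_TiNaS_ToNaS) == (60.0, 75.0)
        assert (r.k_TiK_ToK, r.k_ToK_TiK) == (5.0, 4.0)


class TestInhibitorExtension:
    def test_single_state_scheme_adds_one_state(self, default_model):
        scheme = InhibitorScheme("i", {"TiK": 12e-6})
        ext = extend_with_inhibitor(default_model, scheme)
        assert ext.n_states == 9
        assert "TiK*I" in ext.states

    def test_two_state_scheme_adds_two_states(self, default_model):
        scheme = InhibitorScheme("noribogaine-like", {"ToNa": 120e-6, "TiK": 12e-6})
        ext = extend_with_inhibitor(default_model, scheme)
        assert ext.n_states == 10

    def test_koff_derived_from_kd(self):
        scheme = InhibitorScheme("i", {"TiK": 12e-6}, kon_I=1e6)
        assert scheme.koff_I("TiK") == pytest.approx(12.0, rel=1e-15)

    def test_zero_inhibitor_is_a_steady_state_noop(self, model_at_10uM):
        scheme = InhibitorScheme("i", {"TiK": 12e-6})
        ext = extend_with_inhibitor(model_at_10uM, scheme)
        base_flux = steady_state_flux(model_at_10uM)
        ext_flux = steady_state_flux(ext)
        assert ext_flux == pytest.approx(base_flux, rel=1e-10)
        occ = steady_state(ext)
        assert occ[ext.state_index("TiK*I")] == pytest.approx(0.0, abs=1e-12)

    def test_rejects_empty_and_unknown_targets(self, default_model):
        with pytest.raises(ValueError, match="at least one target"):
            InhibitorScheme("i", {})
        with pytest.raises(ValueError, match="unknown target state"):
            InhibitorScheme("i", {"TiNa": 1e-6})

    def test_rejects_double_extension(self, default_model):
        scheme = InhibitorScheme("i", {"TiK": 12e-6})
        ext = extend_with_inhibitor(default_model, scheme)
        with pytest.raises(ValueError, match="already carries"):
            extend_with_inhibitor(ext, scheme)


class TestRateMatrix:
    def test_columns_sum_to_zero(self, model_at_10uM):
        Q = assemble_rate_matrix(model_at_10uM)
        assert Q.shape == (8, 8)
        assert np.abs(Q.sum(axis=0)).max() < 1e-12

    def test_matrix_exponential_agrees_with_ode_solver(self, model_at_10uM):
        """Propagation over 1 ms: expm oracle vs stiff ODE integration."""
        Q = assemble_rate_matrix(model_at_10uM)
        p0 = np.zeros(8)
        p0[0] = 1.0
        expected = expm(Q * 1e-3) @ p0
        traj = integrate(model_at_10uM, [0.0, 1e-3], p0)
        assert np.abs(traj.final() - expected).max() < 1e-8


class TestIntegration:
    def test_conservation_along_trajectory(self, model_at_10uM):
        traj = integrate(model_at_10uM, np.linspace(0, 2.0, 50))
        assert np.abs(traj.occupancy.sum(axis=1) - 1).max() < 1e-8

    def test_steady_state_is_a_fixed_point(self, model_at_10uM):
        ss = steady_state(model_at_10uM)
        traj = integrate(model_at_10uM, [0.0, 10.0], ss)
        assert np.abs(traj.final() - ss).max() < 1e-8

    def test_no_substrate_keeps_inward_substrate_states_empty(self, default_model):
        model = default_model.with_conditions(S_out=0.0)
        traj = integrate(model, np.linspace(0, 5.0, 20))
        assert np.abs(traj.state_series("TiNaS")).max() < 1e-12
        assert np.abs(traj.state_series("TiS")).max() < 1e-12

    def test_trajectory_plateau_matches_null_space(self, model_at_10uM):
        traj = integrate(model_at_10uM, np.linspace(0, 100.0, 11))
        assert np.abs(traj.final() - steady_state(model_at_10uM)).max() < 1e-8

    def test_invalid_inputs_rejected(self, model_at_10uM):
        with pytest.raises(ValueError, match="strictly increasing"):
            integrate(model_at_10uM, [1.0, 0.5])
        bad = np.full(8, 0.5)
        with pytest.raises(ValueError, match="probability vector"):
            integrate(model_at_10uM, [0.0, 1.0], bad)


class TestSteadyState:
    def test_normalized(self, model_at_10uM):
        ss = steady_state(model_at_10uM)
        assert ss.sum() == pytest.approx(1.0, abs=1e-12)
        assert ss.min() >= 0

    def test_disconnected_graph_reports_components(self, default_model):
        transitions = (
            Transition("To", "ToNa", 100.0),
            Transition("ToNa", "To", 50.0),
            Transition("TiK", "ToK", 5.0),
            Transition("ToK", "TiK", 4.0),
        )
        model = TransportCycleModel(
            ("To", "ToNa", "TiK", "ToK"),
            transitions,
            default_model.rates,
            default_model.conditions,
        )
        with pytest.raises(ValueError, match="components"):
            steady_state(model)

    def test_null_space_vs_expm_on_random_models(self):
        """Stationary solve equals long-time propagation on random cycles."""
        rng = np.random.default_rng(20240917)
        for _ in range(25):
            model = build_sert_cycle(random_rate_set(rng), random_conditions(rng))
            Q = assemble_rate_matrix(model)
            # relaxation is governed by the spectral gap
            gap = np.sort(np.abs(np.linalg.eigvals(Q).real))[1]
            p0 = np.zeros(8)
            p0[rng.integers(8)] = 1.0
            propagated = expm(Q * (1000.0 / gap)) @ p0
            assert np.abs(propagated - steady_state(model)).max() < 1e-6


class TestUptakeRate:
    def test_flux_formula_arithmetic(self, default_model):
        occ = np.zeros(8)
        occ[default_model.state_index("TiS")] = 0.02
        assert uptake_rate(occ, default_model) == pytest.approx(10.0)

    def test_all_outward_gives_zero_flux(self, default_model):
        occ = np.zeros(8)
        occ[default_model.state_index("To")] = 1.0
        assert uptake_rate(occ, default_model) == 0.0

    def test_no_substrate_no_flux(self, default_model):
        assert steady_state_flux(
            default_model.with_conditions(S_out=0.0)
        ) == pytest.approx(0.0, abs=1e-9)

    def test_flux_ratio_tracks_tik_occupancy_ratio(self, default_model):
        """Without inward Na+ rebinding and outward K+ rebinding, the flux
        and TiK-occupancy substrate dependences coincide (the general-case
        link runs through the IC50 shift, tested with the experiments)."""
        model = default_model.with_conditions(K_out=0.0, Na_in=0.0)
        lo = model.with_conditions(S_out=0.1e-6)
        hi = model.with_conditions(S_out=10e-6)
        flux_ratio = steady_state_flux(hi) / steady_state_flux(lo)
        i_tik = model.state_index("TiK")
        occ_ratio = steady_state(hi)[i_tik] / steady_state(lo)[i_tik]
        assert flux_ratio == pytest.approx(occ_ratio, rel=0.05)


class TestRandomizedInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=100_000))
    def test_steady_state_is_a_probability_vector(self, seed):
        rng = np.random.default_rng(seed)
        model = build_sert_cycle(random_rate_set(rng), random_conditions(rng))
        p = steady_state(model)
        assert p.sum() == pytest.approx(1.0, abs=1e-10)
        assert p.min() >= 0.0 and p.max() <= 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=100_000),
        st.sampled_from(CYCLE_STATES),
        st.floats(min_value=-8, max_value=-3),
    )
    def test_zero_inhibitor_neutrality(self, seed, state, log_kd):
        """Attaching any inhibitor scheme at I_out = 0 leaves the
        steady-state flux unchanged."""
        rng = np.random.default_rng(seed)
        model = build_sert_cycle(random_rate_set(rng), random_conditions(rng))
        ext = extend_with_inhibitor(
            model, InhibitorScheme("i", {state: 10.0**log_kd})
        )
        base = steady_state_flux(model)
        # tolerance set by the conditioning of two separate linear solves
        assert abs(steady_state_flux(ext) - base) <= 1e-9 * max(abs(base), 1e-30)


class TestMichaelianBehaviour:
    def test_flux_vs_substrate_is_hyperbolic(self, default_model):
        s_grid = np.logspace(-8, -4, 40)
        flux = np.array(
            [steady_state_flux(default_model.with_conditions(S_out=s)) for s in s_grid]
        )
        fit = fit_hyperbola(s_grid * 1e6, flux, ci_method="wald")
        predicted = fit["ymax"] * s_grid * 1e6 / (s_grid * 1e6 + fit["x50"])
        ss_res = np.sum((flux - predicted) ** 2)
        ss_tot = np.sum((flux - flux.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999

    def test_apparent_km_matches_dense_grid_oracle(self, default_model):
        """Protocol-style coarse grid vs brute-force dense scan."""
        coarse = np.logspace(-1, 2, 12)
        dense = np.logspace(-2, 2.5, 200)
        def km_of(grid_uM):
            flux = np.array(
                [steady_state_flux(default_model.with_conditions(S_out=s * 1e-6))
                 for s in grid_uM]
            )
            return fit_hyperbola(grid_uM, flux, ci_method="wald")["x50"]
        assert km_of(coarse) == pytest.approx(km_of(dense), rel=0.05)
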