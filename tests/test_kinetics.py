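"""Unit tests for the single-cell metabolism kinetics."""

import numpy as np
import pytest
from scipy.linalg import expm

from zonasim import (
    SPECIES,
    CellState,
    InitialCondition,
    RateConstants,
    baseline_steady_state,
    branch_fraction,
    conservation_residual,
    fit_rate_constants,
    rhs,
    simulate,
)
from zonasim.kinetics import RATE_CONSTANT_NAMES, Trajectory


def reference_rhs(state: CellState, p: RateConstants) -> dict:
    """Literal term-by-term re-evaluation of the mass-action expressions.

    Kept deliberately independent of the implementation: every flux is
    written out once per equation rather than shared.
    """
    return {
        "P": -p.k_sul * state.S * state.P - p.k_gluc * state.P
             - p.k_450 * state.P + p.k_rev * state.N,
        "S": p.beta_S - p.delta_S * state.S - p.k_sul * state.S * state.P,
        "N": p.k_450 * state.P - p.k_rev * state.N
             - p.k_GSH * state.G * state.N - p.k_PSH * state.N,
        "G": p.beta_G - p.delta_G * state.G - p.k_GSH * state.G * state.N,
        "T": p.k_PSH * state.N - p.delta_T * state.T,
        "E_sul": p.k_sul * state.S * state.P,
        "E_gluc": p.k_gluc * state.P,
        "C_GSH": p.k_GSH * state.G * state.N,
    }


class TestRateConstants:
    def test_exactly_ten_rate_constants_by_default(self):
        assert len(RateConstants().names) == 10
        assert set(RateConstants().names) == set(RATE_CONSTANT_NAMES)

    def test_optional_adduct_decay_is_an_eleventh_parameter(self):
        assert len(RateConstants(delta_T=0.05).names) == 11

    @pytest.mark.parametrize("bad", [{"k_sul": -1.0}, {"delta_S": 0.0},
                                     {"delta_G": 0.0}, {"k_GSH": float("nan")}])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            RateConstants(**bad)


class TestRhs:
    def test_drug_free_baseline_is_a_fixed_point(self, default_params):
        p = default_params
        s0, g0 = baseline_steady_state(p)
        deriv = rhs(CellState(P=0.0, S=s0, N=0.0, G=g0, T=0.0), p)
        assert deriv.as_array() == pytest.approx(np.zeros(len(SPECIES)), abs=1e-15)

    def test_no_reactions_means_only_turnover(self):
        p = RateConstants(k_sul=0, k_gluc=0, k_450=0, k_rev=0, k_GSH=0, k_PSH=0,
                          beta_S=0.05, delta_S=0.1, beta_G=0.5, delta_G=0.1)
        s0, g0 = baseline_steady_state(p)
        deriv = rhs(CellState(P=5.0, S=s0, N=0.0, G=g0, T=0.0), p)
        assert deriv.as_array() == pytest.approx(np.zeros(len(SPECIES)), abs=1e-15)

    @pytest.mark.parametrize("state", [
        CellState(P=3.0, S=0.4, N=0.02, G=2.5, T=0.1, E_sul=0.3, E_gluc=0.8, C_GSH=0.5),
        CellState(P=0.1, S=0.5, N=0.5, G=0.01, T=2.0),
        CellState(P=40.0, S=0.0, N=0.0, G=5.0, T=0.0),
    ])
    def test_matches_term_by_term_oracle(self, state, default_params):
        deriv = rhs(state, default_params)
        expected = reference_rhs(state, default_params)
        for name in SPECIES:
            assert getattr(deriv, name) == pytest.approx(expected[name], rel=1e-14)

    def test_negative_state_rejected(self, default_params):
        with pytest.raises(ValueError, match="negative"):
            rhs(CellState(P=-1.0, S=0.5, N=0.0, G=5.0, T=0.0), default_params)


class TestSimulate:
    def test_no_dose_stays_at_baseline(self, default_params):
        traj = simulate(InitialCondition(P0=0.0), default_params, 10.0)
        s0, g0 = baseline_steady_state(default_params)
        assert np.allclose(traj.species("S"), s0, rtol=1e-7)
        assert np.allclose(traj.species("G"), g0, rtol=1e-7)
        assert np.all(traj.species("T") == 0.0)

    def test_first_state_equals_initial_condition(self, standard_trajectory):
        first = standard_trajectory.initial
        assert first.P == pytest.approx(20.0)
        assert first.N == 0.0 and first.T == 0.0
        s0, g0 = baseline_steady_state(standard_trajectory.params)
        assert first.S == pytest.approx(s0) and first.G == pytest.approx(g0)

    def test_linear_submodel_matches_matrix_exponential(self):
        """With S and G frozen at zero, (P, N, T) evolve linearly; the
        trajectory must match the closed-form matrix exponential."""
        p = RateConstants(k_sul=0.0, k_gluc=0.4, k_450=0.3, k_rev=0.05,
                          k_GSH=3.0, k_PSH=0.2, beta_S=0.0, delta_S=0.1,
                          beta_G=0.0, delta_G=0.1)
        P0 = 7.0
        init = InitialCondition(P0=P0, S0=0.0, G0=0.0)
        grid = np.linspace(0.0, 12.0, 25)
        traj = simulate(init, p, 12.0, output_grid=grid, rtol=1e-10, atol=1e-12)
        A = np.array([
            [-(p.k_gluc + p.k_450), p.k_rev, 0.0],
            [p.k_450, -(p.k_rev + p.k_PSH), 0.0],
            [0.0, p.k_PSH, 0.0],
        ])
        for i, t in enumerate(grid):
            exact = expm(A * t) @ np.array([P0, 0.0, 0.0])
            got = np.array([traj.species(s)[i] for s in ("P", "N", "T")])
            assert np.abs(got - exact).max() / P0 < 1e-8

    def test_absorbing_adduct_pool_collects_entire_dose(self):
        """With both detox branches and GSH conjugation off, every APAP
        molecule must end up in the adduct pool."""
        p = RateConstants(k_sul=0.0, k_gluc=0.0, k_450=1.0, k_rev=0.02,
                          k_GSH=0.0, k_PSH=1.0, beta_S=0.0, delta_S=0.1,
                          beta_G=0.0, delta_G=0.1)
        P0 = 5.0
        traj = simulate(InitialCondition(P0=P0, G0=0.0), p, 60.0)
        assert traj.species("T")[-1] == pytest.approx(P0, rel=1e-6)
        assert traj.species("P")[-1] == pytest.approx(0.0, abs=1e-6)
        assert traj.species("N")[-1] == pytest.approx(0.0, abs=1e-6)

    def test_cumulative_pools_non_decreasing(self, standard_trajectory):
        for name in ("T", "E_sul", "E_gluc", "C_GSH"):
            diffs = np.diff(standard_trajectory.species(name))
            assert np.all(diffs >= -1e-9), name

    def test_states_non_negative(self, standard_trajectory):
        # margin: 10x the absolute solver tolerance covers dense-output error
        assert standard_trajectory.states.min() >= -1e-9

    def test_perturbed_cofactors_relax_to_baseline(self, default_params):
        s0, g0 = baseline_steady_state(default_params)
        init = InitialCondition(P0=0.0, S0=3.0 * s0, G0=0.2 * g0)
        traj = simulate(init, default_params, 120.0)  # t >> 1/delta
        assert traj.species("S")[-1] == pytest.approx(s0, rel=1e-4)
        assert traj.species("G")[-1] == pytest.approx(g0, rel=1e-4)

    def test_deterministic(self, default_params):
        a = simulate(InitialCondition(P0=15.0), default_params, 24.0)
        b = simulate(InitialCondition(P0=15.0), default_params, 24.0)
        assert np.array_equal(a.states, b.states)

    def test_bad_inputs_rejected(self, default_params):
        with pytest.raises(ValueError):
            simulate(InitialCondition(P0=1.0), default_params, -1.0)
        with pytest.raises(ValueError):
            simulate(InitialCondition(P0=1.0), default_params, 10.0,
                     output_grid=[0.0, 5.0, 20.0])


class TestConservation:
    def test_residual_within_tolerance(self, standard_trajectory):
        assert conservation_residual(standard_trajectory).max() <= 1e-8 * 20.0

    def test_broken_bookkeeping_is_detected(self, standard_trajectory):
        states = standard_trajectory.states.copy()
        states[:, SPECIES.index("T")] = 0.0  # zero out the adduct column
        broken = Trajectory(times=standard_trajectory.times, states=states,
                            params=standard_trajectory.params)
        assert conservation_residual(broken).max() > 1e-8 * 20.0

    def test_stiff_regime_conserves_and_matches_tighter_solve(self):
        """k_GSH*G0 four decades above every other rate: the residual must
        stay within tolerance and the solution must agree with a 100x
        tighter re-run."""
        p = RateConstants(k_sul=0.1, k_gluc=0.2, k_450=0.5, k_rev=0.01,
                          k_GSH=2e3, k_PSH=0.05, beta_S=0.05, delta_S=0.1,
                          beta_G=0.5, delta_G=0.1)  # k_GSH*G0 = 1e4
        init = InitialCondition(P0=10.0)
        grid = np.linspace(0.0, 24.0, 49)
        traj = simulate(init, p, 24.0, output_grid=grid)
        assert conservation_residual(traj).max() <= 1e-8 * 10.0
        tight = simulate(init, p, 24.0, output_grid=grid, rtol=1e-10, atol=1e-12)
        assert np.abs(traj.states - tight.states).max() < 1e-6 * 10.0


class TestBaselineAndBranch:
    def test_baseline_arithmetic(self):
        p = RateConstants(beta_G=2.0, delta_G=0.5)
        assert baseline_steady_state(p) == (pytest.approx(p.beta_S / p.delta_S), 4.0)
        assert baseline_steady_state(RateConstants(beta_S=0.0))[0] == 0.0

    def test_branch_fraction_limits(self, default_params):
        p = default_params
        huge_g = CellState(P=1.0, S=0.5, N=0.1, G=1e12, T=0.0)
        assert branch_fraction(huge_g, p) < 1e-10
        no_g = CellState(P=1.0, S=0.5, N=0.1, G=0.0, T=0.0)
        assert branch_fraction(no_g, p) == 1.0
        balanced = CellState(P=1.0, S=0.5, N=0.1, G=p.k_PSH / p.k_GSH, T=0.0)
        assert branch_fraction(balanced, p) == pytest.approx(0.5)

    def test_branch_fraction_undefined_without_outflux(self):
        p = RateConstants(k_PSH=0.0)
        with pytest.raises(ValueError):
            branch_fraction(CellState(P=1.0, S=0.5, N=0.1, G=0.0, T=0.0), p)


class TestFitRateConstants:
    def test_noiseless_fit_from_truth_recovers_exactly(self, default_params):
        grid = np.linspace(0.0, 24.0, 31)
        traj = simulate(InitialCondition(P0=20.0), default_params, 24.0, output_grid=grid)
        res = fit_rate_constants(grid, traj.states, InitialCondition(P0=20.0),
                                 default_params, ("k_450", "k_GSH", "k_PSH"))
        assert res.success and res.identifiable
        assert max(res.relative_errors(default_params).values()) < 1e-6

    def test_noisy_fit_recovers_within_tolerance(self, default_params, rng):
        grid = np.linspace(0.0, 24.0, 31)
        traj = simulate(InitialCondition(P0=20.0), default_params, 24.0, output_grid=grid)
        noisy = np.clip(traj.states * (1 + 0.01 * rng.standard_normal(traj.states.shape)),
                        0.0, None)
        start = default_params.replace(k_450=default_params.k_450 * 2.0,
                                       k_GSH=default_params.k_GSH * 0.5,
                                       k_PSH=default_params.k_PSH * 1.7)
        res = fit_rate_constants(grid, noisy, InitialCondition(P0=20.0), start,
                                 ("k_450", "k_GSH", "k_PSH"))
        assert res.success
        assert max(res.relative_errors(default_params).values()) < 0.10

    def test_unexcited_trajectory_flagged_non_identifiable(self, default_params):
        grid = np.linspace(0.0, 24.0, 11)
        traj = simulate(InitialCondition(P0=0.0), default_params, 24.0, output_grid=grid)
        res = fit_rate_constants(grid, traj.states, InitialCondition(P0=0.0),
                                 default_params, ("k_450", "k_GSH", "k_PSH"))
        assert not res.identifiable and not res.success
        assert "identifiable" in res.message

    def test_empty_free_set_rejected(self, default_params, standard_trajectory):
        with pytest.raises(ValueError):
            fit_rate_constants(standard_trajectory.times, standard_trajectory.states,
                               InitialCondition(P0=20.0), default_params, ())
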