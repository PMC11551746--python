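"""Kinetic core: derivatives, simulation, equilibrium algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strandex.reactions import (
    InvalidParameterError,
    RateConstants,
    ReactionScheme,
    ReactionState,
    UndefinedEquilibriumError,
    algebraic_equilibrium,
    equilibrium_constants,
    mass_action_derivatives,
    relative_equilibrium_change,
    simulate,
)
from .conftest import random_rate_constants

ZERO = RateConstants(0, 0, 0, 0, 0, 0)


class TestDerivatives:
    def test_all_zero_rates_freeze_every_species(self, standard_state):
        d = mass_action_derivatives("three_step", ZERO, standard_state)
        assert all(v == 0 for v in d.values())

    def test_capture_only_flux_is_k1_A_B(self, standard_state):
        rates = RateConstants(k1=1e-3, k_m1=0, k2=0, k_m2=0)
        d = mass_action_derivatives("three_step", rates, standard_state)
        assert d["A"] == pytest.approx(-1.296)
        assert d["B"] == pytest.approx(-1.296)
        assert d["C1"] == pytest.approx(1.296)

    @pytest.mark.parametrize("scheme", ["three_step", "two_step"])
    def test_filament_strand_conservation_in_fluxes(self, scheme):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rates = random_rate_constants(rng)
            state = ReactionState(*rng.uniform(0, 50, size=6))
            d = mass_action_derivatives(scheme, rates, state)
            assert d["A"] + d["C1"] + d["C2"] + d["D"] == pytest.approx(0, abs=1e-12)
            assert d["B"] + d["C1"] + d["C2"] + d["D"] == pytest.approx(0, abs=1e-12)
            assert d["D"] == pytest.approx(d["E"], abs=1e-15)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            RateConstants(k1=-1e-3, k_m1=0, k2=0, k_m2=0)


class TestSimulate:
    def test_zero_rates_give_constant_trajectory(self, standard_state):
        traj = simulate("three_step", ZERO, standard_state, np.linspace(0, 100, 11))
        assert np.allclose(traj.states, standard_state.as_array()[None, :])

    def test_irreversible_equal_concentration_closed_form(self):
        # A + B -> C1 with A0 = B0 has A(t) = A0 / (1 + k1*A0*t)
        k1, A0 = 1e-3, 36.0
        rates = RateConstants(k1=k1, k_m1=0, k2=0, k_m2=0)
        times = np.linspace(0, 2000, 201)
        traj = simulate("three_step", rates, ReactionState(A=A0, B=A0), times)
        expected = A0 / (1 + k1 * A0 * times)
        assert np.max(np.abs(traj.A - expected) / expected) < 1e-6

    @pytest.mark.parametrize("scheme", ["three_step", "two_step"])
    def test_long_time_limit_matches_algebraic_equilibrium(self, scheme):
        rng = np.random.default_rng(7)
        for _ in range(5):
            rates = random_rate_constants(rng)
            eq = algebraic_equilibrium(scheme, rates, 36.0, 36.0)
            times = np.array([0.0, 1e6, 2e6])
            traj = simulate(scheme, rates, ReactionState(A=36, B=36), times)
            final = traj.states[-1]
            expect = eq.as_array()
            scale = np.maximum(np.abs(expect), 1e-9)
            assert np.max(np.abs(final - expect) / scale) < 1e-6

    def test_conservation_and_product_symmetry(self, three_step_rates, coarse_grid):
        traj = simulate(
            "three_step", three_step_rates, ReactionState(A=36, B=36), coarse_grid
        )
        total_a = traj.A + traj.C1 + traj.C2 + traj.D
        total_b = traj.B + traj.C1 + traj.C2 + traj.D
        assert np.max(np.abs(total_a - 36)) < 1e-6
        assert np.max(np.abs(total_b - 36)) < 1e-6
        assert np.max(np.abs(traj.D - traj.E)) < 1e-9

    def test_irreversible_reaction_is_monotone(self, coarse_grid):
        rates = RateConstants(k1=1e-4, k_m1=0, k2=5e-3, k_m2=0, k3=2e-3, k_m3=0)
        traj = simulate("three_step", rates, ReactionState(A=36, B=36), coarse_grid)
        assert np.all(np.diff(traj.A) <= 1e-12)
        assert np.all(np.diff(traj.D) >= -1e-12)

    def test_times_must_start_at_zero_and_increase(self, three_step_rates):
        with pytest.raises(InvalidParameterError):
            simulate("three_step", three_step_rates, ReactionState(A=36, B=36), [1, 2])
        with pytest.raises(InvalidParameterError):
            simulate(
                "three_step", three_step_rates, ReactionState(A=36, B=36), [0, 5, 5]
            )


class TestEquilibriumConstants:
    def test_direct_ratios(self):
        rates = RateConstants(1e-3, 1e-2, 5e-3, 1e-3, 2e-3, 1e-4)
        eq = equilibrium_constants(rates)
        assert eq.K1 == pytest.approx(0.1)
        assert eq.K2 == pytest.approx(5.0)
        assert eq.K3 == pytest.approx(20.0)
        assert eq.K_total == pytest.approx(10.0)

    def test_balanced_rates_give_unity(self):
        eq = equilibrium_constants(RateConstants(1e-3, 1e-3, 1e-2, 1e-2, 1e-4, 1e-4))
        assert (eq.K1, eq.K2, eq.K3, eq.K_total) == (1.0, 1.0, 1.0, 1.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        logs=st.lists(
            st.floats(min_value=-5, max_value=0), min_size=6, max_size=6
        )
    )
    def test_product_identity(self, logs):
        rates = RateConstants(*(10.0**np.array(logs)))
        eq = equilibrium_constants(rates)
        assert eq.K_total == pytest.approx(eq.K1 * eq.K2 * eq.K3, rel=1e-12)

    def test_zero_reverse_rate_is_undefined(self):
        with pytest.raises(UndefinedEquilibriumError):
            equilibrium_constants(RateConstants(1e-3, 0, 1e-3, 1e-3, 1e-3, 1e-3))


class TestRelativeChange:
    def test_identity_and_direct_division(self):
        base = equilibrium_constants(RateConstants(1e-3, 1e-2, 5e-3, 1e-3, 2e-3, 1e-4))
        assert relative_equilibrium_change(base, base) == {
            "K1": 1.0, "K2": 1.0, "K3": 1.0, "K_total": 1.0
        }
        stim = equilibrium_constants(
            RateConstants(1e-3, 1e-2, 5e-3, 1e-3, 1.2e-2, 1e-4)
        )
        ratios = relative_equilibrium_change(stim, base)
        assert ratios["K3"] == pytest.approx(6.0)
        assert ratios["K_total"] == pytest.approx(6.0)

    def test_matches_scalar_division_for_random_scalings(self):
        rng = np.random.default_rng(3)
        base = equilibrium_constants(random_rate_constants(rng))
        other = equilibrium_constants(random_rate_constants(rng))
        ratios = relative_equilibrium_change(other, base)
        for name in ("K1", "K2", "K3", "K_total"):
            assert ratios[name] == pytest.approx(
                getattr(other, name) / getattr(base, name)
            )


class TestAlgebraicEquilibrium:
    def test_single_step_reduces_to_quadratic_binding(self):
        # with only A + B <=> C1 active the equilibrium solves
        # K1*(A0-C)*(B0-C) = C, a quadratic with closed form
        k1, km1, A0, B0 = 1e-3, 1e-2, 36.0, 50.0
        K1 = k1 / km1
        rates = RateConstants(k1=k1, k_m1=km1, k2=0, k_m2=1e-3, k3=0, k_m3=1e-4)
        eq = algebraic_equilibrium("three_step", rates, A0, B0)
        b = A0 + B0 + 1 / K1
        c_closed = (b - np.sqrt(b**2 - 4 * A0 * B0)) / 2
        assert eq.C1 == pytest.approx(c_closed, rel=1e-10)
        assert eq.C2 == 0 and eq.D == 0

    def test_no_forward_flux_leaves_free_substrates(self):
        rates = RateConstants(k1=0, k_m1=1e-2, k2=0, k_m2=1e-3, k3=0, k_m3=1e-4)
        eq = algebraic_equilibrium("three_step", rates, 36, 36)
        assert (eq.A, eq.B, eq.C1, eq.C2, eq.D, eq.E) == (36, 36, 0, 0, 0, 0)

    @pytest.mark.parametrize("scheme", ["three_step", "two_step"])
    def test_equilibrium_state_has_zero_derivatives(self, scheme):
        rng = np.random.default_rng(11)
        for _ in range(10):
            rates = random_rate_constants(rng)
            eq = algebraic_equilibrium(scheme, rates, 36, 36)
            d = mass_action_derivatives(scheme, rates, eq)
            assert max(abs(v) for v in d.values()) < 1e-9


class TestSubstrateConcentrationRobustness:
    def test_doubling_substrates_preserves_recovered_constants(self, three_step_rates):
        """Fits at 36 nM and 72 nM recover the same equilibrium constants."""
        import warnings
        from strandex.estimators import FitConfig, fit_time_course
        from strandex.synthetic import NoiseModel, generate_exchange_course

        truth = equilibrium_constants(three_step_rates)
        times = np.arange(0, 1001, 10.0)
        recovered = {}
        for conc in (36.0, 72.0):
            data = generate_exchange_course(
                rates=three_step_rates, A0=conc, B0=conc, times=times,
                noise=NoiseModel(sd=0.0),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_time_course(
                    data, FitConfig(n_starts=8, seed=2, rtol=1e-7, atol=1e-9)
                )
            recovered[conc] = fit.equilibrium_
        for name in ("K1", "K2", "K3", "K_total"):
            for conc in (36.0, 72.0):
                assert getattr(recovered[conc], name) == pytest.approx(
                    getattr(truth, name), rel=0.05
                )
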