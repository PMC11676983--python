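"""Mass-action model: rate law, integration, closed form, equilibrium."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmsdr.reaction_model import (
    ReactionState,
    TMSDRSystem,
    Trajectory,
    closed_form_extent,
    equilibrium_extent,
    mass_action_rhs,
    simulate,
    substitution_ratio,
)


@pytest.mark.parametrize(
    "ka,kd,state,expected",
    [
        # empty system: nothing reacts
        (1e-3, 1e-4, (0, 0, 0, 0), (0, 0, 0, 0)),
        # detailed balance: equal rates, equal concentrations
        (1e-3, 1e-3, (1, 1, 1, 1), (0, 0, 0, 0)),
        # hand evaluation: v = 1e-3*10*10 - 0 = 0.1 nM/s
        (1e-3, 1e-4, (10, 10, 0, 0), (-0.1, -0.1, 0.1, 0.1)),
    ],
)
def test_rhs_examples(ka, kd, state, expected):
    system = TMSDRSystem(ka=ka, kd=kd)
    rates = mass_action_rhs(ReactionState(*state), system)
    np.testing.assert_allclose(rates, expected, atol=1e-15)


@given(
    x=st.lists(st.floats(0, 100), min_size=4, max_size=4),
    ka=st.floats(1e-6, 1e-2),
    kd=st.floats(0, 1e-2),
)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_rhs_conserves_pairings(x, ka, kd):
    """dx1+dx3, dx2+dx3 and dx4-dx3 all have zero instantaneous change."""
    rates = mass_action_rhs(ReactionState(*x), TMSDRSystem(ka=ka, kd=kd))
    assert rates[0] + rates[2] == 0
    assert rates[1] + rates[2] == 0
    assert rates[3] - rates[2] == 0


def test_rhs_rejects_negative_concentration():
    system = TMSDRSystem(ka=1e-3, kd=0.0)
    with pytest.raises(ValueError, match="negative"):
        mass_action_rhs(np.array([-1.0, 1.0, 0.0, 0.0]), system)


class TestSimulate:
    def test_irreversible_goes_to_completion(self):
        system = TMSDRSystem(ka=1e-3, kd=0.0)
        traj = simulate(system, ReactionState(10, 10), [0, 1e3, 1e7])
        # equal initials: x1(t) = C/(1 + C*ka*t) = 1e-4 nM at t = 1e7 s
        assert traj.x1[-1] == pytest.approx(0.0, abs=2e-4)

    def test_missing_coreactant_is_inert(self):
        system = TMSDRSystem(ka=1e-3, kd=1e-4)
        traj = simulate(system, ReactionState(10, 0), np.arange(0, 1000.0, 10))
        np.testing.assert_allclose(
            traj.states, np.tile(traj.states[0], (traj.times.size, 1)), atol=1e-12
        )

    def test_long_time_matches_equilibrium_quadratic_oracle(self):
        """Final product level equals the physical root of the equilibrium
        polynomial, computed independently with numpy's root finder."""
        system = TMSDRSystem(ka=4.78e-5, kd=4.60e-3)
        traj = simulate(system, ReactionState(10, 10), [0, 1e4, 1e6])
        # ka*(10-x)^2 = kd*x^2 rearranged to standard polynomial form
        ka, kd = system.ka, system.kd
        roots = np.roots([ka - kd, -20 * ka, 100 * ka])
        oracle = min(r for r in roots.real if 0 <= r <= 10 + 1e-9)
        assert oracle == pytest.approx(0.925, abs=5e-3)
        assert traj.x4[-1] == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("ka,kd", [(1e-3, 1e-4), (5e-5, 4e-3), (1e-6, 1e-6)])
    def test_conservation_along_trajectory(self, ka, kd):
        system = TMSDRSystem(ka=ka, kd=kd)
        traj = simulate(system, ReactionState(8, 12, 1, 2), np.arange(0, 5401.0, 10))
        for conserved in (traj.x1 + traj.x3, traj.x2 + traj.x3, traj.x4 - traj.x3):
            assert np.max(np.abs(conserved - conserved[0])) < 1e-6

    def test_detailed_balance_at_convergence(self):
        system = TMSDRSystem(ka=1.74e-4, kd=8.51e-4)
        traj = simulate(system, ReactionState(10, 10), [0, 1e5, 1e7])
        final = traj.final_state
        flux = system.ka * final.x1 * final.x2 - system.kd * final.x3 * final.x4
        assert abs(flux) < 1e-9

    def test_rejects_bad_grid(self):
        system = TMSDRSystem(ka=1e-3, kd=0.0)
        with pytest.raises(ValueError):
            simulate(system, ReactionState(10, 10), [10.0, 20.0])
        with pytest.raises(ValueError):
            simulate(system, ReactionState(10, 10), [0.0, 5.0, 5.0])

    def test_single_point_grid_returns_initial(self):
        system = TMSDRSystem(ka=1e-3, kd=0.0)
        traj = simulate(system, ReactionState(10, 10), [0.0])
        np.testing.assert_array_equal(traj.states, [[10, 10, 0, 0]])


class TestClosedForm:
    def test_starts_at_zero_and_reaches_equilibrium(self):
        system = TMSDRSystem(ka=1e-4, kd=3e-4)
        initial = ReactionState(10, 10)
        assert closed_form_extent(system, initial, 0.0) == 0.0
        x_inf = closed_form_extent(system, initial, 1e12)
        assert x_inf == pytest.approx(equilibrium_extent(system, initial), rel=1e-12)

    def test_irreversible_textbook_progress_curve(self):
        """kd=0, equal initials C: x(t) = C^2*ka*t / (1 + C*ka*t)."""
        ka, C = 1e-3, 10.0
        system = TMSDRSystem(ka=ka, kd=0.0)
        t = np.array([0.0, 10.0, 100.0, 1e3, 1e5])
        expected = C * C * ka * t / (1 + C * ka * t)
        np.testing.assert_allclose(
            closed_form_extent(system, ReactionState(C, C), t), expected, rtol=1e-12
        )

    @pytest.mark.parametrize("ka", [1e-6, 1e-4, 1e-2])
    @pytest.mark.parametrize("kd", [1e-6, 1e-4, 1e-2])
    @pytest.mark.parametrize("init", [(10, 10, 0, 0), (5, 12, 3, 1), (1, 20, 0, 0)])
    def test_matches_numeric_integration(self, ka, kd, init):
        """Analytic progress curve vs the stiff ODE integrator."""
        system = TMSDRSystem(ka=ka, kd=kd)
        initial = ReactionState(*init)
        t = np.array([0, 10, 100, 1000, 5400, 5e4])
        traj = simulate(system, initial, t)
        numeric = initial.x1 - traj.x1
        analytic = closed_form_extent(system, initial, t)
        scale = max(1e-3, np.max(np.abs(analytic)))
        np.testing.assert_allclose(analytic, numeric, atol=1e-5 * scale, rtol=1e-5)

    def test_equal_rates_uses_linear_limit(self):
        """ka = kd makes the rate polynomial linear; no division by zero."""
        system = TMSDRSystem(ka=2e-4, kd=2e-4)
        initial = ReactionState(10, 10)
        t = np.array([0, 100.0, 1e4, 1e8])
        traj = simulate(system, initial, t)
        np.testing.assert_allclose(
            closed_form_extent(system, initial, t), initial.x1 - traj.x1, atol=1e-6
        )
        assert closed_form_extent(system, initial, 1e12) == pytest.approx(5.0)

    def test_monotone_from_zero_products(self):
        system = TMSDRSystem(ka=9.68e-5, kd=1.60e-3)
        t = np.arange(0, 5401.0, 10)
        x = closed_form_extent(system, ReactionState(10, 10), t)
        assert np.all(np.diff(x) >= -1e-12)


class TestEquilibrium:
    def test_symmetric_rates_give_half_conversion(self):
        for C in (1.0, 10.0):
            system = TMSDRSystem(ka=3e-4, kd=3e-4)
            assert equilibrium_extent(system, ReactionState(C, C)) == pytest.approx(C / 2)

    @pytest.mark.parametrize("C", [1.0, 10.0, 100.0])
    def test_equal_initials_ratio_concentration_invariant(self, C):
        """x*/C = sqrt(K)/(1+sqrt(K)) regardless of the common concentration."""
        system = TMSDRSystem(ka=1.74e-4, kd=8.51e-4)
        K = system.ka / system.kd
        expected = np.sqrt(K) / (1 + np.sqrt(K))
        x_star = equilibrium_extent(system, ReactionState(C, C))
        assert x_star / C == pytest.approx(expected, rel=1e-12)

    def test_irreversible_runs_to_limiting_reactant(self):
        system = TMSDRSystem(ka=1e-3, kd=0.0)
        assert equilibrium_extent(system, ReactionState(7, 12)) == pytest.approx(7.0)

    def test_backward_running_reaction_has_negative_extent(self):
        """Starting product-heavy with dominant back reaction, x* < 0."""
        system = TMSDRSystem(ka=1e-5, kd=1e-3)
        x_star = equilibrium_extent(system, ReactionState(1, 1, 9, 9))
        assert x_star < 0
        t = np.array([0.0, 1e3, 1e8])
        traj = simulate(system, ReactionState(1, 1, 9, 9), t)
        assert traj.x1[-1] - 1.0 == pytest.approx(-x_star, rel=1e-6)

    @given(
        ka=st.floats(1e-6, 1e-2),
        kd=st.floats(1e-6, 1e-2),
        a=st.floats(0.1, 100),
        b=st.floats(0.1, 100),
        c=st.floats(0, 50),
        d=st.floats(0, 50),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_root_is_physical_and_balances_fluxes(self, ka, kd, a, b, c, d):
        system = TMSDRSystem(ka=ka, kd=kd)
        initial = ReactionState(a, b, c, d)
        x = equilibrium_extent(system, initial)
        assert -min(c, d) - 1e-9 <= x <= min(a, b) + 1e-9
        forward = ka * (a - x) * (b - x)
        backward = kd * (c + x) * (d + x)
        assert forward == pytest.approx(backward, rel=1e-6, abs=1e-9)


class TestSubstitutionRatio:
    def test_endpoint_values(self):
        assert substitution_ratio(0.0, 10.0) == 0.0
        assert substitution_ratio(10.0, 10.0) == 1.0

    def test_strongly_forward_construct_reaches_80_pct(self):
        """ka/kd ~ 22 gives sqrt(K)/(1+sqrt(K)) ~ 0.823 at equal initials."""
        system = TMSDRSystem(ka=6.48e-4, kd=2.98e-5)
        x_star = equilibrium_extent(system, ReactionState(10, 10))
        ratio = substitution_ratio(x_star, 10.0)
        K = system.ka / system.kd
        assert ratio == pytest.approx(np.sqrt(K) / (1 + np.sqrt(K)), rel=1e-12)
        assert ratio == pytest.approx(0.823, abs=5e-4)

    def test_trajectory_input(self):
        system = TMSDRSystem(ka=1e-3, kd=0.0)
        traj = simulate(system, ReactionState(10, 10), [0, 100.0, 1e7])
        r = substitution_ratio(traj, 10.0)
        assert r[0] == pytest.approx(0.0, abs=1e-12)
        assert r[-1] == pytest.approx(1.0, abs=2e-5)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            substitution_ratio(1.0, 0.0)
        with pytest.raises(ValueError):
            substitution_ratio(-0.5, 10.0)


def test_trajectory_csv_round_trip(tmp_path):
    system = TMSDRSystem(ka=2e-4, kd=1e-4)
    traj = simulate(system, ReactionState(10, 10), np.arange(0, 100.0, 10))
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == "time_s,x1_nM,x2_nM,x3_nM,x4_nM"
    loaded = Trajectory.from_csv(path)
    np.testing.assert_allclose(loaded.states, traj.states, rtol=1e-12)


def test_system_validation():
    with pytest.raises(ValueError):
        TMSDRSystem(ka=0.0, kd=1e-4)
    with pytest.raises(ValueError):
        TMSDRSystem(ka=1e-4, kd=-1e-5)
    with pytest.raises(ValueError):
        TMSDRSystem(ka=1e-4, kd=0.0, toehold_length=0)
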