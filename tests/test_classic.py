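"""Classic one-compartment kinetics and phase-switch variants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tkcd import (
    ExposureSchedule,
    OneCompartmentParams,
    PhaseSwitchParams,
    effective_k_series,
    fit_one_compartment,
    integrate,
    one_compartment_solution,
    phase_switch_solution,
    solve_equilibrium,
)
from tkcd.core import ValidationError


class TestOneCompartment:
    def test_closed_form_matches_numerical_integration(self):
        """The exponential solution solves dC/dt = ka*Cext - ke*C."""
        p = OneCompartmentParams(k_a=0.3, k_e=0.12, c_ext=50.0, c0=5.0)
        t = np.linspace(0.0, 40.0, 81)
        sol = solve_ivp(
            lambda _t, y: [p.k_a * p.c_ext - p.k_e * y[0]],
            (0.0, 40.0),
            [p.c0],
            t_eval=t,
            rtol=1e-11,
            atol=1e-12,
        )
        assert np.allclose(one_compartment_solution(p, t), sol.y[0], atol=1e-8)

    def test_asymptote(self):
        p = OneCompartmentParams(k_a=0.3, k_e=0.1, c_ext=10.0)
        assert one_compartment_solution(p, 1e6) == pytest.approx(30.0)

    def test_equal_constants_asymptote_is_external_concentration(self):
        p = OneCompartmentParams(k_a=0.2, k_e=0.2, c_ext=7.0)
        assert one_compartment_solution(p, 1e6) == pytest.approx(7.0)

    def test_depuration_is_pure_exponential_decay(self):
        p = OneCompartmentParams(k_a=0.3, k_e=0.25, c_ext=0.0, c0=12.0)
        t = np.array([0.0, 1.0, 4.0])
        assert np.allclose(
            one_compartment_solution(p, t), 12.0 * np.exp(-0.25 * t)
        )

    def test_zero_elimination_accumulates_linearly(self):
        p = OneCompartmentParams(k_a=0.5, k_e=0.0, c_ext=10.0, c0=1.0)
        assert one_compartment_solution(p, 4.0) == pytest.approx(21.0)


class TestPhaseSwitch:
    def test_identical_constants_reduce_to_one_compartment(self):
        # (near-)identical constants in both phases: the switch is invisible
        same = PhaseSwitchParams(
            scenario=2, k_a1=0.3, k_e1=0.1, k_a2=0.3 - 1e-15, k_e2=0.1,
            c_ext=10.0, trigger="time", trigger_value=15.0,
        )
        t = np.linspace(0.01, 60.0, 200)
        ref = one_compartment_solution(
            OneCompartmentParams(0.3, 0.1, 10.0), t
        )
        assert np.allclose(phase_switch_solution(same, t), ref, atol=1e-12)

    def test_unreached_trigger_reduces_to_one_compartment(self):
        p = PhaseSwitchParams(
            scenario=1, k_a1=0.3, k_e1=0.1, k_a2=0.3, k_e2=0.4,
            c_ext=10.0, trigger="amount", trigger_value=1e9,
        )
        t = np.linspace(0.01, 60.0, 200)
        ref = one_compartment_solution(OneCompartmentParams(0.3, 0.1, 10.0), t)
        assert np.allclose(phase_switch_solution(p, t), ref, atol=1e-12)

    def test_scenario1_rise_then_fall_under_constant_exposure(self):
        """Low early elimination, then a jump to k_e2 > k_e1: the amount
        climbs, then declines toward the new lower asymptote."""
        p = PhaseSwitchParams(
            scenario=1, k_a1=0.3, k_e1=0.05, k_a2=0.3, k_e2=0.3,
            c_ext=10.0, trigger="time", trigger_value=10.0,
        )
        t = np.linspace(0.01, 80.0, 400)
        c = phase_switch_solution(p, t)
        before = c[t < 10.0]
        after = c[t >= 10.0]
        assert np.all(np.diff(before) > 0)
        assert np.all(np.diff(after) < 0)
        assert after[-1] == pytest.approx(0.3 * 10.0 / 0.3, rel=0.01)

    def test_amount_trigger_switches_at_the_threshold(self):
        p = PhaseSwitchParams(
            scenario=2, k_a1=0.5, k_e1=0.1, k_a2=0.1, k_e2=0.1,
            c_ext=10.0, trigger="amount", trigger_value=20.0,
        )
        t = np.linspace(0.01, 100.0, 2000)
        c = phase_switch_solution(p, t)
        assert c.max() == pytest.approx(20.0, abs=0.1)
        assert c[-1] == pytest.approx(0.1 * 10.0 / 0.1, rel=0.01)

    def test_continuity_at_switch_and_depuration(self):
        p = PhaseSwitchParams(
            scenario=3, k_a1=0.5, k_e1=0.05, k_a2=0.2, k_e2=0.3,
            c_ext=10.0, trigger="time", trigger_value=8.0,
            depuration_start=30.0,
        )
        t = np.linspace(0.0, 60.0, 6001)
        c = phase_switch_solution(p, t)
        assert np.all(np.abs(np.diff(c)) < 0.1)  # no jumps on a 0.01 grid
        assert c[-1] < 0.01 * c.max()  # washout toward pre-exposure level

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(scenario=1, k_a1=0.3, k_e1=0.4, k_a2=0.3, k_e2=0.2,
                  c_ext=1.0), "k_e1 < k_e2"),
            (dict(scenario=1, k_a1=0.3, k_e1=0.1, k_a2=0.2, k_e2=0.2,
                  c_ext=1.0), "single absorption"),
            (dict(scenario=2, k_a1=0.1, k_e1=0.1, k_a2=0.3, k_e2=0.1,
                  c_ext=1.0), "k_a1 > k_a2"),
            (dict(scenario=3, k_a1=0.3, k_e1=0.1, k_a2=0.4, k_e2=0.2,
                  c_ext=1.0), "scenario 3"),
        ],
    )
    def test_scenario_orderings_enforced(self, kwargs, message):
        with pytest.raises(ValidationError, match=message):
            PhaseSwitchParams(**kwargs)


class TestEffectiveK:
    def test_onset_value_is_second_class_death_rate(
        self, preset_trajectories
    ):
        """When contamination begins, all burden sits in class 2, so the
        emergent elimination rate starts at d_2 = 0.11."""
        k = effective_k_series(preset_trajectories["high"])
        defined = k[~np.isnan(k)]
        assert defined[0] == pytest.approx(0.11, abs=1e-3)

    def test_series_rises_toward_equilibrium_value(
        self, preset_trajectories, params
    ):
        traj = preset_trajectories["moderate"]
        k = effective_k_series(traj)
        defined = k[~np.isnan(k)]
        eq_k = solve_equilibrium(params, 9.0).elimination_rate
        assert defined[-1] == pytest.approx(eq_k, rel=1e-6)
        assert defined[-1] > defined[0]

    def test_uncontaminated_trajectory_is_all_undefined(self, params):
        traj = integrate(params, ExposureSchedule.constant(0.0, 10.0))
        assert np.all(np.isnan(effective_k_series(traj)))

    def test_single_contaminated_class_gives_constant_k(self):
        """A two-class demography confines all burden to class 2: the
        emergent rate is the constant d_2, the classic linear picture."""
        from tkcd import ModelParams

        p = ModelParams(10.0, [0.1, 1.0])
        traj = integrate(p, ExposureSchedule.constant(1.0, 50.0))
        k = effective_k_series(traj)
        defined = k[~np.isnan(k)]
        assert np.allclose(defined, 1.0, atol=1e-12)


def test_diagnostic_fit_recovers_linear_kinetics(rng):
    """Fitting the one-compartment form to data it generated returns the
    generating constants (sanity of the diagnostic utility only)."""
    truth = OneCompartmentParams(k_a=0.25, k_e=0.15, c_ext=20.0)
    t = np.linspace(0.5, 60.0, 60)
    fitted = fit_one_compartment(t, one_compartment_solution(truth, t), 20.0)
    assert fitted.k_a == pytest.approx(0.25, rel=1e-5)
    assert fitted.k_e == pytest.approx(0.15, rel=1e-5)
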