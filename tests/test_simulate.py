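"""Integration of the cell-demography system over exposure schedules."""

import numpy as np
import pytest

from tkcd import (
    ExposureSchedule,
    InadmissibleExposureError,
    IntestineState,
    SolverOptions,
    integrate,
    run_preset,
    solve_equilibrium,
)
from tkcd.core import ValidationError


def test_clean_start_stays_at_turnover_equilibrium(params):
    """With zero influx the uncontaminated steady state is invariant."""
    traj = integrate(params, ExposureSchedule.constant(0.0, 50.0))
    assert traj.equilibrated
    assert np.allclose(traj.final_state.N, [100, 0, 0, 0, 0], atol=1e-12)


def test_clean_relaxation_matches_linear_decay(params):
    """Starting off-equilibrium with no influx, class 1 relaxes as
    N_1(t) = b/d_1 + (N_0 - b/d_1) e^{-d_1 t}."""
    start = IntestineState(0.0, [50.0, 0, 0, 0, 0])
    traj = integrate(
        params,
        ExposureSchedule.constant(0.0, 30.0),
        SolverOptions(equilibrium_eps=1e-13),
        initial=start,
    )
    expected = 100.0 + (50.0 - 100.0) * np.exp(-0.1 * traj.times)
    assert np.allclose(traj.N[:, 0], expected, rtol=1e-9)


@pytest.mark.parametrize("name, delta_c", [("low", 1.0), ("moderate", 9.0),
                                           ("high", 34.0)])
def test_equilibrated_run_matches_fixed_point(
    preset_trajectories, params, name, delta_c
):
    traj = preset_trajectories[name]
    assert traj.equilibrated
    eq = solve_equilibrium(params, delta_c)
    assert np.allclose(traj.final_state.N, eq.N, rtol=1e-6)


def test_intestine_size_monotone_under_constant_exposure(preset_trajectories):
    """From the clean start, constant influx only shrinks the gut."""
    for traj in preset_trajectories.values():
        assert np.all(np.diff(traj.total) <= 1e-9)


def test_balance_identities_along_trajectory(preset_trajectories, params):
    """Finite-difference rates satisfy the cell-balance identity."""
    traj = preset_trajectories["moderate"]
    t, N = traj.times, traj.N
    dN = np.diff(N, axis=0) / np.diff(t)[:, None]
    # compare against the analytic balance at midpoints (2nd-order accurate)
    mid = 0.5 * (N[1:] + N[:-1])
    expected = params.b - mid @ params.d
    assert np.allclose(dN.sum(axis=1), expected, atol=1e-3)


def test_step_halving_convergence(params):
    """Halving dt changes the endpoint by far less than 1e-6 relative."""
    sched = ExposureSchedule.constant(9.0, 30.0)
    coarse = integrate(params, sched, SolverOptions(dt=0.02))
    fine = integrate(params, sched, SolverOptions(dt=0.01))
    rel = np.abs(coarse.final_state.N - fine.final_state.N) / np.abs(
        fine.final_state.N
    )
    assert np.max(rel) < 1e-6


def test_adaptive_agrees_with_rk4(params):
    sched = ExposureSchedule.constant(9.0, 30.0)
    rk4 = integrate(params, sched, SolverOptions(method="rk4"))
    ada = integrate(params, sched, SolverOptions(method="adaptive"))
    assert np.allclose(rk4.final_state.N, ada.final_state.N, rtol=1e-7)


def test_integration_restarts_at_breakpoints(params):
    """Exposure-then-depuration: burden rises, then decays back toward 0."""
    sched = ExposureSchedule([(0.0, 9.0), (30.0, 0.0)], 120.0)
    traj = integrate(params, sched)
    assert 30.0 in traj.times  # breakpoint is an exact grid point
    c = traj.c_int
    i_break = int(np.flatnonzero(traj.times == 30.0)[0])
    assert c[i_break] > 30.0  # accumulated during exposure
    assert np.all(np.diff(c[i_break:]) <= 1e-12)  # monotone depuration
    assert c[-1] < 0.05 * c[i_break]
    # gut recovers toward the 100-cell baseline on clean food
    assert traj.total[-1] > 0.99 * 100.0


def test_inadmissible_exposure_raises(params):
    sched = ExposureSchedule.constant(150.0, 10.0)
    with pytest.raises(InadmissibleExposureError):
        integrate(params, sched)


def test_clamp_mode_completes_with_warning(params):
    sched = ExposureSchedule.constant(150.0, 10.0)
    with pytest.warns(Warning):
        traj = integrate(params, sched, SolverOptions(clamp_absorption=True))
    assert not traj.admissible
    assert traj.max_absorption > 1.0


def test_explicit_initial_state_must_match_classes(params):
    with pytest.raises(ValidationError):
        integrate(
            params,
            ExposureSchedule.constant(1.0, 10.0),
            initial=IntestineState(0.0, [10.0, 0.0]),
        )


def test_unknown_preset_rejected():
    with pytest.raises(ValidationError, match="unknown preset"):
        run_preset("extreme")


def test_trajectory_frame_schema(preset_trajectories):
    frame = preset_trajectories["low"].to_frame()
    expected = (
        ["t"]
        + [f"N_{i}" for i in range(1, 6)]
        + ["N_total", "C_int", "loss_pct", "k"]
        + [f"q_{i}" for i in range(1, 6)]
        + ["delta_c"]
    )
    assert list(frame.columns) == expected
    assert np.isnan(frame["k"].iloc[0])  # clean gut: rate undefined
    assert frame["q_1"].iloc[0] == pytest.approx(1.0)
    q = frame[[f"q_{i}" for i in range(1, 6)]].to_numpy()
    assert np.allclose(q.sum(axis=1), 1.0)


class TestPresetScience:
    """Qualitative features of the three built-in scenarios."""

    def test_low_toxicity_losses_are_minor(self, preset_trajectories):
        traj = preset_trajectories["low"]
        loss = 100.0 * (1.0 - traj.total[-1] / 100.0)
        assert loss < 5.0

    def test_moderate_burden_peaks_then_declines_slightly(
        self, preset_trajectories
    ):
        traj = preset_trajectories["moderate"]
        t_peak, c_peak = traj.peak_toxicant()
        assert c_peak > traj.c_int[-1] > 0.9 * c_peak

    def test_high_burden_peak_then_decline_to_moderate_level(
        self, preset_trajectories, params
    ):
        """The hallmark rise-then-fall: the burden overshoots, then falls
        to roughly the moderate scenario's equilibrium level."""
        traj = preset_trajectories["high"]
        t_peak, c_peak = traj.peak_toxicant()
        final = traj.c_int[-1]
        assert c_peak > 1.5 * final  # clear peak
        moderate_eq = solve_equilibrium(params, 9.0).c_int
        assert final == pytest.approx(moderate_eq, rel=0.15)

    def test_high_run_remains_admissible(self, preset_trajectories):
        traj = preset_trajectories["high"]
        assert traj.admissible
        assert traj.max_absorption <= 1.0
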