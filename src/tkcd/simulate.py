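"""Numerical integration of the contamination-class system over an exposure.

The default integrator is classic fixed-step RK4: the system is small
(``l`` equations), smooth and non-stiff at demographically plausible
parameters, so a fixed step of 0.01 time units resolves it far below the
tolerances anything downstream needs.  An adaptive alternative
(``method="adaptive"``, SciPy RK45) is available for unusual parameter
ranges.  Integration restarts exactly at exposure breakpoints, so step
changes in influx are never smeared across a step.

Integration stops at the horizon, or earlier — once inside the final
exposure segment — when the system has equilibrated
(``max_i |dN_i/dt| < equilibrium_eps``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from numpy.typing import NDArray
from scipy.integrate import solve_ivp

from . import observables
from .core import IntestineState, ModelParams, ValidationError, derivatives
from .exposure import ExposureSchedule

__all__ = ["SolverOptions", "Trajectory", "integrate", "run_preset", "PRESET_NAMES"]

PRESET_NAMES = ("low", "moderate", "high")


@dataclass(frozen=True)
class SolverOptions:
    """Integrator configuration.

    Parameters
    ----------
    method : {"rk4", "adaptive"}
        Fixed-step RK4 (default) or SciPy's adaptive RK45.
    dt : float
        RK4 step, in model time units.
    store_stride : int
        Store every ``store_stride``-th step (segment boundaries and the
        final point are always stored).  Peak-time resolution equals
        ``store_stride * dt``.
    equilibrium_eps : float
        Stop once ``max|dN_i/dt|`` falls below this, within the final
        exposure segment.
    rtol, atol : float
        Tolerances for the adaptive method.
    clamp_absorption : bool
        Clamp ``delta_c/N > 1`` to 1 with a warning instead of raising.
    """

    method: Literal["rk4", "adaptive"] = "rk4"
    dt: float = 0.01
    store_stride: int = 1
    equilibrium_eps: float = 1e-9
    rtol: float = 1e-10
    atol: float = 1e-12
    clamp_absorption: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("rk4", "adaptive"):
            raise ValidationError(f"unknown solver method {self.method!r}")
        if self.dt <= 0 or self.store_stride < 1:
            raise ValidationError("dt must be positive and store_stride >= 1")
        if self.equilibrium_eps <= 0 or self.rtol <= 0 or self.atol <= 0:
            raise ValidationError("tolerances must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Stored time course of the intestine state with derived observables.

    ``N`` has one row per stored time point and one column per
    contamination class.  ``admissible`` records whether the absorption
    probability ``delta_c/N`` stayed at or below one throughout;
    ``equilibrated`` whether integration ended by the stationarity
    criterion rather than the horizon.
    """

    params: ModelParams
    times: NDArray[np.float64]
    N: NDArray[np.float64]
    delta_c: NDArray[np.float64]
    equilibrated: bool
    admissible: bool
    max_absorption: float
    options: SolverOptions = field(default_factory=SolverOptions)

    @property
    def final_state(self) -> IntestineState:
        return IntestineState(self.times[-1], self.N[-1])

    @property
    def c_int(self) -> NDArray[np.float64]:
        """Body burden series ``sum_i N_i (i-1)`` at stored points."""
        return self.N @ np.arange(self.params.l, dtype=float)

    @property
    def total(self) -> NDArray[np.float64]:
        """Intestine size series."""
        return self.N.sum(axis=1)

    def peak_toxicant(self) -> tuple[float, float]:
        """(time, value) of the maximum body burden over stored points."""
        return observables.peak_toxicant(self.times, self.c_int)

    def elimination_rate_series(self) -> NDArray[np.float64]:
        """Instantaneous elimination rate per stored point; NaN when the
        intestine is uncontaminated (the rate is undefined there)."""
        weights = np.arange(self.params.l, dtype=float)
        burden = self.c_int
        removed = (self.N * self.params.d) @ weights
        out = np.full(burden.shape, np.nan)
        np.divide(removed, burden, out=out, where=burden > 0)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the trajectory with all per-point observables.

        Columns: ``t``, ``N_1..N_l``, ``N_total``, ``C_int``, ``loss_pct``,
        ``k`` (NaN where undefined), ``q_1..q_l``, ``delta_c``.
        """
        l = self.params.l
        total = self.total
        data: dict[str, NDArray[np.float64]] = {"t": self.times}
        for i in range(l):
            data[f"N_{i + 1}"] = self.N[:, i]
        data["N_total"] = total
        data["C_int"] = self.c_int
        data["loss_pct"] = 100.0 * (1.0 - total / self.params.baseline_cells)
        data["k"] = self.elimination_rate_series()
        for i in range(l):
            data[f"q_{i + 1}"] = self.N[:, i] / total
        data["delta_c"] = self.delta_c
        return pd.DataFrame(data)

    def plot(self, path=None):
        """Three-panel summary figure (cells, burden, elimination rate)."""
        from .plotting import plot_trajectory

        return plot_trajectory(self, path=path)


def _rk4_segment(
    N: NDArray[np.float64],
    t0: float,
    t1: float,
    level: float,
    params: ModelParams,
    opts: SolverOptions,
    check_equilibrium: bool,
    store: list[tuple[float, NDArray[np.float64]]],
) -> tuple[NDArray[np.float64], float, bool]:
    """Advance one constant-influx segment; returns (state, t, equilibrated)."""
    dt = opts.dt
    clamp = opts.clamp_absorption
    n_steps = max(1, int(np.ceil((t1 - t0) / dt - 1e-12)))
    t = t0
    for step in range(n_steps):
        h = min(dt, t1 - t)
        k1 = derivatives(N, level, params, clamp=clamp)
        if check_equilibrium and np.max(np.abs(k1)) < opts.equilibrium_eps:
            return N, t, True
        k2 = derivatives(N + 0.5 * h * k1, level, params, clamp=clamp)
        k3 = derivatives(N + 0.5 * h * k2, level, params, clamp=clamp)
        k4 = derivatives(N + h * k3, level, params, clamp=clamp)
        N = N + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = t + h
        # RK4 can undershoot an empty class by O(h^5); anything larger than
        # roundoff-scale negativity indicates a genuinely bad step.
        if np.any(N < 0):
            if np.min(N) < -1e-9:
                raise ValidationError(
                    f"integration produced negative occupancy {np.min(N):.3g} "
                    f"at t={t:.4g}; reduce dt"
                )
            N = np.clip(N, 0.0, None)
        if not np.all(np.isfinite(N)):
            raise ValidationError(f"non-finite state at t={t:.4g}")
        if (step + 1) % opts.store_stride == 0 and t < t1:
            store.append((t, N))
    return N, t1, False


def integrate(
    params: ModelParams,
    schedule: ExposureSchedule,
    opts: SolverOptions | None = None,
    *,
    initial: IntestineState | None = None,
) -> Trajectory:
    """Integrate the contamination-class system over an exposure schedule.

    Starts from the uncontaminated steady state (``N_1 = b/d_1``) unless an
    explicit ``initial`` state is given.  The integration grid restarts at
    every schedule breakpoint, and stops early once the final segment has
    equilibrated.

    Raises :class:`tkcd.core.InadmissibleExposureError` if the absorption
    probability ``delta_c/N`` exceeds one (unless
    ``opts.clamp_absorption``), and a validation error on non-finite or
    negative states.
    """
    opts = opts or SolverOptions()
    if initial is None:
        N = np.zeros(params.l)
        N[0] = params.b / params.d[0]
        t = 0.0
    else:
        if initial.N.shape[0] != params.l:
            raise ValidationError("initial state has wrong number of classes")
        N, t = initial.N.copy(), initial.t

    boundaries = [s for s, _ in schedule.segments if s > t] + [schedule.horizon]
    store: list[tuple[float, NDArray[np.float64]]] = [(t, N.copy())]
    equilibrated = False
    for t1 in boundaries:
        level = schedule.delta_c_at(t)
        is_last = t1 == schedule.horizon
        if opts.method == "rk4":
            N, t, equilibrated = _rk4_segment(
                N, t, t1, level, params, opts, check_equilibrium=is_last, store=store
            )
        else:
            N, t = _adaptive_segment(N, t, t1, level, params, opts, store)
            if is_last:
                rhs = derivatives(N, level, params, clamp=opts.clamp_absorption)
                equilibrated = bool(np.max(np.abs(rhs)) < opts.equilibrium_eps)
        store.append((t, N.copy()))
        if equilibrated:
            break

    times = np.array([s[0] for s in store])
    states = np.array([s[1] for s in store])
    # drop duplicated boundary points (stored both by stride and explicitly)
    keep = np.concatenate([[True], np.diff(times) > 0])
    times, states = times[keep], states[keep]
    dc = np.array([schedule.delta_c_at(min(tt, schedule.horizon)) for tt in times])
    with np.errstate(divide="ignore"):
        totals = states.sum(axis=1)
        absorption = np.where(totals > 0, dc / totals, np.inf)
    max_abs = float(np.max(absorption))
    return Trajectory(
        params=params,
        times=times,
        N=states,
        delta_c=dc,
        equilibrated=equilibrated,
        admissible=bool(max_abs <= 1.0 + 1e-12),
        max_absorption=max_abs,
        options=opts,
    )


def _adaptive_segment(N, t0, t1, level, params, opts, store):
    """Integrate one constant-influx segment with SciPy's RK45."""
    sol = solve_ivp(
        lambda _t, y: derivatives(y, level, params, clamp=opts.clamp_absorption),
        (t0, t1),
        N,
        method="RK45",
        rtol=opts.rtol,
        atol=opts.atol,
        dense_output=True,
    )
    if not sol.success:
        raise ValidationError(f"adaptive integration failed: {sol.message}")
    grid = np.arange(t0, t1, opts.dt * opts.store_stride)[1:]
    for tt in grid:
        store.append((float(tt), np.clip(sol.sol(tt), 0.0, None)))
    return np.clip(sol.y[:, -1], 0.0, None), t1


def _load_preset(name: str) -> dict:
    if name not in PRESET_NAMES:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {', '.join(PRESET_NAMES)}"
        )
    ref = importlib.resources.files("tkcd") / "presets" / f"{name}.yaml"
    return yaml.safe_load(ref.read_text())


def run_preset(
    name: str, opts: SolverOptions | None = None
) -> Trajectory:
    """Run one of the built-in constant-exposure scenarios to equilibrium.

    ``low``, ``moderate`` and ``high`` correspond to constant influx
    ``delta_c`` of 1, 9 and 34 toxic particles per time unit on the
    reference demography (``b = 10``, ``d = (0.1, 0.11, 0.2, 0.9, 1)``,
    100 cells at start).  Horizons are long enough for the equilibration
    criterion to trigger.
    """
    cfg = _load_preset(name)
    params = ModelParams(cfg["b"], cfg["d"])
    schedule = ExposureSchedule.constant(cfg["delta_c"], cfg["horizon"])
    return integrate(params, schedule, opts)
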