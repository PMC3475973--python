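"""Classic one-compartment kinetics and phenomenological phase-switch variants.

The traditional description of toxicant kinetics is the linear balance

.. math::

    \\dot C_{int} = k_a C_{ext} - k_e C_{int}

with constant absorption and elimination rate constants: exponential
approach to the plateau ``k_a C_ext / k_e`` during exposure, exponential
washout during depuration.  Observed rise-then-fall kinetics under constant
exposure cannot come out of this form; phenomenological fixes switch one or
both constants partway through exposure:

- scenario 1: one ``k_a``, elimination jumps up (``k_e1 < k_e2``);
- scenario 2: one ``k_e``, absorption drops (``k_a1 > k_a2``);
- scenario 3: both switch.

These are provided for comparison against the cell-demography model, whose
elimination rate emerges from the class structure instead of being imposed.
:func:`effective_k_series` extracts that emergent rate from a simulated
trajectory so the two descriptions can be overlaid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import least_squares

from .core import ModelParams, ValidationError
from .simulate import Trajectory

__all__ = [
    "OneCompartmentParams",
    "PhaseSwitchParams",
    "one_compartment_solution",
    "phase_switch_solution",
    "effective_k_series",
    "fit_one_compartment",
]


@dataclass(frozen=True)
class OneCompartmentParams:
    """Constants of the linear one-compartment model."""

    k_a: float
    k_e: float
    c_ext: float
    c0: float = 0.0

    def __post_init__(self) -> None:
        if self.k_a < 0 or self.k_e < 0:
            raise ValidationError("rate constants must be non-negative")
        if self.c_ext < 0 or self.c0 < 0:
            raise ValidationError("concentrations must be non-negative")


def one_compartment_solution(
    p: OneCompartmentParams, t: ArrayLike
) -> NDArray[np.float64]:
    """Closed-form internal amount at times ``t``.

    ``C(t) = (k_a/k_e) C_ext (1 - e^{-k_e t}) + C0 e^{-k_e t}`` for
    ``k_e > 0``; linear accumulation ``C0 + k_a C_ext t`` when ``k_e = 0``.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValidationError("times must be non-negative")
    if p.k_e == 0.0:
        return p.c0 + p.k_a * p.c_ext * tt
    decay = np.exp(-p.k_e * tt)
    return (p.k_a / p.k_e) * p.c_ext * (1.0 - decay) + p.c0 * decay


@dataclass(frozen=True)
class PhaseSwitchParams:
    """Two-phase rate constants with an explicit switching rule.

    ``trigger`` names what flips the constants: ``"time"`` (switch at
    ``trigger_value`` time units of exposure) or ``"amount"`` (switch when
    the internal amount first reaches ``trigger_value``).
    ``depuration_start`` is the time at which the external concentration
    drops to zero (None: exposure never ends).
    """

    scenario: Literal[1, 2, 3]
    k_a1: float
    k_e1: float
    k_a2: float
    k_e2: float
    c_ext: float
    c0: float = 0.0
    trigger: Literal["time", "amount"] = "time"
    trigger_value: float = np.inf
    depuration_start: float | None = None

    def __post_init__(self) -> None:
        for v in (self.k_a1, self.k_e1, self.k_a2, self.k_e2):
            if v < 0:
                raise ValidationError("rate constants must be non-negative")
        if self.scenario not in (1, 2, 3):
            raise ValidationError(f"scenario must be 1, 2 or 3, got {self.scenario}")
        if self.scenario == 1:
            if not self.k_e1 < self.k_e2:
                raise ValidationError("scenario 1 requires k_e1 < k_e2")
            if self.k_a1 != self.k_a2:
                raise ValidationError("scenario 1 has a single absorption constant")
        elif self.scenario == 2:
            if not self.k_a1 > self.k_a2:
                raise ValidationError("scenario 2 requires k_a1 > k_a2")
            if self.k_e1 != self.k_e2:
                raise ValidationError("scenario 2 has a single elimination constant")
        else:
            if not (self.k_e1 < self.k_e2 and self.k_a1 > self.k_a2):
                raise ValidationError(
                    "scenario 3 requires k_e1 < k_e2 and k_a1 > k_a2"
                )
        if self.trigger not in ("time", "amount"):
            raise ValidationError(f"unknown trigger {self.trigger!r}")
        if self.trigger_value < 0:
            raise ValidationError("trigger value must be non-negative")
        if self.depuration_start is not None and self.depuration_start < 0:
            raise ValidationError("depuration start must be non-negative")


def _crossing_time(p: OneCompartmentParams, threshold: float) -> float:
    """First time the closed-form solution reaches ``threshold`` (inf if never)."""
    if p.c0 >= threshold:
        return 0.0
    if p.k_e == 0.0:
        rate = p.k_a * p.c_ext
        return (threshold - p.c0) / rate if rate > 0 else np.inf
    asymptote = p.k_a * p.c_ext / p.k_e
    if threshold >= asymptote:
        return np.inf
    # invert C(t) = A + (C0 - A) e^{-k_e t}
    return float(-np.log((threshold - asymptote) / (p.c0 - asymptote)) / p.k_e)


def phase_switch_solution(
    p: PhaseSwitchParams, times: ArrayLike
) -> NDArray[np.float64]:
    """Piecewise closed-form internal amount on an increasing time grid.

    The solution is continuous at the constant switch and at depuration
    start; each piece is the one-compartment closed form with the
    constants in force, restarted from the boundary amount.  If the switch
    trigger is never reached, the series coincides with the plain
    one-compartment solution.
    """
    grid = np.asarray(times, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValidationError("times must be a strictly increasing 1-D grid")
    if np.any(grid < 0):
        raise ValidationError("times must be non-negative")

    phase1 = OneCompartmentParams(p.k_a1, p.k_e1, p.c_ext, p.c0)
    if p.trigger == "time":
        t_switch = p.trigger_value
    else:
        t_switch = _crossing_time(phase1, p.trigger_value)
    t_dep = np.inf if p.depuration_start is None else p.depuration_start
    if t_switch >= t_dep:
        t_switch = np.inf  # exposure ends first: the constants never switch

    out = np.empty_like(grid)
    # phase boundaries in order; each carries (start, params-for-piece)
    boundaries = sorted({0.0, t_switch, t_dep} - {np.inf})
    c_at = p.c0
    for j, start in enumerate(boundaries):
        end = boundaries[j + 1] if j + 1 < len(boundaries) else np.inf
        switched = start >= t_switch
        depurating = start >= t_dep
        piece = OneCompartmentParams(
            p.k_a2 if switched else p.k_a1,
            p.k_e2 if switched else p.k_e1,
            0.0 if depurating else p.c_ext,
            c_at,
        )
        mask = (grid >= start) & (grid < end)
        out[mask] = one_compartment_solution(piece, grid[mask] - start)
        if np.isfinite(end):
            c_at = float(one_compartment_solution(piece, end - start))
    return out


def effective_k_series(
    traj: Trajectory, params: ModelParams | None = None
) -> NDArray[np.float64]:
    """Emergent elimination-rate series of a cell-demography trajectory.

    Applies the elimination-rate functional pointwise over stored states;
    points with zero body burden are NaN (undefined).  When contamination
    starts from a clean gut, the first defined value is ``d_2`` — the death
    rate of the lowest contaminated class — and the series then rises
    toward its equilibrium value.
    """
    if params is not None and params != traj.params:
        raise ValidationError("params disagree with the trajectory's own")
    return traj.elimination_rate_series()


def fit_one_compartment(
    times: ArrayLike, amounts: ArrayLike, c_ext: float, *, c0: float = 0.0
) -> OneCompartmentParams:
    """Diagnostic least-squares fit of the linear model to a trajectory.

    This is a descriptive overlay utility only: the fitted ``k_a``/``k_e``
    are effective constants of a phenomenological approximation, not
    mechanistic parameters, and should not be interpreted as such.
    """
    tt = np.asarray(times, dtype=float)
    cc = np.asarray(amounts, dtype=float)
    if tt.shape != cc.shape or tt.size < 3:
        raise ValidationError("need matching time/amount series of length >= 3")

    def resid(theta):
        ka, ke = np.exp(theta)  # log-parametrisation keeps constants positive
        return one_compartment_solution(
            OneCompartmentParams(ka, ke, c_ext, c0), tt
        ) - cc

    sol = least_squares(resid, x0=np.log([0.1, 0.1]))
    ka, ke = np.exp(sol.x)
    return OneCompartmentParams(ka, ke, c_ext, c0)
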