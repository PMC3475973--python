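"""Stationary states of the contamination-class system at constant influx.

Setting every time derivative to zero and treating the intestine size ``N``
as known turns the system into a forward recursion (with ``x = delta_c/N``):

.. math::

    N_1 = \\frac{b}{d_1 + (1 - d_1) x}, \\qquad
    N_i = \\frac{(1 - d_{i-1}) x}{d_i + (1 - d_i) x} N_{i-1}, \\qquad
    N_l = (1 - d_{l-1})\\, x\\, N_{l-1}.

The nonlinearity is confined to the self-consistency requirement
``sum_i N_i(N) = N``, closed here by damped fixed-point iteration with a
bracketing root-finder as fallback.  The solved state is cross-checked
against the ODE right-hand side before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import brentq

from . import observables
from .core import (
    InadmissibleExposureError,
    IntestineState,
    ModelParams,
    ValidationError,
    derivatives,
)

__all__ = ["EquilibriumResult", "stationary_classes", "solve_equilibrium"]


class ConvergenceError(RuntimeError):
    """The stationary-state solver failed to converge."""


@dataclass(frozen=True)
class EquilibriumResult:
    """Solved stationary state and its derived observables."""

    params: ModelParams
    delta_c: float
    N: NDArray[np.float64]  # per-class occupancies
    iterations: int
    residual: float  # |sum N_i(N*) - N*| / N*

    @property
    def total(self) -> float:
        return float(self.N.sum())

    @property
    def c_int(self) -> float:
        return observables.total_toxicant(self.N)

    @property
    def percent_loss(self) -> float:
        return observables.percent_cell_loss(self.N, self.params.baseline_cells)

    @property
    def elimination_rate(self) -> float | None:
        return observables.elimination_rate(self.N, self.params)

    @property
    def state(self) -> IntestineState:
        return IntestineState(np.inf, self.N)


def stationary_classes(
    params: ModelParams, delta_c: float, N: float
) -> NDArray[np.float64]:
    """Per-class occupancies of the stationary state at assumed size ``N``.

    Evaluates the forward recursion above; for ``delta_c = 0`` this is the
    uncontaminated fixed point ``(b/d_1, 0, ..., 0)``.
    """
    if N <= 0:
        raise ValidationError(f"intestine size must be positive, got {N}")
    if delta_c < 0:
        raise ValidationError(f"influx must be non-negative, got {delta_c}")
    d = params.d
    x = delta_c / N
    out = np.zeros(params.l)
    out[0] = params.b / (d[0] + (1.0 - d[0]) * x)
    for i in range(1, params.l - 1):
        out[i] = (1.0 - d[i - 1]) * x * out[i - 1] / (d[i] + (1.0 - d[i]) * x)
    out[-1] = (1.0 - d[-2]) * x * out[-2]  # terminal class: loss coefficient is 1
    return out


def _size_mismatch(params: ModelParams, delta_c: float, N: float) -> float:
    """g(N) = sum_i N_i(N) - N; a stationary size is a root of g."""
    return float(stationary_classes(params, delta_c, N).sum() - N)


def solve_equilibrium(
    params: ModelParams,
    delta_c: float,
    *,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    ode_tol: float = 1e-8,
) -> EquilibriumResult:
    """Solve the self-consistent stationary intestine size and state.

    Iterates ``N <- (1 - damping) N + damping sum_i N_i(N)`` from the
    uncontaminated size ``b/d_1`` until the relative update falls below
    ``tol``; if that stalls, falls back to bracketed root finding on
    ``g(N) = sum_i N_i(N) - N`` over ``(0, b/d_1]``.  Before returning, the
    size axis is scanned for additional sign changes of ``g`` — a second
    root would mean the fixed point is not unique, which is reported rather
    than silently resolved — and the state is verified to be admissible
    (``delta_c / N* <= 1``) and stationary for the ODE right-hand side.

    Raises
    ------
    InadmissibleExposureError
        If the only stationary state has ``delta_c / N* > 1``.
    ConvergenceError
        If neither iteration nor bracketing converges, or multiple
        stationary sizes are found.
    """
    if params.b == 0:
        raise ValidationError("b = 0 admits no positive stationary intestine")
    N_max = params.baseline_cells  # largest possible size: zero influx
    if delta_c == 0:
        N = stationary_classes(params, 0.0, N_max)
        return EquilibriumResult(params, 0.0, N, 0, 0.0)

    N = N_max
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        N_new = float(stationary_classes(params, delta_c, N).sum())
        if abs(N_new - N) / N < tol:
            N = N_new
            converged = True
            break
        N = (1.0 - damping) * N + damping * N_new

    if not converged:
        # Bracketing fallback; g(N_max) <= 0 always (influx only shrinks the
        # gut), so walk the lower edge until the sign changes.
        lo, hi = 1e-12 * N_max, N_max
        if _size_mismatch(params, delta_c, lo) <= 0:
            raise ConvergenceError(
                f"no stationary intestine size found for delta_c={delta_c}"
            )
        N = float(brentq(lambda s: _size_mismatch(params, delta_c, s), lo, hi,
                         xtol=tol * N_max))

    # Scan for extra sign changes of g: a unique fixed point is assumed but
    # not proven, so additional candidates are an error, not a choice.
    grid = np.linspace(1e-6 * N_max, N_max, 512)
    g = np.array([_size_mismatch(params, delta_c, s) for s in grid])
    crossings = np.flatnonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)
    if crossings.size > 1:
        locs = ", ".join(f"[{grid[i]:.4g}, {grid[i + 1]:.4g}]" for i in crossings)
        raise ConvergenceError(
            f"multiple stationary sizes bracketed for delta_c={delta_c}: {locs}"
        )

    Nvec = stationary_classes(params, delta_c, N)
    residual = abs(Nvec.sum() - N) / N
    if delta_c / N > 1.0:
        raise InadmissibleExposureError(
            f"stationary state inadmissible: delta_c/N* = {delta_c / N:.4g} > 1 "
            f"(delta_c={delta_c}, N*={N:.6g})"
        )
    rhs = derivatives(Nvec, delta_c, params)
    if np.max(np.abs(rhs)) > ode_tol:
        raise ConvergenceError(
            f"stationary residual too large: max|dN/dt| = {np.max(np.abs(rhs)):.3g}"
        )
    return EquilibriumResult(params, delta_c, Nvec, iterations, residual)
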