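"""Derived quantities: body burden, cell loss, elimination rate, class mix.

All observables are simple functionals of a single state; trajectory-level
series are built by applying them pointwise (see
:meth:`tkcd.simulate.Trajectory.to_frame`).

The central quantity is the instantaneous elimination rate

.. math::

    k(N_1, \\ldots, N_l)
    = \\frac{\\sum_i N_i d_i (i-1)}{\\sum_i N_i (i-1)}
    = \\frac{\\sum_i q_i d_i (i-1)}{\\sum_i q_i (i-1)},
    \\qquad q_i = N_i / N,

the toxicant removed per unit time (cells dying, each taking its particles
with it) divided by the body burden.  It is a weighted mean of
``d_2 .. d_l`` — hence bounded by ``d_2`` and 1 — and depends only on the
class *fractions* ``q_i``, not on intestine size.  A classic one-compartment
model is the degenerate case where all contaminated mass sits in a single
class, making ``k`` the constant ``d_j``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .core import IntestineState, ModelParams, ValidationError

__all__ = [
    "ClassFractions",
    "total_toxicant",
    "percent_cell_loss",
    "removal_amount",
    "elimination_rate",
    "class_fractions",
    "peak_toxicant",
]


def _occupancies(state: IntestineState | ArrayLike) -> NDArray[np.float64]:
    if isinstance(state, IntestineState):
        return state.N
    return np.asarray(state, dtype=float)


@dataclass(frozen=True)
class ClassFractions:
    """Relative sizes of the contamination classes, ``q_i = N_i / N``."""

    q: NDArray[np.float64]

    def __post_init__(self) -> None:
        if abs(self.q.sum() - 1.0) > 1e-9 or np.any(self.q < 0):
            raise ValidationError("class fractions must be non-negative and sum to 1")


def total_toxicant(state: IntestineState | ArrayLike) -> float:
    """Body burden ``C_int = sum_i N_i (i - 1)``.

    Class ``i`` carries ``i - 1`` particles per cell, so the burden is the
    occupancy vector weighted by per-cell particle count.
    """
    N = _occupancies(state)
    return float(N @ np.arange(N.shape[0]))


def percent_cell_loss(
    state: IntestineState | ArrayLike, baseline: float
) -> float:
    """Percent of the baseline cell count lost: ``100 (1 - N / baseline)``.

    ``baseline`` is normally the uncontaminated steady state ``b / d_1``.
    """
    if baseline <= 0:
        raise ValidationError(f"baseline must be positive, got {baseline}")
    N = _occupancies(state)
    return 100.0 * (1.0 - N.sum() / baseline)


def removal_amount(
    state: IntestineState | ArrayLike, params: ModelParams
) -> float:
    """Toxicant removed per unit time: ``sum_i N_i d_i (i - 1)``.

    Each dying cell carries its particles out of the intestine.
    """
    N = _occupancies(state)
    return float((N * params.d) @ np.arange(N.shape[0]))


def elimination_rate(
    state: IntestineState | ArrayLike, params: ModelParams
) -> float | None:
    """Instantaneous elimination rate ``k`` = removal / body burden.

    Returns ``None`` when the intestine is uncontaminated (``C_int = 0``):
    the rate is then undefined, and serialisation writes it as a missing
    value, never as zero.
    """
    burden = total_toxicant(state)
    if burden == 0.0:
        return None
    return removal_amount(state, params) / burden


def class_fractions(state: IntestineState | ArrayLike) -> ClassFractions:
    """Normalised class occupancies ``q_i = N_i / N``."""
    N = _occupancies(state)
    total = N.sum()
    if total <= 0:
        raise ValidationError("cannot normalise an empty intestine")
    return ClassFractions(N / total)


def peak_toxicant(times: ArrayLike, c_int: ArrayLike) -> tuple[float, float]:
    """Time and value of the maximum body burden over stored points.

    Ties break to the earliest time; resolution equals the storage stride
    of the trajectory (no interpolation between stored points).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(c_int, dtype=float)
    if t.size == 0:
        raise ValidationError("empty trajectory")
    i = int(np.argmax(c))  # argmax returns the first maximal index
    return float(t[i]), float(c[i])
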