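"""State space and right-hand side of the contamination-class ODE system.

The intestine is modelled as a population of epithelial cells partitioned
into ``l`` contamination classes; a cell in class ``i`` carries ``i - 1``
toxic particles.  Per unit time, ``b`` fresh (class-1) cells are produced,
a cell in class ``i`` dies with hazard coefficient ``d_i``, and a surviving
cell absorbs one particle with probability ``delta_c / N`` — the toxicant
influx shared uniformly over the ``N`` cells present — moving it up one
class.  Death probabilities increase with contamination (``d_i < d_{i+1}``),
baseline turnover is positive (``d_1 > 0``) and the terminal class is lethal
(``d_l = 1``), which is what keeps cells cycling instead of accumulating
toxicant forever.

Rates are taken proportional to the per-step probabilities with the time
scale constant ``1/dt`` set to one, so all times are expressed in units of
the underlying demographic step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "ModelParams",
    "IntestineState",
    "ValidationError",
    "InadmissibleExposureError",
    "AdmissibilityWarning",
    "validate_params",
    "initial_state",
    "absorption_probability",
    "derivatives",
]


class ValidationError(ValueError):
    """A model parameter violates the demographic constraints."""


class InadmissibleExposureError(ValueError):
    """Toxicant influx exceeds one particle per cell (``delta_c / N > 1``)."""


class AdmissibilityWarning(UserWarning):
    """Emitted when an inadmissible absorption probability is clamped to 1."""


@dataclass(frozen=True)
class ModelParams:
    """Demographic parameters of the cell population.

    Parameters
    ----------
    b : float
        Number of new (uncontaminated) cells produced per unit time.
    d : array-like of float
        Death probabilities per contamination class, length ``l``.
        Must be strictly increasing with ``d[0] > 0`` and ``d[-1] == 1``.
    """

    b: float
    d: NDArray[np.float64] = field(repr=True)

    def __init__(self, b: float, d: ArrayLike) -> None:
        object.__setattr__(self, "b", float(b))
        object.__setattr__(
            self, "d", np.ascontiguousarray(np.asarray(d, dtype=float))
        )
        validate_params(self)

    @property
    def l(self) -> int:
        """Number of contamination classes."""
        return self.d.shape[0]

    @property
    def baseline_cells(self) -> float:
        """Uncontaminated steady-state intestine size ``b / d_1``."""
        return self.b / self.d[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelParams):
            return NotImplemented
        return self.b == other.b and np.array_equal(self.d, other.d)

    def __hash__(self) -> int:
        return hash((self.b, self.d.tobytes()))


@dataclass(frozen=True)
class IntestineState:
    """Snapshot of the cell population: time and per-class occupancies."""

    t: float
    N: NDArray[np.float64]

    def __init__(self, t: float, N: ArrayLike) -> None:
        arr = np.ascontiguousarray(np.asarray(N, dtype=float))
        if arr.ndim != 1:
            raise ValidationError("N must be a 1-D occupancy vector")
        if np.any(arr < 0):
            raise ValidationError("class occupancies must be non-negative")
        object.__setattr__(self, "t", float(t))
        object.__setattr__(self, "N", arr)

    @property
    def total(self) -> float:
        """Intestine size ``N = sum_i N_i``."""
        return float(self.N.sum())


def validate_params(params: ModelParams) -> ModelParams:
    """Check the demographic constraints on ``(b, d)``.

    Raises :class:`ValidationError` naming the violated constraint;
    returns ``params`` unchanged when everything holds.
    """
    d = params.d
    if d.ndim != 1 or d.shape[0] < 2:
        raise ValidationError(
            f"need at least 2 contamination classes, got d of shape {d.shape}"
        )
    if not np.all(np.isfinite(d)) or not np.isfinite(params.b):
        raise ValidationError("parameters must be finite")
    if params.b < 0:
        raise ValidationError(f"birth rate must be non-negative, got b={params.b}")
    if d[0] <= 0:
        raise ValidationError(f"baseline death probability must be positive, got d_1={d[0]}")
    if d[-1] != 1.0:
        raise ValidationError(f"terminal class must be lethal (d_l = 1), got d_l={d[-1]}")
    if np.any(np.diff(d) <= 0):
        i = int(np.flatnonzero(np.diff(d) <= 0)[0])
        raise ValidationError(
            f"death probabilities must be strictly increasing; d_{i + 1}={d[i]} "
            f">= d_{i + 2}={d[i + 1]}"
        )
    return params


def initial_state(params: ModelParams) -> IntestineState:
    """Steady state of the uncontaminated system: ``N_1 = b/d_1``, rest empty.

    With no toxicant influx the only class with traffic is class 1, whose
    balance ``b = d_1 N_1`` fixes the intestine size.
    """
    N = np.zeros(params.l)
    N[0] = params.b / params.d[0]
    return IntestineState(0.0, N)


def absorption_probability(
    delta_c: float, N: float, *, clamp: bool = False
) -> float:
    """Per-cell probability of absorbing a particle, ``delta_c / N``.

    The influx ``delta_c`` is split uniformly over the ``N`` cells present;
    a probability above one is not biologically meaningful.  By default an
    inadmissible ratio raises :class:`InadmissibleExposureError`; with
    ``clamp=True`` it is clamped to 1 and an :class:`AdmissibilityWarning`
    is emitted instead.
    """
    if delta_c < 0:
        raise ValidationError(f"toxicant influx must be non-negative, got {delta_c}")
    if N <= 0:
        raise InadmissibleExposureError(
            "intestine size must be positive (no cells left to absorb)"
        )
    p = delta_c / N
    if p > 1.0:
        if not clamp:
            raise InadmissibleExposureError(
                f"absorption probability delta_c/N = {p:.6g} exceeds 1 "
                f"(delta_c={delta_c:.6g}, N={N:.6g})"
            )
        warnings.warn(
            f"clamping absorption probability {p:.6g} to 1", AdmissibilityWarning,
            stacklevel=2,
        )
        p = 1.0
    return p


def derivatives(
    N: ArrayLike,
    delta_c: float,
    params: ModelParams,
    *,
    clamp: bool = False,
) -> NDArray[np.float64]:
    """Right-hand side of the contamination-class ODE system.

    With absorption probability ``x = delta_c / N``:

    .. math::

        \\dot N_1 &= b - (d_1 + (1 - d_1) x) N_1 \\\\
        \\dot N_i &= (1 - d_{i-1}) x N_{i-1} - (d_i + (1 - d_i) x) N_i \\\\
        \\dot N_l &= (1 - d_{l-1}) x N_{l-1} - N_l

    Each class loses cells to death and (except the terminal one) to
    promotion by absorption, and gains the promoted survivors of the class
    below; class 1 is fed by cell production ``b``.
    """
    Nv = np.asarray(N, dtype=float)
    d = params.d
    if Nv.shape != d.shape:
        raise ValidationError(
            f"occupancy vector has length {Nv.shape[0]}, expected {d.shape[0]}"
        )
    total = Nv.sum()
    if delta_c == 0.0:
        x = 0.0
    else:
        x = absorption_probability(delta_c, total, clamp=clamp)
    promoted = (1.0 - d[:-1]) * x * Nv[:-1]  # survivors moving up one class
    # d_l = 1 makes the terminal loss coefficient exactly 1, so the loss
    # term (d_i + (1 - d_i) x) N_i applies uniformly to every class.
    out = -(d + (1.0 - d) * x) * Nv
    out[0] += params.b
    out[1:] += promoted
    return out
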