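"""Concentration-to-mortality curves and toxic-unit scaling.

Toxicity enters the demographic model in one of three ways:

1. *Explicit mortality curve* — a monotone function mapping the per-cell
   particle count to a death probability, sampled at the class centres to
   give the vector ``d`` (one curve per substance).
2. *Toxic-unit equivalence* — substances assumed additive share a single
   ``d`` vector, and the influx is rescaled by a substance potency into an
   effective influx in toxic units (:func:`effective_influx`).
3. *Hybrid* — the influx is rescaled as in (2) **and** the substance brings
   its own curve as in (1); this needs no extra machinery, just compose
   :func:`effective_influx` with :func:`discretize_mortality` of the
   substance-specific curve.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ModelParams, ValidationError

__all__ = [
    "MortalityCurve",
    "PiecewiseLinearCurve",
    "SigmoidCurve",
    "TabulatedCurve",
    "ToxicUnitSpec",
    "discretize_mortality",
    "effective_influx",
]


class MortalityCurve(ABC):
    """Monotone map from per-cell particle count to death probability.

    The curve is evaluated on the particle counts ``0 .. l-1`` (class ``i``
    carries ``i - 1`` particles).  Valid curves are non-decreasing, positive
    at zero particles (baseline turnover) and reach 1 at the terminal count.
    """

    @abstractmethod
    def __call__(self, particles: np.ndarray) -> np.ndarray:
        """Death probability at the given per-cell particle counts."""


@dataclass(frozen=True)
class PiecewiseLinearCurve(MortalityCurve):
    """Linear interpolation between a baseline and full mortality.

    ``d0`` is the death probability of uncontaminated cells; mortality
    rises linearly to 1 at ``max_particles`` (typically ``l - 1``).
    """

    d0: float
    max_particles: float

    def __post_init__(self) -> None:
        if not 0 < self.d0 < 1:
            raise ValidationError(f"baseline mortality must be in (0, 1), got {self.d0}")
        if self.max_particles <= 0:
            raise ValidationError("max_particles must be positive")

    def __call__(self, particles: np.ndarray) -> np.ndarray:
        p = np.asarray(particles, dtype=float)
        return np.clip(self.d0 + (1.0 - self.d0) * p / self.max_particles, None, 1.0)


@dataclass(frozen=True)
class SigmoidCurve(MortalityCurve):
    """Saturating Hill-type dose response pinned to 1 at ``max_particles``.

    ``d(p) = d0 + (1 - d0) * s(p)/s(max)`` with ``s(p) = p^h / (ec50^h + p^h)``:
    a standard sigmoid in per-cell burden, renormalised so the terminal
    class is exactly lethal.  ``ec50`` is the half-effect burden, ``h`` the
    Hill steepness.
    """

    d0: float
    ec50: float
    hill: float
    max_particles: float

    def __post_init__(self) -> None:
        if not 0 < self.d0 < 1:
            raise ValidationError(f"baseline mortality must be in (0, 1), got {self.d0}")
        if self.ec50 <= 0 or self.hill <= 0 or self.max_particles <= 0:
            raise ValidationError("ec50, hill and max_particles must be positive")

    def __call__(self, particles: np.ndarray) -> np.ndarray:
        p = np.asarray(particles, dtype=float)
        s = p**self.hill / (self.ec50**self.hill + p**self.hill)
        smax = self.max_particles**self.hill / (
            self.ec50**self.hill + self.max_particles**self.hill
        )
        return self.d0 + (1.0 - self.d0) * s / smax


@dataclass(frozen=True)
class TabulatedCurve(MortalityCurve):
    """User-supplied table of (particle count, death probability) pairs.

    Intermediate counts are linearly interpolated, so the table may be
    coarser or finer than the class grid it will be sampled on.
    """

    particles: tuple[float, ...]
    values: tuple[float, ...]

    def __init__(self, particles: Sequence[float], values: Sequence[float]) -> None:
        p = tuple(float(v) for v in particles)
        d = tuple(float(v) for v in values)
        if len(p) != len(d) or len(p) < 2:
            raise ValidationError("need at least two (particles, d) pairs")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValidationError("particle counts must be strictly increasing")
        object.__setattr__(self, "particles", p)
        object.__setattr__(self, "values", d)

    def __call__(self, particles: np.ndarray) -> np.ndarray:
        p = np.asarray(particles, dtype=float)
        return np.interp(p, self.particles, self.values)


def discretize_mortality(
    curve: MortalityCurve,
    l: int,
    b: float = 0.0,
    *,
    pin_tolerance: float = 1e-6,
) -> np.ndarray:
    """Sample a mortality curve on the class grid to obtain ``d``.

    ``d_i = curve(i - 1)`` for ``i = 1 .. l``.  The terminal value is
    pinned to exactly 1 when within ``pin_tolerance`` of it (interpolation
    or renormalisation can miss by rounding); a larger discrepancy is an
    error, as is any non-monotone or non-positive sample.  The result
    passes :func:`tkcd.core.validate_params`.
    """
    if l < 2:
        raise ValidationError(f"need at least 2 contamination classes, got l={l}")
    d = np.asarray(curve(np.arange(l, dtype=float)), dtype=float)
    if d[0] <= 0:
        raise ValidationError(
            f"curve must give positive baseline mortality, got curve(0)={d[0]}"
        )
    if np.any(np.diff(d) <= 0):
        raise ValidationError("curve samples are not strictly increasing on the class grid")
    if abs(d[-1] - 1.0) > pin_tolerance:
        raise ValidationError(
            f"curve({l - 1})={d[-1]:.8g} is not 1 within tolerance {pin_tolerance}; "
            "the terminal contamination class must be lethal"
        )
    d[-1] = 1.0
    ModelParams(b, d)  # final validation of the assembled vector
    return d


@dataclass(frozen=True)
class ToxicUnitSpec:
    """Potency of a substance: toxic units per particle.

    Converts a particle influx into an effective influx on the shared
    toxic-unit scale, valid for substances whose effects combine additively.
    """

    potency: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.potency <= 0:
            raise ValidationError(f"potency must be positive, got {self.potency}")


def effective_influx(particle_influx: float, spec: ToxicUnitSpec) -> float:
    """Influx in toxic units: ``potency * particle_influx``."""
    if particle_influx < 0:
        raise ValidationError(f"influx must be non-negative, got {particle_influx}")
    return spec.potency * particle_influx
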