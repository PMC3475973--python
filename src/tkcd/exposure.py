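"""Piecewise-constant toxicant exposure schedules.

The influx ``delta_c(t)`` — particles (or toxic units) entering the gut per
unit time — is a step function: an ordered list of ``(start, level)``
segments up to a horizon.  Step changes are all that is needed to express
the classic exposure-then-depuration experiment (constant influx followed
by a switch to clean food).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

from .core import ValidationError

__all__ = ["ExposureSchedule"]


@dataclass(frozen=True)
class ExposureSchedule:
    """Step-function toxicant influx over ``[0, horizon]``.

    Segments use half-open intervals ``[start, next_start)``: at a
    breakpoint the new level applies.  A single segment is a constant
    exposure.
    """

    segments: tuple[tuple[float, float], ...]
    horizon: float

    def __init__(
        self, segments: Sequence[tuple[float, float]], horizon: float
    ) -> None:
        segs = tuple((float(t), float(lvl)) for t, lvl in segments)
        if not segs:
            raise ValidationError("schedule needs at least one segment")
        if segs[0][0] != 0.0:
            raise ValidationError(f"first segment must start at t=0, got {segs[0][0]}")
        starts = [t for t, _ in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValidationError("segment start times must be strictly increasing")
        if any(lvl < 0 for _, lvl in segs):
            raise ValidationError("influx levels must be non-negative")
        horizon = float(horizon)
        if horizon <= starts[-1]:
            raise ValidationError(
                f"horizon {horizon} must exceed the last segment start {starts[-1]}"
            )
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "horizon", horizon)

    @classmethod
    def constant(cls, level: float, horizon: float) -> "ExposureSchedule":
        """Constant influx at ``level`` over ``[0, horizon]``."""
        return cls([(0.0, level)], horizon)

    def delta_c_at(self, t: float) -> float:
        """Influx level of the segment whose interval contains ``t``."""
        if t < 0 or t > self.horizon:
            raise ValidationError(
                f"t={t} outside the schedule's range [0, {self.horizon}]"
            )
        starts = [s for s, _ in self.segments]
        return self.segments[bisect_right(starts, t) - 1][1]

    @property
    def breakpoints(self) -> tuple[float, ...]:
        """Interior segment boundaries (integration restart points)."""
        return tuple(t for t, _ in self.segments[1:])

    @property
    def is_constant(self) -> bool:
        return len(self.segments) == 1
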