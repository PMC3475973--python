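"""Run configuration: schema, loading, and output serialisation.

A run is fully described by a YAML or JSON document::

    mode: simulate            # simulate | equilibrium
    b: 10.0
    d: [0.1, 0.11, 0.2, 0.9, 1.0]   # or a mortality curve, see below
    delta_c: 1.0              # constant influx, or a schedule:
    # schedule: [{t: 0.0, delta_c: 34.0}, {t: 50.0, delta_c: 0.0}]
    horizon: 400.0
    solver: {method: rk4, dt: 0.01, store_stride: 10}

Death probabilities may instead be generated from a curve::

    curve: {form: linear, d0: 0.05, l: 5}
    curve: {form: sigmoid, d0: 0.1, ec50: 2.5, hill: 3.0, l: 5}
    curve: {form: table, particles: [0, 1, 2, 3, 4], values: [0.1, 0.11, 0.2, 0.9, 1.0]}

Outputs are a trajectory (or equilibrium-scan) CSV plus a JSON metadata
sidecar echoing every materialised parameter; the pipeline is fully
deterministic, so identical configs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .core import ModelParams
from .equilibrium import EquilibriumResult
from .exposure import ExposureSchedule
from .mortality import (
    PiecewiseLinearCurve,
    SigmoidCurve,
    TabulatedCurve,
    discretize_mortality,
)
from .simulate import SolverOptions, Trajectory

__all__ = ["RunConfig", "load_config", "write_outputs"]

# repr-style numeric format for CSV output: 12 significant digits
_CSV_FLOAT = "%.12g"


class CurveSpec(BaseModel):
    """Mortality-curve specification (alternative to an explicit ``d``)."""

    model_config = ConfigDict(extra="forbid")

    form: Literal["linear", "sigmoid", "table"]
    l: int | None = Field(default=None, ge=2)
    d0: float | None = None
    ec50: float | None = None
    hill: float | None = None
    particles: list[float] | None = None
    values: list[float] | None = None

    def build(self, l: int) -> list[float]:
        if self.form == "linear":
            curve = PiecewiseLinearCurve(d0=self.d0, max_particles=l - 1)
        elif self.form == "sigmoid":
            curve = SigmoidCurve(
                d0=self.d0, ec50=self.ec50, hill=self.hill, max_particles=l - 1
            )
        else:
            if self.particles is None or self.values is None:
                raise ValueError("table curve needs 'particles' and 'values'")
            curve = TabulatedCurve(self.particles, self.values)
        return list(discretize_mortality(curve, l))


class SolverSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    method: Literal["rk4", "adaptive"] = "rk4"
    dt: float = Field(default=0.01, gt=0)
    store_stride: int = Field(default=1, ge=1)
    equilibrium_eps: float = Field(default=1e-9, gt=0)
    rtol: float = Field(default=1e-10, gt=0)
    atol: float = Field(default=1e-12, gt=0)
    clamp_absorption: bool = False

    def build(self) -> SolverOptions:
        return SolverOptions(**self.model_dump())


class ScheduleEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    t: float = Field(ge=0)
    delta_c: float = Field(ge=0)


class RunConfig(BaseModel):
    """Validated, fully materialised description of one run."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["simulate", "equilibrium"] = "simulate"
    b: float = Field(ge=0)
    l: int | None = Field(default=None, ge=2)
    d: list[float] | None = None
    curve: CurveSpec | None = None
    delta_c: float | None = Field(default=None, ge=0)
    schedule: list[ScheduleEntry] | None = None
    horizon: float = Field(default=200.0, gt=0)
    solver: SolverSpec = Field(default_factory=SolverSpec)

    @model_validator(mode="after")
    def _materialise(self) -> "RunConfig":
        if (self.d is None) == (self.curve is None):
            raise ValueError("specify exactly one of 'd' or 'curve'")
        if self.d is not None:
            if self.l is not None and self.l != len(self.d):
                raise ValueError(
                    f"d has length {len(self.d)} but l={self.l} was declared"
                )
            self.l = len(self.d)
        else:
            l = self.l or self.curve.l
            if l is None:
                raise ValueError("curve-based configs must give 'l' (class count)")
            self.l = l
            self.d = self.curve.build(l)
        ModelParams(self.b, self.d)  # demographic invariants
        if (self.delta_c is None) == (self.schedule is None):
            raise ValueError("specify exactly one of 'delta_c' or 'schedule'")
        self.build_schedule()  # surfaces schedule errors at load time
        return self

    def build_params(self) -> ModelParams:
        return ModelParams(self.b, self.d)

    def build_schedule(self) -> ExposureSchedule:
        if self.delta_c is not None:
            return ExposureSchedule.constant(self.delta_c, self.horizon)
        return ExposureSchedule(
            [(e.t, e.delta_c) for e in self.schedule], self.horizon
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    raw: Any = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return RunConfig.model_validate(raw)


def _metadata(config: RunConfig, extra: dict[str, Any]) -> dict[str, Any]:
    return {
        "tool": "tkcd",
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        **extra,
    }


def write_outputs(
    result: Trajectory | EquilibriumResult | pd.DataFrame,
    config: RunConfig,
    csv_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Write the result CSV and its JSON metadata sidecar.

    Undefined elimination rates (zero body burden) appear as empty CSV
    fields, never as zeros.  The metadata echoes the full materialised
    configuration together with the admissibility and equilibration flags,
    so a run can be reproduced exactly from its sidecar.
    """
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".meta.json")
    if isinstance(result, Trajectory):
        frame = result.to_frame()
        extra: dict[str, Any] = {
            "equilibrated": result.equilibrated,
            "admissible": result.admissible,
            "max_absorption_probability": result.max_absorption,
        }
    elif isinstance(result, EquilibriumResult):
        frame = equilibrium_frame([result])
        extra = {"iterations": result.iterations, "residual": result.residual}
    else:
        frame = result
        extra = {}
    frame.to_csv(csv_path, index=False, float_format=_CSV_FLOAT, na_rep="")
    Path(meta_path).write_text(
        json.dumps(_metadata(config, extra), indent=2, sort_keys=True) + "\n"
    )


def equilibrium_frame(results: list[EquilibriumResult]) -> pd.DataFrame:
    """Tabulate equilibrium results, one row per influx level."""
    rows = []
    for r in results:
        row: dict[str, Any] = {"delta_c": r.delta_c}
        for i, n in enumerate(r.N):
            row[f"N_{i + 1}"] = n
        row.update(
            N_total=r.total,
            C_int=r.c_int,
            loss_pct=r.percent_loss,
            k=r.elimination_rate,
        )
        rows.append(row)
    return pd.DataFrame(rows)
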