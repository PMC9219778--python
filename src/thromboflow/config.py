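"""Versioned JSON run configuration.

A run is fully described by one JSON document: geometry (a built-in fixture
or an imported field), model parameters, thresholds, numerical controls and
output options.  Unknown keys are rejected with an error naming the key, and
the resolved configuration is re-serialized into every output directory so a
finished run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .closures import ModelParameters, Thresholds
from .errors import InvalidInputError
from .fixtures import FixtureSpec

__all__ = ["RunConfig", "load_config", "config_errors"]


class GeometryConfig(BaseModel):
    """Either a built-in fixture kind (+ knob overrides) or an import path."""

    model_config = ConfigDict(extra="forbid")

    kind: str | None = None
    knobs: dict[str, float] = {}
    import_path: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "GeometryConfig":
        if (self.kind is None) == (self.import_path is None):
            raise ValueError("specify exactly one of 'kind' or 'import_path'")
        if self.kind is not None:
            try:
                self.to_fixture_spec()  # validates kind, knob names, ranges
            except TypeError as e:
                raise ValueError(f"unknown geometry knob: {e}") from None
        return self

    def to_fixture_spec(self) -> FixtureSpec:
        return FixtureSpec(kind=self.kind, **self.knobs)


class ControlsConfig(BaseModel):
    """Numerical controls (see species_transport.TransportControls)."""

    model_config = ConfigDict(extra="forbid")

    dt: float | None = None
    horizon: float = 30.0
    steady_tol: float = 1e-4
    feedback: bool = False
    feedback_interval: int = 100
    scheme: str = "implicit"
    cfs_advection: bool = True
    cf_release: str = "activation"
    tc_gate: str = "tcs"
    ap_frac0: float = 1.0
    crossing_depth: int = 3
    flow_tol: float = 1e-6
    flow_max_iter: int = 200
    sink_form: str = "brinkman"
    check_every: int = 5

    @model_validator(mode="after")
    def _check(self) -> "ControlsConfig":
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.scheme not in ("implicit", "explicit"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.cf_release not in ("activation", "aps_rate"):
            raise ValueError(f"unknown cf_release {self.cf_release!r}")
        if self.tc_gate not in ("tcs", "unity", "ap_fraction"):
            raise ValueError(f"unknown tc_gate {self.tc_gate!r}")
        if self.sink_form not in ("brinkman", "constant"):
            raise ValueError(f"unknown sink_form {self.sink_form!r}")
        return self


class OutputsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    directory: str = "thromboflow_out"
    snapshot_every: int = 0  # 0: only the final fields


class RunConfig(BaseModel):
    """Top-level run description; the schema_version guards forward drift."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    geometry: GeometryConfig
    model: ModelParameters = ModelParameters()
    thresholds: Thresholds = Thresholds()
    controls: ControlsConfig = ControlsConfig()
    outputs: OutputsConfig = OutputsConfig()

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.schema_version != 1:
            raise ValueError(
                f"unsupported schema_version {self.schema_version}; expected 1"
            )
        return self

    def resolved_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)


def load_config(path) -> RunConfig:
    """Parse and validate a JSON run configuration.

    Raises :class:`InvalidInputError` with field-level messages on any
    defect, including unknown keys.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except OSError as e:
        raise InvalidInputError(f"cannot read config {path}: {e}") from None
    except json.JSONDecodeError as e:
        raise InvalidInputError(f"{path} is not valid JSON: {e}") from None
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in e.errors()
        ]
        raise InvalidInputError(
            f"invalid configuration {path}:\n" + "\n".join(lines)
        ) from None


def config_errors(path) -> list[str]:
    """Validation errors of a config file; empty when it is valid."""
    try:
        load_config(path)
    except InvalidInputError as e:
        return str(e).splitlines()
    return []
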