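"""Run configuration: YAML/JSON parsing with strict validation.

A run config has a ``model`` block (rate constants, dose, horizon, solver
tolerances), optional ``zonation`` and ``doseresponse`` blocks, plus a seed
and log level.  Unknown keys anywhere are rejected, and validation failures
are collected into a single itemized :class:`ConfigError` so a user fixes a
bad config in one pass.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .kinetics import InitialCondition, RateConstants
from .zonation import FlowConditions, KroghGeometry, ParameterMapping

__all__ = [
    "ConfigError",
    "ModelConfig",
    "ZonationConfig",
    "DoseResponseConfig",
    "RunConfig",
    "load_config",
    "write_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Config validation failure carrying an itemized error list."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelConfig(_Strict):
    """Cell-model block: the ten rate constants, dose, horizon, solver knobs."""

    k_sul: float = Field(default=0.2, ge=0)
    k_gluc: float = Field(default=0.4, ge=0)
    k_450: float = Field(default=0.3, ge=0)
    k_rev: float = Field(default=0.02, ge=0)
    k_GSH: float = Field(default=10.0, ge=0)
    k_PSH: float = Field(default=0.1, ge=0)
    beta_S: float = Field(default=0.05, ge=0)
    delta_S: float = Field(default=0.1, gt=0)
    beta_G: float = Field(default=0.5, ge=0)
    delta_G: float = Field(default=0.1, gt=0)
    delta_T: float = Field(default=0.0, ge=0)
    P0: float = Field(default=10.0, ge=0, description="initial APAP dose, mM")
    t_end: float = Field(default=24.0, gt=0, description="horizon, h")
    n_output: int = Field(default=201, ge=2)
    rtol: float = Field(default=1e-8, gt=0)
    atol: float = Field(default=1e-10, gt=0)

    def rate_constants(self) -> RateConstants:
        names = RateConstants().as_dict().keys()
        return RateConstants(**{n: getattr(self, n) for n in names})

    def initial_condition(self) -> InitialCondition:
        return InitialCondition(P0=self.P0)


class ZonationConfig(_Strict):
    """Zonation block: Krogh geometry, flow/uptake, mapping ranges, zoning."""

    L: float = Field(default=20.0, gt=0)
    R_l: float = Field(default=0.1, gt=0)
    R_m: float = Field(default=0.02, gt=0)
    R_e: float = Field(default=0.1, gt=0)
    Q: float = Field(default=400.0, gt=0)
    c_in: float = Field(default=0.2, gt=0)
    uptake_vmax: float = Field(default=25.0, ge=0)
    uptake_km: float = Field(default=0.01, ge=0)
    k450_min: float = Field(default=0.15, ge=0)
    k450_max: float = Field(default=0.45, ge=0)
    betaG_min: float = Field(default=0.25, ge=0)
    betaG_max: float = Field(default=0.5, ge=0)
    n_zones: int = Field(default=24, ge=2)
    pattern_threshold: float | None = Field(
        default=None, ge=0,
        description="terminal-T injury threshold (mM); default = 80% of the per-run range",
    )

    @model_validator(mode="after")
    def _ranges_ordered(self) -> "ZonationConfig":
        if self.k450_min > self.k450_max:
            raise ValueError("k450_min must be <= k450_max")
        if self.betaG_min > self.betaG_max:
            raise ValueError("betaG_min must be <= betaG_max")
        return self

    def geometry(self) -> KroghGeometry:
        return KroghGeometry(L=self.L, R_l=self.R_l, R_m=self.R_m, R_e=self.R_e)

    def flow(self) -> FlowConditions:
        return FlowConditions(Q=self.Q, c_in=self.c_in,
                              uptake_vmax=self.uptake_vmax, uptake_km=self.uptake_km)

    def mapping(self, P0: float) -> ParameterMapping:
        return ParameterMapping(k450_min=self.k450_min, k450_max=self.k450_max,
                                betaG_min=self.betaG_min, betaG_max=self.betaG_max, P0=P0)


class DoseResponseConfig(_Strict):
    """Dose-response block: dose grid, damage metric, survival Hill transform."""

    dose_min: float = Field(default=0.5, gt=0)
    dose_max: float = Field(default=50.0, gt=0)
    n_doses: int = Field(default=12, ge=4)
    metric: str = Field(default="terminal_T")
    survival_ec50: float = Field(default=1.0, gt=0, description="damage at half-survival, mM")
    survival_hill_n: float = Field(default=2.0, gt=0)

    @model_validator(mode="after")
    def _checks(self) -> "DoseResponseConfig":
        from .doseresponse import DAMAGE_METRICS

        if self.metric not in DAMAGE_METRICS:
            raise ValueError(f"metric must be one of {DAMAGE_METRICS}, got {self.metric!r}")
        if self.dose_min >= self.dose_max:
            raise ValueError("dose_min must be < dose_max")
        return self


class RunConfig(_Strict):
    """Top-level run configuration."""

    model: ModelConfig = Field(default_factory=ModelConfig)
    zonation: ZonationConfig | None = None
    doseresponse: DoseResponseConfig | None = None
    seed: int = Field(default=0, ge=0)
    log_level: str = Field(default="INFO")


def _format_errors(exc: ValidationError) -> list[str]:
    out = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        out.append(f"{loc}: {err['msg']}")
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run config.

    Raises :class:`ConfigError` with one line per problem: unknown keys,
    out-of-range rates, malformed blocks.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"could not parse {path}: {exc}"]) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError([f"top level of {path} must be a mapping"])
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from exc


def write_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a run config back to YAML (round-trips through load_config)."""
    payload = config.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable content hash of a config, for provenance headers."""
    payload = json.dumps(config.model_dump(exclude_none=True), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
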