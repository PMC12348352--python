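"""Run configuration: a validated TOML/JSON schema for the whole pipeline.

Unknown keys are rejected (typos surface as errors naming the key), and the
resolved model round-trips to a dict whose hash is embedded in every output
sidecar.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, ValidationError

from .landscape import E_MAX, FieldSpec
from .sampler import SamplerConfig
from .string_fts import FTSConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FieldSettings(_Strict):
    axis: str = "x"
    sign: int = 1
    strength: float = 0.0

    def build(self) -> FieldSpec | None:
        if self.strength == 0.0:
            return None
        return FieldSpec(axis=self.axis, sign=self.sign, strength=self.strength)


class LandscapeSettings(_Strict):
    transverse_stiffness: float = 0.02          # kJ/mol/deg^2
    max_field_barrier_shift: float = 4.8        # kJ/mol at E_MAX
    n_nodes: int = 4001

    @property
    def field_coupling(self) -> float:
        return self.max_field_barrier_shift / E_MAX


class SamplerSettings(_Strict):
    time_step: float = 5e-4
    mobility: float = 1.0
    temperature: float = 298.15
    n_steps: int = 25000
    burn_in_fraction: float = 0.2
    spring: float = 100.0

    def build(self, seed: int = 0) -> SamplerConfig:
        return SamplerConfig(time_step=self.time_step, mobility=self.mobility,
                             temperature=self.temperature, n_steps=self.n_steps,
                             burn_in_fraction=self.burn_in_fraction,
                             seed=seed, spring=self.spring)


class FTSSettings(_Strict):
    n_images: int = 20
    max_iterations: int = 100
    string_step: float = 20.0
    max_displacement: float = 3.0
    smoothing_lambda: float = 0.1
    convergence_tol: float = 0.3
    convergence_window: int = 5
    tensor_mode: str = "identity"
    force_mode: str = "sampled"

    def build(self, sampler: SamplerConfig) -> FTSConfig:
        return FTSConfig(n_images=self.n_images,
                         max_iterations=self.max_iterations,
                         string_step=self.string_step,
                         max_displacement=self.max_displacement,
                         smoothing_lambda=self.smoothing_lambda,
                         convergence_tol=self.convergence_tol,
                         convergence_window=self.convergence_window,
                         sampler=sampler, tensor_mode=self.tensor_mode,
                         force_mode=self.force_mode)


class RunConfig(_Strict):
    master_seed: int = 1
    field: FieldSettings = FieldSettings()
    landscape: LandscapeSettings = LandscapeSettings()
    sampler: SamplerSettings = SamplerSettings()
    fts: FTSSettings = FTSSettings()
    output: str = "out"
    verbosity: str = "info"

    def as_dict(self) -> dict:
        return self.model_dump()


def load_config(path: str | Path | None) -> RunConfig:
    """Load TOML (or JSON) configuration; defaults when path is None."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        raw = tomllib.loads(path.read_text())
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(loc) for loc in first["loc"])
        raise ConfigError(f"invalid config key '{key}': {first['msg']}") from exc
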