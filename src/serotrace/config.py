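"""Run configurations: model registry, YAML loading and execution.

A run is a shareable artifact: a YAML file naming the registered models,
pointing at the input tables (demography, biomarker map, FOE grid, kinetics
parameters, observation design) and carrying the assay characteristics and
any model-specific extra arguments.  ``load_config`` validates everything up
front with field-level messages; ``run_from_config`` assembles the inputs
and calls the engine.

Custom models plug in through the registries: ``register_model("immunity",
"my_model")`` adds a named callable with the documented signature, after
which configs may reference it by name.
"""

from __future__ import annotations

import inspect
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import antibody, exposure, immunity, observation
from .antibody import ModelPars
from .biomarker_map import BiomarkerMap, reformat_biomarker_map
from .demography import Demography, generate_pop_demography
from .engine import _ASSAY_KEYS, _ENGINE_KEYS, SimulationOutputs, runserosim
from .errors import ConfigurationError
from .exposure import FOEGrid
from .observation import AssaySpec

# -- model registries ------------------------------------------------------

EXPOSURE_MODELS = {
    "simple_foe": exposure.exposure_model_simple_FOE,
    "dem_mod": exposure.exposure_model_dem_mod,
}
IMMUNITY_MODELS = {
    "all_successful": immunity.immunity_model_all_successful,
    "vacc_ifxn_simple": immunity.immunity_model_vacc_ifxn_simple,
    "biomarker_protection": immunity.immunity_model_biomarker_protection,
}
ANTIBODY_MODELS = {
    "monophasic": antibody.antibody_model_monophasic,
    "biphasic": antibody.antibody_model_biphasic,
}
OBSERVATION_MODELS = {
    "continuous_noise": observation.observation_model_continuous_noise,
    "discrete_noise": observation.observation_model_discrete_noise,
}
DRAW_PARAMETERS = {
    "fixed_fx": antibody.draw_parameters_fixed_fx,
    "random_fx": antibody.draw_parameters_random_fx,
}

_REGISTRIES = {
    "exposure": EXPOSURE_MODELS,
    "immunity": IMMUNITY_MODELS,
    "antibody": ANTIBODY_MODELS,
    "observation": OBSERVATION_MODELS,
    "draw_parameters": DRAW_PARAMETERS,
}


def register_model(kind: str, name: str):
    """Decorator registering a user-written model under ``name``."""
    if kind not in _REGISTRIES:
        raise ConfigurationError(f"unknown model kind {kind!r}")

    def decorator(func):
        _REGISTRIES[kind][name] = func
        return func

    return decorator


# -- config schema ---------------------------------------------------------

class SimulationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_start: int = 1
    t_end: int


class DemographySpec(BaseModel):
    """Either a file reference or generation instructions."""
    model_config = ConfigDict(extra="forbid")
    file: Optional[str] = None
    n_individuals: Optional[int] = None
    prob_removal: float = 0.0

    @field_validator("prob_removal")
    @classmethod
    def _prob(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError("prob_removal must be in [0, 1]")
        return v


class ModelChoices(BaseModel):
    model_config = ConfigDict(extra="forbid")
    exposure: str = "simple_foe"
    immunity: str = "all_successful"
    antibody: str = "monophasic"
    observation: str = "continuous_noise"
    draw_parameters: str = "random_fx"


class AssayConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    noise_sd: Optional[float] = None   # None -> obs_sd row of model_pars
    sensitivity: float = 1.0
    specificity: float = 1.0
    lower_bound: Optional[float] = None
    upper_bound: Optional[float] = None
    output: str = "continuous"


class RunConfig(BaseModel):
    """Fully validated run configuration."""
    model_config = ConfigDict(extra="forbid")

    simulation: SimulationSettings
    seed: int = 0
    demography: DemographySpec
    biomarker_map: str
    foe: str
    model_pars: str
    models: ModelChoices = Field(default_factory=ModelChoices)
    model_args: dict = Field(default_factory=dict)
    assay: AssayConfig = Field(default_factory=AssayConfig)
    observation_design: Optional[str] = None
    base_dir: Optional[str] = None  # resolved at load time

    def resolve_path(self, ref: str) -> Path:
        p = Path(ref)
        if not p.is_absolute() and self.base_dir:
            p = Path(self.base_dir) / p
        return p

    def registered_models(self) -> dict:
        out = {}
        for kind, registry in _REGISTRIES.items():
            name = getattr(self.models, kind)
            if name not in registry:
                raise ConfigurationError(
                    f"models.{kind}: unknown model {name!r} "
                    f"(registered: {sorted(registry)})")
            out[kind] = registry[name]
        return out


def _validate_model_args(cfg: RunConfig) -> None:
    models = cfg.registered_models()
    stages = [models["exposure"], models["immunity"], models["antibody"],
              models["draw_parameters"]]
    for key in cfg.model_args:
        if key in _ENGINE_KEYS or key in _ASSAY_KEYS:
            continue
        consumers = [m for m in stages
                     if key in inspect.signature(m).parameters]
        if len(consumers) != 1:
            raise ConfigurationError(
                f"model_args.{key}: must be consumed by exactly one "
                f"registered model, matched {len(consumers)}")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    raw.setdefault("base_dir", str(path.parent))
    try:
        cfg = RunConfig(**raw)
    except Exception as exc:  # pydantic ValidationError carries field paths
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc
    cfg.registered_models()
    _validate_model_args(cfg)
    if cfg.demography.file is None and cfg.demography.n_individuals is None:
        raise ConfigurationError(
            "demography: provide either 'file' or 'n_individuals'")
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    data = cfg.model_dump(exclude_none=True)
    data.pop("base_dir", None)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def run_from_config(cfg: RunConfig, seed: int | None = None) -> SimulationOutputs:
    """Assemble all inputs referenced by ``cfg`` and run the simulation."""
    models = cfg.registered_models()
    run_seed = cfg.seed if seed is None else seed
    dem_seed, engine_seed = (
        np.random.SeedSequence(run_seed).generate_state(2)
        % np.uint32(2 ** 31)).astype(int)

    t_start, t_end = cfg.simulation.t_start, cfg.simulation.t_end
    if cfg.demography.file:
        demography = Demography.from_csv(cfg.resolve_path(cfg.demography.file))
    else:
        demography = generate_pop_demography(
            cfg.demography.n_individuals,
            range(t_start, t_end + 1),
            prob_removal=cfg.demography.prob_removal,
            rng_seed=int(dem_seed),
        )

    raw_map = BiomarkerMap.from_csv(cfg.resolve_path(cfg.biomarker_map))
    numeric_map, exp_lookup, bio_lookup = reformat_biomarker_map(raw_map)
    model_pars = ModelPars.from_csv(cfg.resolve_path(cfg.model_pars))
    model_pars = model_pars.with_numeric_ids(exp_lookup, bio_lookup)
    foe = FOEGrid.from_csv(cfg.resolve_path(cfg.foe))

    design = None
    if cfg.observation_design:
        import pandas as pd
        design = pd.read_csv(cfg.resolve_path(cfg.observation_design))

    noise_sd = cfg.assay.noise_sd
    if noise_sd is None:
        noise_sd = model_pars.obs_sd() or 0.0
    assay = AssaySpec(
        noise_sd=noise_sd,
        sensitivity=cfg.assay.sensitivity,
        specificity=cfg.assay.specificity,
        lower_bound=cfg.assay.lower_bound,
        upper_bound=cfg.assay.upper_bound,
        output=cfg.assay.output,
    )

    return runserosim(
        settings=(t_start, t_end),
        demography=demography,
        biomarker_map=numeric_map,
        foe=foe,
        model_pars=model_pars,
        exposure_model=models["exposure"],
        immunity_model=models["immunity"],
        antibody_model=models["antibody"],
        observation_model=models["observation"],
        draw_parameters=models["draw_parameters"],
        observation_design=design,
        model_extra_args=_normalize_keys(cfg.model_args),
        rng_seed=int(engine_seed),
        assay=assay,
    )


def _normalize_keys(model_args: dict) -> dict:
    """YAML mapping keys for per-exposure-type params may parse as strings."""
    out = {}
    for key, value in model_args.items():
        if isinstance(value, dict):
            value = {int(k) if isinstance(k, str) and k.isdigit() else k: v
                     for k, v in value.items()}
        out[key] = value
    return out
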