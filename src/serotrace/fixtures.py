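"""Ready-made example inputs: the quickstart serosurvey scenario.

The quickstart emulates a ten-year (120 monthly time steps) single-pathogen
system observed with an IgG assay: 100 individuals with uniform random birth
months and no removal, one natural-infection exposure type (constant monthly
FOE 0.01) and one vaccination exposure type (constant monthly FOE 0.1), both
boosting the same biomarker.  Each individual can be infected at most once
and vaccinated at most once, with vaccine eligibility from nine months of
age.  Kinetics are monophasic boosting-waning with log-normal random
effects; the assay is continuous with noise sd 0.25, sensitivity 85%,
specificity 90% and an observable range of 0-10 titer units; all individuals
are sampled once at the final month for the single biomarker.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .antibody import ModelPars
from .biomarker_map import BiomarkerMap
from .demography import generate_pop_demography
from .exposure import FOEGrid

QUICKSTART_T_START = 1
QUICKSTART_T_END = 120
QUICKSTART_N = 100
QUICKSTART_FOE = {"ifxn": 0.01, "vacc": 0.1}

#: monophasic boosting-waning hyperparameters (natural scale)
QUICKSTART_MODEL_PARS = pd.DataFrame(
    [
        ("ifxn", "IgG", "boost", 4.0, 2.0, "log-normal"),
        ("ifxn", "IgG", "wane", 0.0033, 0.0005, "log-normal"),
        ("vacc", "IgG", "boost", 2.0, 1.0, "log-normal"),
        ("vacc", "IgG", "wane", 0.0016, 0.0005, "log-normal"),
        (None, None, "obs_sd", 0.25, None, None),
    ],
    columns=["exposure_id", "biomarker_id", "name", "mean", "sd",
             "distribution"],
)

QUICKSTART_ASSAY = {
    "noise_sd": 0.25,
    "sensitivity": 0.85,
    "specificity": 0.9,
    "lower_bound": 0.0,
    "upper_bound": 10.0,
}

QUICKSTART_MODEL_ARGS = {
    "max_events": {1: 1, 2: 1},
    "vacc_exposures": [2],
    "vacc_age": {2: 9},
}


def quickstart_biomarker_map(labels: bool = False) -> BiomarkerMap:
    """Two exposure types (infection, vaccination) boosting one biomarker."""
    if labels:
        return BiomarkerMap(pd.DataFrame({
            "exposure_id": ["ifxn", "vacc"], "biomarker_id": ["IgG", "IgG"]}))
    return BiomarkerMap(pd.DataFrame({
        "exposure_id": [1, 2], "biomarker_id": [1, 1]}))


def quickstart_inputs(rng_seed: int = 1) -> dict:
    """In-memory quickstart inputs, keyed by runserosim argument name."""
    times = range(QUICKSTART_T_START, QUICKSTART_T_END + 1)
    demography = generate_pop_demography(
        QUICKSTART_N, times, prob_removal=0.0, rng_seed=rng_seed)
    foe = FOEGrid.constant(
        [QUICKSTART_FOE["ifxn"], QUICKSTART_FOE["vacc"]],
        t_start=QUICKSTART_T_START, t_end=QUICKSTART_T_END)
    design = pd.DataFrame({
        "i": np.arange(1, QUICKSTART_N + 1),
        "t": QUICKSTART_T_END,
        "b": 1,
    })
    return {
        "settings": (QUICKSTART_T_START, QUICKSTART_T_END),
        "demography": demography,
        "biomarker_map": quickstart_biomarker_map(),
        "foe": foe,
        "model_pars": ModelPars(
            QUICKSTART_MODEL_PARS.assign(
                exposure_id=[1, 1, 2, 2, None],
                biomarker_id=[1, 1, 1, 1, None])),
        "observation_design": design,
        "model_extra_args": dict(QUICKSTART_MODEL_ARGS),
        "assay_kwargs": dict(QUICKSTART_ASSAY),
    }


def run_quickstart(rng_seed: int = 1):
    """Run the quickstart simulation end to end with one seed."""
    from .config import (ANTIBODY_MODELS, DRAW_PARAMETERS, EXPOSURE_MODELS,
                         IMMUNITY_MODELS, OBSERVATION_MODELS)
    from .engine import runserosim
    from .observation import AssaySpec

    inputs = quickstart_inputs(rng_seed=rng_seed)
    assay = AssaySpec(**inputs.pop("assay_kwargs"))
    return runserosim(
        exposure_model=EXPOSURE_MODELS["simple_foe"],
        immunity_model=IMMUNITY_MODELS["vacc_ifxn_simple"],
        antibody_model=ANTIBODY_MODELS["monophasic"],
        observation_model=OBSERVATION_MODELS["continuous_noise"],
        draw_parameters=DRAW_PARAMETERS["random_fx"],
        rng_seed=rng_seed,
        assay=assay,
        **inputs,
    )


def make_quickstart_fixture(out_dir, rng_seed: int = 1) -> dict[str, Path]:
    """Write the quickstart input files plus a config referencing them.

    Returns a dict of the paths written.  Two calls with the same seed
    produce identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv"
             for name in ("demography", "biomarker_map", "foe", "model_pars",
                          "observation_design")}
    paths["config"] = out / "config.yaml"

    times = range(QUICKSTART_T_START, QUICKSTART_T_END + 1)
    demography = generate_pop_demography(
        QUICKSTART_N, times, prob_removal=0.0, rng_seed=rng_seed)
    demography.to_csv(paths["demography"])

    quickstart_biomarker_map(labels=True).to_csv(paths["biomarker_map"])
    QUICKSTART_MODEL_PARS.to_csv(paths["model_pars"], index=False)

    FOEGrid.constant(
        [QUICKSTART_FOE["ifxn"], QUICKSTART_FOE["vacc"]],
        t_start=QUICKSTART_T_START, t_end=QUICKSTART_T_END,
    ).to_csv(paths["foe"])

    pd.DataFrame({
        "i": np.arange(1, QUICKSTART_N + 1),
        "t": QUICKSTART_T_END,
        "b": 1,
    }).to_csv(paths["observation_design"], index=False)

    config = {
        "simulation": {"t_start": QUICKSTART_T_START,
                       "t_end": QUICKSTART_T_END},
        "seed": rng_seed,
        "demography": {"file": "demography.csv"},
        "biomarker_map": "biomarker_map.csv",
        "foe": "foe.csv",
        "model_pars": "model_pars.csv",
        "observation_design": "observation_design.csv",
        "models": {
            "exposure": "simple_foe",
            "immunity": "vacc_ifxn_simple",
            "antibody": "monophasic",
            "observation": "continuous_noise",
            "draw_parameters": "random_fx",
        },
        "model_args": {
            "max_events": {1: 1, 2: 1},
            "vacc_exposures": [2],
            "vacc_age": {2: 9},
        },
        "assay": dict(QUICKSTART_ASSAY),
    }
    import yaml
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return paths
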