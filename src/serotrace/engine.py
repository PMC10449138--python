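"""Simulation engine: orchestrates exposure, immunity, kinetics, observation.

For every time step ``t`` (outer loop), individual ``i`` (ascending), and
exposure type ``x`` (ascending), the engine computes the probability of
exposure ``p_e`` from the exposure model and the conditional success
probability ``p_s`` from the immunity model, stores their product
``phi = p_e * p_s``, and draws the latent success state
``Z ~ Bernoulli(phi)``.  Drawing Z from phi directly is distributionally
identical to drawing the exposure indicator first and the success indicator
conditionally — the raw exposure indicator is never materialized.

Cells covered by a user-supplied fixed immune history take their value
verbatim; no model runs for them, their phi is recorded as absent and a
``fixed`` flag is raised.  On every success, per-event kinetics parameters
are drawn and stored; after the event loop the latent biomarker quantities
``A_{i,t,b}`` are evaluated with the antibody model, and finally the
observation design and model produce the observed quantities ``Y``.

A single sequential random stream (seeded by ``rng_seed``) drives the whole
run, so identical seeds and configurations reproduce outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from collections.abc import Mapping
from dataclasses import dataclass, field
import inspect

import numpy as np
import pandas as pd

from .__about__ import __version__
from .antibody import KineticsDraws, ModelPars, apply_titer_ceiling
from .biomarker_map import BiomarkerMap, reformat_biomarker_map
from .demography import Demography
from .errors import ConfigurationError, InvalidInputError
from .exposure import FOEGrid
from .immunity import ImmunityContext
from .observation import AssaySpec, apply_observation_design

#: model_extra_args keys consumed by the engine itself
_ENGINE_KEYS = {"titer_ceiling_gradient"}
#: model_extra_args keys consumed by the observation stage (assay spec)
_ASSAY_KEYS = {"noise_sd", "sensitivity", "specificity",
               "lower_bound", "upper_bound", "assay_output"}


@dataclass(frozen=True)
class BiomarkerStates:
    """Latent biomarker quantities A on an (i, t, b) grid; NaN = absent."""

    values: np.ndarray
    t_start: int = 1

    def to_long(self) -> pd.DataFrame:
        n, n_times, n_bio = self.values.shape
        i, t, b = np.meshgrid(np.arange(1, n + 1),
                              np.arange(self.t_start, self.t_start + n_times),
                              np.arange(1, n_bio + 1), indexing="ij")
        return pd.DataFrame({"i": i.ravel(), "t": t.ravel(), "b": b.ravel(),
                             "value": self.values.ravel()})


@dataclass
class SimulationOutputs:
    """All arrays and tables produced by one :func:`runserosim` call."""

    exposure_probabilities: np.ndarray   # (N, T, X) phi; NaN absent/fixed
    fixed_mask: np.ndarray               # (N, T, X) bool, True where fixed
    immune_history: np.ndarray           # (N, T, X) in {0, 1, NaN}
    biomarker_states: BiomarkerStates    # (N, T, B)
    kinetics_draws: KineticsDraws
    observed: pd.DataFrame               # i, t, b, observed
    metadata: dict = field(default_factory=dict)
    t_start: int = 1

    def _grid_long(self, arr: np.ndarray, value_col: str,
                   axis_col: str = "x") -> pd.DataFrame:
        n, n_times, k = arr.shape
        i, t, x = np.meshgrid(np.arange(1, n + 1),
                              np.arange(self.t_start, self.t_start + n_times),
                              np.arange(1, k + 1), indexing="ij")
        return pd.DataFrame({"i": i.ravel(), "t": t.ravel(),
                             axis_col: x.ravel(), value_col: arr.ravel()})

    def exposure_probabilities_long(self) -> pd.DataFrame:
        return self._grid_long(self.exposure_probabilities, "phi")

    def immune_histories_long(self) -> pd.DataFrame:
        return self._grid_long(self.immune_history, "z")

    def biomarker_states_long(self) -> pd.DataFrame:
        return self.biomarker_states.to_long().rename(columns={"value": "a"})

    def save(self, out_dir) -> None:
        """Write the five long tables plus a metadata file."""
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.exposure_probabilities_long().to_csv(
            out / "exposure_probabilities.csv", index=False)
        self.immune_histories_long().to_csv(
            out / "immune_histories.csv", index=False)
        self.biomarker_states_long().to_csv(
            out / "biomarker_states.csv", index=False)
        self.kinetics_draws.to_frame().to_csv(
            out / "kinetics_draws.csv", index=False)
        self.observed.to_csv(out / "observed_biomarkers.csv", index=False)
        (out / "metadata.json").write_text(
            json.dumps(self.metadata, indent=2, default=str))


def _accepted_kwargs(func, extra: Mapping) -> dict:
    params = inspect.signature(func).parameters
    return {k: v for k, v in extra.items() if k in params}


def _validate_extra_args(extra: Mapping, models) -> None:
    """Every extra key must be consumed by exactly one stage."""
    for key in extra:
        consumers = [m.__name__ for m in models
                     if key in inspect.signature(m).parameters]
        if key in _ENGINE_KEYS or key in _ASSAY_KEYS:
            if consumers:
                raise ConfigurationError(
                    f"extra argument {key!r} is reserved but also accepted "
                    f"by {consumers}")
            continue
        if len(consumers) == 0:
            raise ConfigurationError(
                f"extra argument {key!r} is not consumed by any model")
        if len(consumers) > 1:
            raise ConfigurationError(
                f"extra argument {key!r} is ambiguous: accepted by {consumers}")


def _coerce_fixed_history(fixed_history, shape, t_start: int) -> np.ndarray:
    if fixed_history is None:
        return np.full(shape, np.nan)
    if isinstance(fixed_history, np.ndarray):
        if fixed_history.shape != shape:
            raise InvalidInputError(
                f"fixed history shape {fixed_history.shape} != {shape}")
        return fixed_history.astype(float)
    out = np.full(shape, np.nan)
    for i, t, x, z in fixed_history:  # iterable of (i, t, x, z) entries
        out[i - 1, t - t_start, x - 1] = float(z)
    return out


class _LazyBiomarkers(Mapping):
    """Mapping b -> A_{i,t,b} computed on first access and cached."""

    def __init__(self, biomarkers, compute):
        self._keys = list(biomarkers)
        self._compute = compute
        self._cache: dict[int, float] = {}

    def __getitem__(self, b):
        if b not in self._cache:
            self._cache[b] = self._compute(b)
        return self._cache[b]

    def __iter__(self):
        return iter(self._keys)

    def __len__(self):
        return len(self._keys)


def _resolve_assay(assay: AssaySpec | None, extra: Mapping,
                   model_pars: ModelPars) -> AssaySpec:
    if assay is not None:
        if any(k in extra for k in _ASSAY_KEYS):
            raise ConfigurationError(
                "pass assay characteristics either as an AssaySpec or via "
                "model_extra_args, not both")
        return assay
    noise_sd = extra.get("noise_sd", model_pars.obs_sd())
    return AssaySpec(
        noise_sd=0.0 if noise_sd is None else float(noise_sd),
        sensitivity=float(extra.get("sensitivity", 1.0)),
        specificity=float(extra.get("specificity", 1.0)),
        lower_bound=extra.get("lower_bound"),
        upper_bound=extra.get("upper_bound"),
        output=extra.get("assay_output", "continuous"),
    )


def runserosim(
    settings: tuple[int, int] | Mapping,
    demography: Demography,
    biomarker_map: BiomarkerMap,
    foe: FOEGrid,
    model_pars: ModelPars,
    exposure_model,
    immunity_model,
    antibody_model,
    observation_model,
    draw_parameters,
    observation_design: pd.DataFrame | None = None,
    fixed_history=None,
    model_extra_args: Mapping | None = None,
    rng_seed: int = 0,
    assay: AssaySpec | None = None,
) -> SimulationOutputs:
    """Run one full individual-based serological simulation.

    Parameters
    ----------
    settings:
        ``(t_start, t_end)`` or a mapping with those keys.
    observation_design:
        DataFrame ``(i, t, b)`` of samples to take; ``None`` observes
        everything.
    fixed_history:
        Optional partial immune history — an ``(N, T, X)`` float array with
        NaN for "simulate me", or an iterable of ``(i, t, x, z)`` entries.
        Fixed entries are taken verbatim and never overwritten.
    model_extra_args:
        Extra keyword arguments routed to whichever model accepts them
        (e.g. ``max_events``, ``vacc_exposures``, ``vacc_age``,
        ``sensitivity``, ``specificity``, ``titer_ceiling_gradient``).
    assay:
        Assay characteristics; when ``None`` they are assembled from
        ``model_extra_args`` and the ``obs_sd`` row of ``model_pars``.
    """
    if isinstance(settings, Mapping):
        t_start, t_end = int(settings["t_start"]), int(settings["t_end"])
    else:
        t_start, t_end = map(int, settings)
    if t_end < t_start:
        raise InvalidInputError("t_end must be >= t_start")

    extra = dict(model_extra_args or {})
    _validate_extra_args(extra, (exposure_model, immunity_model,
                                 antibody_model, draw_parameters))
    assay_spec = _resolve_assay(assay, extra, model_pars)
    gradient = extra.get("titer_ceiling_gradient")

    numeric_map, _, _ = reformat_biomarker_map(biomarker_map)
    exposures = sorted(int(x) for x in numeric_map.exposure_ids)
    biomarkers = sorted(int(b) for b in numeric_map.biomarker_ids)
    n_exposures = max(exposures)
    n_biomarkers = max(biomarkers)

    if not foe.covers(t_start, t_end):
        raise ConfigurationError(
            f"FOE grid [{foe.t_start}, {foe.t_end}] does not cover the "
            f"simulation window [{t_start}, {t_end}]")
    if foe.n_exposures < n_exposures:
        raise ConfigurationError(
            f"FOE grid has {foe.n_exposures} exposure types; map needs "
            f"{n_exposures}")
    for x, b in numeric_map.pairs():
        rows = model_pars.rows_for(x, b)
        if len(rows[rows["name"] != "obs_sd"]) == 0:
            raise ConfigurationError(
                f"model_pars has no kinetics rows for exposure {x}, "
                f"biomarker {b}")

    n = demography.n_individuals
    times = np.arange(t_start, t_end + 1)
    n_times = times.size
    shape_x = (n, n_times, n_exposures)
    active = demography.active_mask(times)
    fixed = _coerce_fixed_history(fixed_history, shape_x, t_start)
    fixed_given = ~np.isnan(fixed)
    if (fixed_given & ~active[:, :, None]).any():
        raise InvalidInputError(
            "fixed immune-history entries conflict with demography "
            "activity (individual inactive at that time)")

    rng = np.random.default_rng(rng_seed)
    phi = np.full(shape_x, np.nan)
    fixed_mask = np.zeros(shape_x, dtype=bool)
    z = np.full(shape_x, np.nan)

    exposure_args = _accepted_kwargs(exposure_model, extra)
    immunity_args = _accepted_kwargs(immunity_model, extra)
    antibody_args = _accepted_kwargs(antibody_model, extra)
    draw_args = _accepted_kwargs(draw_parameters, extra)
    if "biomarker_map" in inspect.signature(immunity_model).parameters:
        immunity_args.setdefault("biomarker_map", numeric_map)
    if "demography" in inspect.signature(exposure_model).parameters:
        exposure_args.setdefault("demography", demography)

    cache_pe = not getattr(exposure_model, "depends_on_individual", True)
    pe_cache: dict[tuple[int, int, int], float] = {}
    needs_biomarkers = getattr(immunity_model, "uses_biomarkers", False)

    events: dict[int, list[tuple[int, int]]] = defaultdict(list)
    counts: dict[int, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    draws = KineticsDraws()
    groups = [demography.group(i) for i in range(1, n + 1)]
    births = [demography.birth_time(i) for i in range(1, n + 1)]

    def latent_at(i: int, t: int, b: int, before: int | None = None) -> float:
        evts = events[i]
        if before is not None:
            evts = [e for e in evts if e[0] < before]
        return antibody_model(i, t, b, evts, draws, numeric_map,
                              **antibody_args)

    for ti, t in enumerate(times):
        for i in range(1, n + 1):
            if not active[i - 1, ti]:
                continue
            g = groups[i - 1]
            # snapshot: events at this same t must not protect against each
            # other, so the context sees only successes strictly before t
            prior_counts = dict(counts[i])
            ctx = None
            for x in exposures:
                xi = x - 1
                if fixed_given[i - 1, ti, xi]:
                    z_val = fixed[i - 1, ti, xi]
                    z[i - 1, ti, xi] = z_val
                    fixed_mask[i - 1, ti, xi] = True
                else:
                    if ctx is None:
                        ctx = ImmunityContext(
                            prior_success_counts=prior_counts,
                            current_biomarkers=_LazyBiomarkers(
                                biomarkers,
                                lambda b, _i=i, _t=t: latent_at(
                                    _i, _t, b, before=_t))
                            if needs_biomarkers else {},
                            age=t - births[i - 1],
                        )
                    if cache_pe:
                        key = (g, t, x)
                        p_e = pe_cache.get(key)
                        if p_e is None:
                            p_e = exposure_model(i, t, x, g, foe,
                                                 **exposure_args)
                            pe_cache[key] = p_e
                    else:
                        p_e = exposure_model(i, t, x, g, foe, **exposure_args)
                    p_s = immunity_model(ctx, x, **immunity_args)
                    p = p_e * p_s
                    phi[i - 1, ti, xi] = p
                    z_val = 1.0 if rng.random() < p else 0.0
                    z[i - 1, ti, xi] = z_val
                if z_val == 1.0:
                    rows = draw_parameters(model_pars, (i, t, x),
                                           numeric_map, rng, **draw_args)
                    if gradient is not None:
                        for row in rows:
                            if row["name"].startswith("boost"):
                                row["value"] = apply_titer_ceiling(
                                    row["value"],
                                    latent_at(i, t, row["b"], before=t),
                                    gradient)
                    draws.add_rows(rows)
                    events[i].append((t, x))
                    counts[i][x] += 1

    # latent biomarker trajectories
    A = np.full((n, n_times, n_biomarkers), np.nan)
    for i in range(1, n + 1):
        evts = events[i]
        for b in biomarkers:
            col = np.full(n_times, np.nan)
            row_active = active[i - 1]
            if not evts:
                col[row_active] = 0.0
            else:
                for ti in np.nonzero(row_active)[0]:
                    col[ti] = latent_at(i, int(times[ti]), b)
            A[i - 1, :, b - 1] = col
    states = BiomarkerStates(A, t_start=t_start)

    observed = apply_observation_design(
        states, observation_design, observation_model, assay_spec, rng,
        demography)

    config_repr = json.dumps({
        "t_start": t_start, "t_end": t_end, "n": n, "seed": rng_seed,
        "models": [m.__name__ for m in (exposure_model, immunity_model,
                                        antibody_model, observation_model,
                                        draw_parameters)],
        "extra": {k: str(v) for k, v in sorted(extra.items())},
    }, sort_keys=True)
    metadata = {
        "seed": rng_seed,
        "t_start": t_start,
        "t_end": t_end,
        "n_individuals": n,
        "models": {
            "exposure": exposure_model.__name__,
            "immunity": immunity_model.__name__,
            "antibody": antibody_model.__name__,
            "observation": observation_model.__name__,
            "draw_parameters": draw_parameters.__name__,
        },
        "config_hash": hashlib.sha256(config_repr.encode()).hexdigest()[:16],
        "package_version": __version__,
    }
    return SimulationOutputs(
        exposure_probabilities=phi,
        fixed_mask=fixed_mask,
        immune_history=z,
        biomarker_states=states,
        kinetics_draws=draws,
        observed=observed,
        metadata=metadata,
        t_start=t_start,
    )


def summarize_run(outputs: SimulationOutputs,
                  seropositivity_threshold: float | None = None) -> dict:
    """Deterministic summary of a completed run.

    Returns per-exposure-type success counts, per-individual event times,
    and (when a threshold is given) the seroprevalence among non-absent
    observations, i.e. the fraction with ``Y >= threshold``.
    """
    z = outputs.immune_history
    n, _, n_exposures = z.shape
    event_counts = {x: int(np.nansum(z[:, :, x - 1]))
                    for x in range(1, n_exposures + 1)}
    per_individual: dict[int, list[tuple[int, int]]] = {}
    for i in range(1, n + 1):
        hits = np.argwhere(z[i - 1] == 1.0)
        per_individual[i] = [(int(t_idx) + outputs.t_start, int(x_idx) + 1)
                             for t_idx, x_idx in hits]
    summary = {
        "event_counts": event_counts,
        "event_times": per_individual,
        "n_observations": int(outputs.observed["observed"].notna().sum()),
    }
    if seropositivity_threshold is not None:
        y = outputs.observed["observed"].dropna()
        summary["seroprevalence"] = (
            float((y >= seropositivity_threshold).mean()) if len(y) else float("nan"))
    return summary
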