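"""Antibody (biomarker) kinetics: parameter draws and latent trajectories.

Population-level kinetics hyperparameters live in a :class:`ModelPars` table
(one row per exposure type x biomarker x parameter name, with a mean, an sd
and a distribution label).  At every successful exposure event a
``draw_parameters`` function realizes per-event parameters from that table —
either fixed effects (the mean, shared by everyone) or random effects
(log-normal or normal draws).  The antibody models then evaluate the latent
biomarker quantity ``A_{i,t,b}`` as a sum of per-event boost/waning
contributions.

Log-normal draws are moment-matched on the natural scale: a row with mean m
and sd s is drawn from LogNormal(mu, sigma) with
``sigma^2 = ln(1 + (s/m)^2)`` and ``mu = ln(m) - sigma^2/2``, so the sample
mean of many draws converges to m and the sample sd to s.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomarker_map import BiomarkerMap
from .errors import ConfigurationError, InvalidInputError, UnknownIdentifierError

_MODEL_PARS_COLUMNS = ("exposure_id", "biomarker_id", "name",
                       "mean", "sd", "distribution")


@dataclass(frozen=True)
class ModelPars:
    """Population-level kinetics (and observation) parameter table.

    Columns: ``exposure_id, biomarker_id, name, mean, sd, distribution``.
    ``distribution`` may be ``"log-normal"``, ``"normal"`` or empty (fixed
    value).  An ``obs_sd`` row with empty exposure/biomarker ids can carry
    the assay noise standard deviation.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in _MODEL_PARS_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidInputError(f"model_pars lacks columns {missing}")
        if df.duplicated(["exposure_id", "biomarker_id", "name"]).any():
            raise InvalidInputError(
                "(exposure_id, biomarker_id, name) must be unique")
        sd = pd.to_numeric(df["sd"], errors="coerce")
        if (sd.dropna() < 0).any():
            raise InvalidInputError("sd must be >= 0")
        df = df[list(_MODEL_PARS_COLUMNS)].reset_index(drop=True)
        object.__setattr__(self, "table", df)
        # per-(exposure, biomarker) kinetics rows, cached for the engine
        by_pair: dict[tuple, list[dict]] = {}
        for rec in df.to_dict("records"):
            if rec["name"] == "obs_sd":
                continue
            by_pair.setdefault(
                (rec["exposure_id"], rec["biomarker_id"]), []).append(rec)
        object.__setattr__(self, "_kinetics_rows", by_pair)

    def rows_for(self, exposure, biomarker) -> pd.DataFrame:
        return self.table[(self.table["exposure_id"] == exposure)
                          & (self.table["biomarker_id"] == biomarker)]

    def row(self, exposure, biomarker, name) -> pd.Series:
        rows = self.rows_for(exposure, biomarker)
        rows = rows[rows["name"] == name]
        if len(rows) == 0:
            raise ConfigurationError(
                f"model_pars has no ({exposure!r}, {biomarker!r}, {name!r}) row")
        return rows.iloc[0]

    def obs_sd(self) -> float | None:
        """Assay noise sd from an ``obs_sd`` row, if present."""
        rows = self.table[self.table["name"] == "obs_sd"]
        if len(rows) == 0:
            return None
        return float(rows.iloc[0]["mean"])

    def with_numeric_ids(self, exposure_lookup: dict,
                         biomarker_lookup: dict) -> "ModelPars":
        """Relabel string ids using lookup tables from map reformatting.

        Rows with empty ids (e.g. ``obs_sd``) are kept as-is.
        """
        df = self.table.copy()
        df["exposure_id"] = df["exposure_id"].map(
            lambda e: exposure_lookup.get(e, e) if pd.notna(e) else e)
        df["biomarker_id"] = df["biomarker_id"].map(
            lambda b: biomarker_lookup.get(b, b) if pd.notna(b) else b)
        return ModelPars(df)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ModelPars":
        return cls(pd.read_csv(path))


class KineticsDraws:
    """Realized kinetics parameters, indexed by (i, event time, x, b, name).

    One draw exists per successful exposure event, per biomarker linked to
    the event's exposure type, per parameter name.
    """

    def __init__(self) -> None:
        self._rows: list[dict] = []
        self._index: dict[tuple, float] = {}

    def add_rows(self, rows: Iterable[dict]) -> None:
        for row in rows:
            key = (row["i"], row["t"], row["x"], row["b"], row["name"])
            self._index[key] = float(row["value"])
            self._rows.append(dict(row))

    def get(self, i: int, t: int, x: int, b: int, name: str) -> float:
        key = (i, t, x, b, name)
        if key not in self._index:
            raise UnknownIdentifierError(
                f"no kinetics draw for event {key}")
        return self._index[key]

    def has(self, i: int, t: int, x: int, b: int, name: str) -> bool:
        return (i, t, x, b, name) in self._index

    def __len__(self) -> int:
        return len(self._rows)

    def n_event_groups(self) -> int:
        """Number of distinct (i, t, x) events with at least one draw."""
        return len({(r["i"], r["t"], r["x"]) for r in self._rows})

    def to_frame(self) -> pd.DataFrame:
        if not self._rows:
            return pd.DataFrame(columns=["i", "t", "x", "b", "name", "value"])
        return pd.DataFrame(self._rows)[["i", "t", "x", "b", "name", "value"]]


# -- parameter draws -------------------------------------------------------

def lognormal_moment_match(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given natural-scale moments."""
    if mean <= 0:
        raise InvalidInputError("log-normal rows require mean > 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_parameter(row: pd.Series, rng: np.random.Generator,
                     size: int | None = None):
    """Draw realized value(s) for one ModelPars row.

    Degenerate rows (sd 0 or missing, or empty distribution) return the mean
    verbatim.
    """
    mean = float(row["mean"])
    sd = row["sd"]
    sd = float(sd) if pd.notna(sd) else 0.0
    dist = row["distribution"]
    dist = "" if pd.isna(dist) else str(dist).strip().lower()
    if sd == 0.0 or dist == "":
        return np.full(size, mean) if size is not None else mean
    if dist in ("log-normal", "lognormal"):
        mu, sigma = lognormal_moment_match(mean, sd)
        return rng.lognormal(mu, sigma, size=size)
    if dist == "normal":
        return rng.normal(mean, sd, size=size)
    raise ConfigurationError(f"unknown distribution label {dist!r}")


def _event_rows(model_pars: ModelPars, event: tuple[int, int, int],
                biomarker_map: BiomarkerMap, value_fn) -> list[dict]:
    i, t, x = event
    out = []
    try:
        linked = sorted(biomarker_map.biomarkers_of(x))
    except KeyError as exc:
        raise ConfigurationError(f"exposure {x} absent from biomarker map") from exc
    for b in linked:
        rows = model_pars._kinetics_rows.get((x, b), [])
        if not rows:
            raise ConfigurationError(
                f"model_pars has no rows for exposure {x}, biomarker {b}")
        for row in rows:
            out.append({"i": i, "t": t, "x": x, "b": b,
                        "name": row["name"], "value": value_fn(row)})
    return out


def draw_parameters_fixed_fx(model_pars: ModelPars, event: tuple[int, int, int],
                             biomarker_map: BiomarkerMap,
                             rng: np.random.Generator) -> list[dict]:
    """Fixed effects: every event receives the mean column verbatim."""
    return _event_rows(model_pars, event, biomarker_map,
                       lambda row: float(row["mean"]))


def draw_parameters_random_fx(model_pars: ModelPars, event: tuple[int, int, int],
                              biomarker_map: BiomarkerMap,
                              rng: np.random.Generator) -> list[dict]:
    """Random effects: per-event draws from the row's distribution."""
    return _event_rows(model_pars, event, biomarker_map,
                       lambda row: float(sample_parameter(row, rng)))


# -- kinetics models -------------------------------------------------------

def cross_reactive_boost_weight(distance: float, sigma: float) -> float:
    """Attenuation ``exp(-sigma * distance)`` of a cross-reactive boost."""
    if distance < 0:
        raise InvalidInputError("antigenic distance must be >= 0")
    if sigma <= 0:
        raise InvalidInputError("sigma must be > 0")
    return math.exp(-sigma * distance)


def apply_titer_ceiling(raw_boost: float, current_A: float,
                        gradient: float) -> float:
    """Biomarker-dependent boosting: attenuate boosts at high titers.

    The realized boost is ``raw_boost * max(0, 1 - gradient * current_A)``,
    applied at the event time before the draw is stored.
    """
    if gradient < 0:
        raise InvalidInputError("gradient must be >= 0")
    return raw_boost * max(0.0, 1.0 - gradient * current_A)


def _event_weight(x: int, b: int, biomarker_map: BiomarkerMap,
                  cross_reactivity_sigma: float | None) -> float:
    if cross_reactivity_sigma is None:
        return 1.0
    return cross_reactive_boost_weight(
        biomarker_map.antigenic_distance(x, b), cross_reactivity_sigma)


def antibody_model_monophasic(
    i: int, t: int, b: int,
    events: Sequence[tuple[int, int]],
    draws: KineticsDraws,
    biomarker_map: BiomarkerMap,
    cross_reactivity_sigma: float | None = None,
) -> float:
    """Monophasic boosting-waning kinetics.

    Each successful event at time ``t'`` whose exposure type boosts ``b``
    contributes ``boost * max(0, 1 - wane * (t - t'))``; contributions are
    additive and each is floored at zero, so A >= 0 always.
    """
    total = 0.0
    for t_event, x in events:
        if t_event > t:
            continue
        if b not in biomarker_map.biomarkers_of(x):
            continue
        boost = draws.get(i, t_event, x, b, "boost")
        wane = draws.get(i, t_event, x, b, "wane")
        w = _event_weight(x, b, biomarker_map, cross_reactivity_sigma)
        total += w * boost * max(0.0, 1.0 - wane * (t - t_event))
    return total


def antibody_model_biphasic(
    i: int, t: int, b: int,
    events: Sequence[tuple[int, int]],
    draws: KineticsDraws,
    biomarker_map: BiomarkerMap,
    cross_reactivity_sigma: float | None = None,
) -> float:
    """Biphasic kinetics: short-lived plus long-lived boost components.

    Per event: ``boost_long * max(0, 1 - wane_long * dt) +
    boost_short * max(0, 1 - wane_short * dt)``.  With ``boost_short = 0``
    this reduces to the monophasic model on (boost_long, wane_long).
    """
    total = 0.0
    for t_event, x in events:
        if t_event > t:
            continue
        if b not in biomarker_map.biomarkers_of(x):
            continue
        dt = t - t_event
        w = _event_weight(x, b, biomarker_map, cross_reactivity_sigma)
        long_part = (draws.get(i, t_event, x, b, "boost_long")
                     * max(0.0, 1.0 - draws.get(i, t_event, x, b, "wane_long") * dt))
        short_part = (draws.get(i, t_event, x, b, "boost_short")
                      * max(0.0, 1.0 - draws.get(i, t_event, x, b, "wane_short") * dt))
        total += w * (long_part + short_part)
    return total
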