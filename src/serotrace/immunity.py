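"""Immunity models: probability that an exposure takes, P(Z=1 | E=1).

Given that an individual encountered exposure type ``x`` at time ``t``, the
immunity model decides how likely the encounter is to produce a measurable
immunological response ("success"), conditioning only on information
available strictly before ``t``: prior successful events, current latent
biomarker quantities, and demographic facts such as age.  Successes at the
same time step never protect against each other.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence, Set
from dataclasses import dataclass, field

from .biomarker_map import BiomarkerMap
from .errors import ConfigurationError, InvalidInputError


@dataclass
class ImmunityContext:
    """Per-(individual, time) information an immunity model may condition on.

    Attributes
    ----------
    prior_success_counts:
        Successful events of each exposure type strictly before the decision
        time.
    current_biomarkers:
        Latent biomarker quantities at the decision time (computed from
        events strictly before it); may be a lazily-evaluated mapping.
    age:
        ``t - birth_time`` in time steps.
    params:
        Free-form extras for user-written models.
    """

    prior_success_counts: Mapping[int, int]
    current_biomarkers: Mapping[int, float]
    age: int
    params: dict = field(default_factory=dict)


def _per_type(spec, x: int, what: str):
    """Resolve a per-exposure-type parameter given as mapping or sequence.

    Sequences follow the 1-based exposure indexing (element ``x-1``); ``None``
    and NaN entries mean "no constraint".  Missing entries raise a
    configuration error for ``what``-style required parameters.
    """
    value = None
    if isinstance(spec, Mapping):
        if x not in spec:
            raise ConfigurationError(f"missing {what} for exposure type {x}")
        value = spec[x]
    elif isinstance(spec, Sequence) and not isinstance(spec, (str, bytes)):
        if not 1 <= x <= len(spec):
            raise ConfigurationError(f"missing {what} for exposure type {x}")
        value = spec[x - 1]
    else:
        value = spec
    if value is None:
        return None
    value = float(value)
    return None if math.isnan(value) else value


def immunity_model_all_successful(ctx: ImmunityContext, x: int) -> float:
    """Every exposure succeeds, regardless of history or age."""
    return 1.0


def immunity_model_vacc_ifxn_simple(
    ctx: ImmunityContext,
    x: int,
    max_events,
    vacc_exposures: Set[int] | Sequence[int] = (),
    vacc_age=None,
) -> float:
    """Success gated by event caps and (for vaccines) age eligibility.

    An exposure of type ``x`` succeeds (probability 1) unless the individual
    has already accrued ``max_events[x]`` successes of that type, or ``x`` is
    a vaccine type and the individual is younger than ``vacc_age[x]`` time
    steps.  Otherwise it fails (probability 0).
    """
    cap = _per_type(max_events, x, "max_events cap")
    if cap is None or cap < 1:
        raise ConfigurationError(f"max_events cap for type {x} must be >= 1")
    if ctx.prior_success_counts.get(x, 0) >= cap:
        return 0.0
    if x in set(vacc_exposures):
        min_age = None if vacc_age is None else _per_type(vacc_age, x, "vacc_age")
        if min_age is not None and ctx.age < min_age:
            return 0.0
    return 1.0


def immunity_model_biomarker_protection(
    ctx: ImmunityContext,
    x: int,
    biomarker_map: BiomarkerMap,
    midpoint: float,
    steepness: float,
    mode: str = "logistic",
    protection_sigma: float | None = None,
) -> float:
    """Success probability decreasing in current protective biomarker level.

    The protective quantity ``a`` is the sum of the individual's current
    latent quantities over the biomarkers linked to ``x`` (optionally
    down-weighted by ``exp(-protection_sigma * antigenic_distance)`` when the
    map carries distances).  ``mode="threshold"`` returns 1 when
    ``a < midpoint`` else 0; ``mode="logistic"`` returns
    ``1 - 1/(1 + exp(-steepness * (a - midpoint)))``, which is strictly
    decreasing in ``a`` and equals 0.5 at the midpoint.
    """
    if steepness <= 0:
        raise InvalidInputError("steepness must be > 0")
    try:
        linked = biomarker_map.biomarkers_of(x)
    except KeyError as exc:
        raise ConfigurationError(
            f"exposure type {x} has no mapped biomarker") from exc
    a = 0.0
    for b in linked:
        weight = 1.0
        if protection_sigma is not None:
            d = biomarker_map.antigenic_distance(x, b)
            weight = math.exp(-protection_sigma * d)
        a += weight * float(ctx.current_biomarkers[b])
    if mode == "threshold":
        return 1.0 if a < midpoint else 0.0
    if mode == "logistic":
        return _expit(-steepness * (a - midpoint))
    raise ConfigurationError(f"unknown protection mode {mode!r}")


def _expit(z: float) -> float:
    # overflow-safe logistic function
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


# flag telling the engine this model needs current biomarker quantities
immunity_model_biomarker_protection.uses_biomarkers = True  # type: ignore[attr-defined]
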