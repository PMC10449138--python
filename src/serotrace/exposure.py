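"""Exposure models: from force of exposure to per-contact probabilities.

The force of exposure (FOE) lambda_{g,t,x} is a per-time-step hazard for
group ``g``, time ``t`` and exposure type ``x``.  An exposure model turns it
into the probability that individual ``i`` encounters exposure type ``x``
during step ``t``.  The built-ins use the standard hazard-to-probability
transform ``P(E=1) = 1 - exp(-lambda)``; demographic modifiers act
multiplicatively on lambda so results stay valid probabilities.

Lambda is interpreted per single time step: rates must be pre-scaled to the
chosen step length (a monthly simulation needs monthly rates).
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import Demography
from .errors import ConfigurationError, InvalidInputError, UnknownIdentifierError


@dataclass(frozen=True)
class FOEGrid:
    """Force of exposure on a (group, time, exposure type) grid.

    ``values[g-1, t-t_start, x-1]`` holds lambda_{g,t,x}.  The time axis must
    span the whole simulation window.
    """

    values: np.ndarray
    t_start: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise InvalidInputError("FOE grid must be 3-dimensional (g, t, x)")
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise InvalidInputError("FOE values must be finite and >= 0")
        object.__setattr__(self, "values", arr)

    @property
    def n_groups(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_exposures(self) -> int:
        return self.values.shape[2]

    @property
    def t_end(self) -> int:
        return self.t_start + self.n_times - 1

    def covers(self, t_start: int, t_end: int) -> bool:
        return self.t_start <= t_start and t_end <= self.t_end

    def lambda_at(self, g: int, t: int, x: int) -> float:
        if not (1 <= g <= self.n_groups and 1 <= x <= self.n_exposures
                and self.t_start <= t <= self.t_end):
            raise UnknownIdentifierError(
                f"(g={g}, t={t}, x={x}) outside FOE grid bounds")
        return float(self.values[g - 1, t - self.t_start, x - 1])

    # -- constructors / serialization -------------------------------------

    @classmethod
    def constant(cls, lambdas, t_start: int, t_end: int,
                 n_groups: int = 1) -> "FOEGrid":
        """Grid with one time-constant lambda per exposure type."""
        lam = np.asarray(lambdas, dtype=float)
        n_times = t_end - t_start + 1
        values = np.broadcast_to(lam, (n_groups, n_times, lam.size)).copy()
        return cls(values, t_start=t_start)

    def to_long(self) -> pd.DataFrame:
        g, t, x = np.meshgrid(
            np.arange(1, self.n_groups + 1),
            np.arange(self.t_start, self.t_end + 1),
            np.arange(1, self.n_exposures + 1),
            indexing="ij",
        )
        return pd.DataFrame({
            "group": g.ravel(), "time": t.ravel(), "exposure": x.ravel(),
            "lambda": self.values.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "FOEGrid":
        for col in ("group", "time", "exposure", "lambda"):
            if col not in df.columns:
                raise InvalidInputError(f"FOE table lacks column {col!r}")
        groups = np.sort(df["group"].unique())
        times = np.sort(df["time"].unique())
        exposures = np.sort(df["exposure"].unique())
        if not np.array_equal(times, np.arange(times[0], times[-1] + 1)):
            raise InvalidInputError("FOE time axis must be contiguous")
        values = np.zeros((len(groups), len(times), len(exposures)))
        gi = {g: k for k, g in enumerate(groups)}
        xi = {x: k for k, x in enumerate(exposures)}
        t0 = int(times[0])
        g_idx = df["group"].map(gi).to_numpy()
        t_idx = df["time"].to_numpy(dtype=int) - t0
        x_idx = df["exposure"].map(xi).to_numpy()
        values[g_idx, t_idx, x_idx] = df["lambda"].to_numpy(dtype=float)
        return cls(values, t_start=t0)

    @classmethod
    def from_csv(cls, path) -> "FOEGrid":
        return cls.from_long(pd.read_csv(path))


# -- exposure models -------------------------------------------------------

def exposure_model_simple_FOE(individual: int, t: int, x: int, g: int,
                              foe: FOEGrid) -> float:
    """P(E=1) = 1 - exp(-lambda_{g,t,x}); depends only on the FOE."""
    return -math.expm1(-foe.lambda_at(g, t, x))


# the simple model ignores the individual, enabling per-(g,t,x) caching in
# the engine
exposure_model_simple_FOE.depends_on_individual = False  # type: ignore[attr-defined]


def exposure_model_dem_mod(
    individual: int, t: int, x: int, g: int, foe: FOEGrid,
    demography: Demography,
    modifiers: Mapping[str, Mapping] | None = None,
) -> float:
    """Demography-modulated exposure probability.

    ``modifiers`` maps an attribute column name to a table of
    ``attribute value -> multiplier`` (multipliers >= 0); the product of the
    individual's multipliers rescales lambda before the hazard transform:
    ``P(E=1) = 1 - exp(-lambda * prod(multipliers))``.
    """
    lam = foe.lambda_at(g, t, x)
    factor = 1.0
    for attr, table in (modifiers or {}).items():
        try:
            value = demography.attribute(individual, attr)
        except UnknownIdentifierError as exc:
            raise ConfigurationError(
                f"modifier attribute {attr!r} missing from demography") from exc
        if value not in table:
            raise ConfigurationError(
                f"no multiplier for {attr!r} value {value!r}")
        mult = float(table[value])
        if mult < 0:
            raise InvalidInputError("modifier multipliers must be >= 0")
        factor *= mult
    return -math.expm1(-lam * factor)
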