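"""Population demography tables.

A :class:`Demography` records, for each simulated individual ``i``, the time
step at which they enter the population (``birth_time``), the time step at
which they leave it (``removal_time``, ``+inf`` when they never do), a group
identifier ``g`` used to index group-specific forces of exposure, and any
number of extra covariate columns (age class, nutritional status, ...) that
exposure or immunity models may consult.

The activity convention is half-open: an individual is available to be
exposed at every ``t`` with ``birth_time <= t < removal_time``.  Output grids
carry an absent sentinel (NaN) wherever an individual is inactive.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UnknownIdentifierError

#: Sentinel removal time for individuals that are never removed.
REMOVAL_NEVER = np.inf

_CORE_COLUMNS = ("i", "birth_time", "removal_time", "group")


@dataclass(frozen=True)
class Demography:
    """Validated population table, one row per individual.

    Parameters
    ----------
    table:
        DataFrame with columns ``i`` (ids exactly ``1..N``), ``birth_time``,
        ``removal_time`` (``np.inf`` allowed) and ``group``; any further
        columns are treated as covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in ("i", "birth_time") if c not in df.columns]
        if missing:
            raise InvalidInputError(f"demography table lacks columns {missing}")
        if "removal_time" not in df.columns:
            df["removal_time"] = REMOVAL_NEVER
        if "group" not in df.columns:
            df["group"] = 1  # everyone in group one unless specified
        df["removal_time"] = df["removal_time"].fillna(REMOVAL_NEVER)
        df = df.sort_values("i").reset_index(drop=True)
        ids = df["i"].to_numpy()
        n = len(df)
        if n == 0 or not np.array_equal(ids, np.arange(1, n + 1)):
            raise InvalidInputError("individual ids must be exactly 1..N")
        if (df["birth_time"].to_numpy() > df["removal_time"].to_numpy()).any():
            raise InvalidInputError("birth_time must be <= removal_time")
        # reorder core columns first for stable serialization
        extra = [c for c in df.columns if c not in _CORE_COLUMNS]
        object.__setattr__(self, "table", df[list(_CORE_COLUMNS) + extra])

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    @property
    def attribute_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in _CORE_COLUMNS]

    def _row(self, individual: int) -> pd.Series:
        if not 1 <= individual <= self.n_individuals:
            raise UnknownIdentifierError(f"unknown individual id {individual}")
        return self.table.iloc[individual - 1]

    def birth_time(self, individual: int) -> int:
        return int(self._row(individual)["birth_time"])

    def removal_time(self, individual: int) -> float:
        return float(self._row(individual)["removal_time"])

    def group(self, individual: int) -> int:
        return int(self._row(individual)["group"])

    def attribute(self, individual: int, name: str):
        row = self._row(individual)
        if name not in self.table.columns:
            raise UnknownIdentifierError(f"unknown demography attribute {name!r}")
        return row[name]

    # -- activity ----------------------------------------------------------

    def is_active(self, individual: int, t: int) -> bool:
        """Whether ``individual`` can be exposed/observed at time ``t``.

        Active on the half-open interval ``[birth_time, removal_time)``.
        """
        row = self._row(individual)
        return bool(row["birth_time"] <= t < row["removal_time"])

    def active_mask(self, times: Sequence[int]) -> np.ndarray:
        """Boolean array of shape ``(N, len(times))``; True where active."""
        t = np.asarray(times)
        birth = self.table["birth_time"].to_numpy()[:, None]
        removal = self.table["removal_time"].to_numpy()[:, None]
        return (birth <= t[None, :]) & (t[None, :] < removal)

    # -- serialization -----------------------------------------------------

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["removal_time"] = out["removal_time"].replace(REMOVAL_NEVER, np.nan)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Demography":
        df = pd.read_csv(path)
        return cls(df)


def _sample_attribute(spec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sample one covariate column from a small declarative spec.

    ``spec`` may be a callable ``(rng, n) -> array``, a mapping with
    ``values`` (+ optional ``probs``) for a categorical draw, or a mapping
    with ``low``/``high`` for a continuous uniform draw.
    """
    if callable(spec):
        return np.asarray(spec(rng, n))
    if isinstance(spec, Mapping):
        if "values" in spec:
            return rng.choice(np.asarray(spec["values"]), size=n,
                              p=spec.get("probs"))
        if "low" in spec and "high" in spec:
            return rng.uniform(spec["low"], spec["high"], size=n)
    raise InvalidInputError(f"unrecognized attribute sampler spec: {spec!r}")


def generate_pop_demography(
    n_individuals: int,
    times: Sequence[int],
    prob_removal: float = 0.0,
    attribute_specs: Sequence[tuple[str, object]] | None = None,
    rng_seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Demography:
    """Simulate a population table with random birth (and removal) times.

    Birth times are uniform over ``times``.  With probability
    ``prob_removal`` an individual additionally receives a removal time drawn
    uniformly from the integers in ``(birth_time, max(times)]``; otherwise
    (and whenever that interval is empty) the removal time is the ``+inf``
    sentinel.

    Parameters
    ----------
    n_individuals:
        Population size ``N`` (ids will be ``1..N``).
    times:
        Strictly increasing integer time grid of the simulation.
    prob_removal:
        Per-individual probability of ever being removed.
    attribute_specs:
        Optional ``(name, sampler-spec)`` pairs; see :func:`_sample_attribute`.
    rng_seed, rng:
        Either a seed or an existing generator; the result is deterministic
        given the generator state.
    """
    times = np.asarray(list(times), dtype=int)
    if times.size == 0:
        raise InvalidInputError("times must be nonempty")
    if times.size > 1 and not (np.diff(times) > 0).all():
        raise InvalidInputError("times must be strictly increasing")
    if not 0.0 <= prob_removal <= 1.0:
        raise InvalidInputError(f"prob_removal must be in [0, 1], got {prob_removal}")
    if n_individuals < 1:
        raise InvalidInputError("n_individuals must be >= 1")
    if rng is None:
        rng = np.random.default_rng(rng_seed)

    birth = rng.choice(times, size=n_individuals, replace=True)
    t_max = int(times.max())
    removal = np.full(n_individuals, REMOVAL_NEVER)
    removed = rng.random(n_individuals) < prob_removal
    for k in np.nonzero(removed)[0]:
        if birth[k] < t_max:  # (birth, t_max] nonempty
            removal[k] = rng.integers(birth[k] + 1, t_max + 1)

    df = pd.DataFrame({
        "i": np.arange(1, n_individuals + 1),
        "birth_time": birth,
        "removal_time": removal,
        "group": 1,
    })
    for name, spec in attribute_specs or []:
        df[name] = _sample_attribute(spec, rng, n_individuals)
    return Demography(df)
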