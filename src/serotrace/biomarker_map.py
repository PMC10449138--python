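"""Exposure-to-biomarker mapping.

Exposure events (infection with a pathogen, a vaccine dose, infection with a
particular strain, ...) stimulate one or more measurable biomarkers (IgG
titer against an antigen, neutralization titer, ...), and the same biomarker
may be boosted by several distinct exposure types.  The :class:`BiomarkerMap`
records this many-to-many relation, optionally with a per-pair antigenic
distance used to attenuate cross-reactive boosting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UnknownIdentifierError


def _is_integral(values) -> bool:
    try:
        arr = np.asarray(values)
    except Exception:
        return False
    if arr.dtype.kind in "iu":
        return True
    if arr.dtype.kind == "f":
        return bool(np.all(arr == np.floor(arr)))
    return False


@dataclass(frozen=True)
class BiomarkerMap:
    """Rows of ``(exposure_id, biomarker_id[, antigenic_distance])``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("exposure_id", "biomarker_id"):
            if col not in df.columns:
                raise InvalidInputError(f"biomarker map lacks column {col!r}")
        if len(df) == 0:
            raise InvalidInputError("biomarker map must be nonempty")
        if df.duplicated(["exposure_id", "biomarker_id"]).any():
            raise InvalidInputError("duplicate (exposure_id, biomarker_id) pairs")
        if "antigenic_distance" in df.columns:
            d = df["antigenic_distance"].to_numpy(dtype=float)
            if (d < 0).any() or not np.isfinite(d).all():
                raise InvalidInputError("antigenic_distance must be finite and >= 0")
        keep = ["exposure_id", "biomarker_id"]
        if "antigenic_distance" in df.columns:
            keep.append("antigenic_distance")
        df = df[keep].reset_index(drop=True)
        object.__setattr__(self, "table", df)
        # precomputed lookups; the per-row pandas filter is too slow for the
        # engine's inner loop
        links: dict = {}
        dists: dict = {}
        has_dist = "antigenic_distance" in df.columns
        for row in df.itertuples(index=False):
            links.setdefault(row.exposure_id, set()).add(row.biomarker_id)
            dists[(row.exposure_id, row.biomarker_id)] = (
                float(row.antigenic_distance) if has_dist else 0.0)
        object.__setattr__(self, "_links", links)
        object.__setattr__(self, "_distances", dists)

    # -- queries -----------------------------------------------------------

    @property
    def is_numeric(self) -> bool:
        return (_is_integral(self.table["exposure_id"].to_numpy())
                and _is_integral(self.table["biomarker_id"].to_numpy()))

    @property
    def exposure_ids(self) -> list:
        return list(pd.unique(self.table["exposure_id"]))

    @property
    def biomarker_ids(self) -> list:
        return list(pd.unique(self.table["biomarker_id"]))

    def biomarkers_of(self, exposure) -> set:
        """Set of biomarker ids boosted by ``exposure``."""
        if exposure not in self._links:
            raise UnknownIdentifierError(f"unknown exposure id {exposure!r}")
        return self._links[exposure]

    def antigenic_distance(self, exposure, biomarker) -> float:
        """Distance for a mapped pair; 0 when no distance column exists."""
        key = (exposure, biomarker)
        if key not in self._distances:
            raise UnknownIdentifierError(
                f"({exposure!r}, {biomarker!r}) not in biomarker map")
        return self._distances[key]

    def pairs(self) -> list[tuple]:
        return list(self.table[["exposure_id", "biomarker_id"]]
                    .itertuples(index=False, name=None))

    # -- serialization -----------------------------------------------------

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BiomarkerMap":
        return cls(pd.read_csv(path))


def reformat_biomarker_map(
    bmap: BiomarkerMap,
) -> tuple[BiomarkerMap, dict, dict]:
    """Relabel exposure and biomarker ids to consecutive integers from 1.

    Labels are assigned in first-appearance order.  Already-numeric maps are
    returned unchanged with identity lookup tables, making the operation
    idempotent.

    Returns
    -------
    (numeric_map, exposure_lookup, biomarker_lookup)
        The lookup dicts map original labels to the assigned integers and
        allow round-tripping back to the original identifiers.
    """
    if bmap.is_numeric:
        exp_lookup = {int(e): int(e) for e in bmap.exposure_ids}
        bio_lookup = {int(b): int(b) for b in bmap.biomarker_ids}
        df = bmap.table.copy()
        df["exposure_id"] = df["exposure_id"].astype(int)
        df["biomarker_id"] = df["biomarker_id"].astype(int)
        return BiomarkerMap(df), exp_lookup, bio_lookup

    exp_lookup = {e: k + 1 for k, e in enumerate(bmap.exposure_ids)}
    bio_lookup = {b: k + 1 for k, b in enumerate(bmap.biomarker_ids)}
    df = bmap.table.copy()
    df["exposure_id"] = df["exposure_id"].map(exp_lookup).astype(int)
    df["biomarker_id"] = df["biomarker_id"].map(bio_lookup).astype(int)
    return BiomarkerMap(df), exp_lookup, bio_lookup
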