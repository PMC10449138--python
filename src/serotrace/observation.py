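"""Observation models: from latent biomarker quantities to assay readouts.

An assay reports the latent quantity ``A`` with Gaussian noise, imperfect
sensitivity and specificity, optional limits of detection, and optionally a
discretized (dilution-style) output:

* a true positive (``A > 0``) is reported as ``Normal(A, noise_sd)`` with
  probability ``sensitivity`` (then clamped into the detection limits), and
  as a false negative of exactly 0 otherwise — even when a lower limit above
  0 exists, the false-negative code stays 0;
* a true negative (``A = 0``) is reported as 0 with probability
  ``specificity``, and otherwise as a false positive drawn uniformly from
  the observable range (which therefore must be given whenever
  ``specificity < 1`` and negatives are sampled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import Demography
from .errors import ConfigurationError, InvalidInputError

_OBSERVED_COLUMNS = ("i", "t", "b", "observed")


@dataclass(frozen=True)
class AssaySpec:
    """Assay characteristics: noise, sensitivity/specificity and bounds."""

    noise_sd: float = 0.0
    sensitivity: float = 1.0
    specificity: float = 1.0
    lower_bound: float | None = None
    upper_bound: float | None = None
    output: str = "continuous"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        for name in ("sensitivity", "specificity"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1]")
        if (self.lower_bound is not None and self.upper_bound is not None
                and not self.lower_bound < self.upper_bound):
            raise InvalidInputError("lower_bound must be < upper_bound")
        if self.output not in ("continuous", "discrete"):
            raise InvalidInputError("output must be 'continuous' or 'discrete'")

    @property
    def has_bounds(self) -> bool:
        return self.lower_bound is not None and self.upper_bound is not None


def _observe_array(A: np.ndarray, spec: AssaySpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorized core of the continuous-noise observation model."""
    if np.nanmin(A, initial=0.0) < 0:
        raise InvalidInputError("latent quantities must be >= 0")
    Y = np.full(A.shape, np.nan)
    valid = ~np.isnan(A)
    pos = valid & (A > 0)
    neg = valid & (A == 0)

    # true positives: detected with prob sensitivity, else reported 0
    detected = rng.random(A.shape) < spec.sensitivity
    noise = rng.normal(0.0, spec.noise_sd, size=A.shape) if spec.noise_sd > 0 \
        else np.zeros(A.shape)
    y_pos = A + noise
    if spec.lower_bound is not None:
        y_pos = np.maximum(y_pos, spec.lower_bound)
    if spec.upper_bound is not None:
        y_pos = np.minimum(y_pos, spec.upper_bound)
    Y[pos] = np.where(detected[pos], y_pos[pos], 0.0)

    # true negatives: reported 0 with prob specificity, else a uniform
    # false positive over the observable range
    if neg.any():
        fp = rng.random(A.shape) >= spec.specificity
        fp &= neg
        Y[neg] = 0.0
        if fp.any():
            if not spec.has_bounds:
                raise ConfigurationError(
                    "specificity < 1 requires lower and upper bounds to "
                    "sample false positives from")
            Y[fp] = rng.uniform(spec.lower_bound, spec.upper_bound,
                                size=int(fp.sum()))
    return Y


def _maybe_scalar(Y: np.ndarray, scalar: bool):
    return float(Y.item()) if scalar else Y


def observation_model_continuous_noise(A, spec: AssaySpec,
                                       rng: np.random.Generator):
    """Continuous assay with Gaussian noise; accepts scalars or arrays."""
    arr = np.asarray(A, dtype=float)
    scalar = arr.ndim == 0
    return _maybe_scalar(_observe_array(np.atleast_1d(arr), spec, rng), scalar)


def observation_model_discrete_noise(A, spec: AssaySpec,
                                     rng: np.random.Generator):
    """Discrete assay: continuous observation, then floor-and-clamp.

    Non-zero readouts are floored to integers and clamped into
    ``[floor(lower_bound), floor(upper_bound)]``; zero results (true and
    false negatives) stay exactly 0.  Both bounds are required.
    """
    if not spec.has_bounds:
        raise ConfigurationError("discrete assay requires lower and upper bounds")
    arr = np.asarray(A, dtype=float)
    scalar = arr.ndim == 0
    Y = _observe_array(np.atleast_1d(arr), spec, rng)
    nonzero = ~np.isnan(Y) & (Y != 0)
    lo, hi = np.floor(spec.lower_bound), np.floor(spec.upper_bound)
    Y[nonzero] = np.clip(np.floor(Y[nonzero]), lo, hi)
    return _maybe_scalar(Y, scalar)


def apply_observation_design(
    latent,
    design: pd.DataFrame | None,
    model,
    spec: AssaySpec,
    rng: np.random.Generator,
    demography: Demography | None = None,
) -> pd.DataFrame:
    """Sample the latent biomarker grid according to a survey design.

    Parameters
    ----------
    latent:
        A :class:`~serotrace.engine.BiomarkerStates` (NaN marks inactive
        individual-times).
    design:
        DataFrame with columns ``i, t, b``; ``None`` observes every
        biomarker of every individual at every time step.
    model:
        One of the observation-model callables ``(A, spec, rng) -> Y``.

    Returns
    -------
    DataFrame with columns ``i, t, b, observed``; rows for inactive
    individuals carry NaN (the absent sentinel).
    """
    n, n_times, n_bio = latent.values.shape
    t0 = latent.t_start
    if design is None:
        i_idx, t_idx, b_idx = np.meshgrid(
            np.arange(1, n + 1), np.arange(t0, t0 + n_times),
            np.arange(1, n_bio + 1), indexing="ij")
        design = pd.DataFrame({"i": i_idx.ravel(), "t": t_idx.ravel(),
                               "b": b_idx.ravel()})
    for col in ("i", "t", "b"):
        if col not in design.columns:
            raise InvalidInputError(f"observation design lacks column {col!r}")
    ii = design["i"].to_numpy(dtype=int)
    tt = design["t"].to_numpy(dtype=int)
    bb = design["b"].to_numpy(dtype=int)
    if ((ii < 1) | (ii > n) | (tt < t0) | (tt >= t0 + n_times)
            | (bb < 1) | (bb > n_bio)).any():
        raise InvalidInputError("observation design row outside simulated range")
    A = latent.values[ii - 1, tt - t0, bb - 1]
    Y = np.full(A.shape, np.nan)
    active = ~np.isnan(A)
    if active.any():
        Y[active] = np.atleast_1d(model(A[active], spec, rng))
    return pd.DataFrame({"i": ii, "t": tt, "b": bb, "observed": Y})
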