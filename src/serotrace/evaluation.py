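"""Seropositivity-threshold evaluation.

Because the simulator knows each individual's true exposure history, it can
score any seropositivity threshold against the truth: run replicate
simulations, label every sampled individual as truly infected (at least one
successful infection-type event at or before the sampling time) or not, and
classify them by ``Y >= threshold``.  Pooling the confusion matrices across
replicates yields the sensitivity and specificity of each threshold.

Vaccination does not count as truth-positive: the sweep scores thresholds
for *identifying infections*, so vaccinated-but-uninfected individuals with
high titers exert false-positive pressure — exactly the trade-off that makes
the specificity-versus-threshold curve interesting.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationOutputs
from .errors import InvalidInputError


def classify_serostatus(Y, threshold: float):
    """Seropositive iff ``Y >= threshold`` (ties count as positive)."""
    if not np.isfinite(threshold):
        raise InvalidInputError("threshold must be finite")
    arr = np.asarray(Y, dtype=float)
    result = arr >= threshold
    return bool(result) if arr.ndim == 0 else result


def _truth_labels(outputs: SimulationOutputs,
                  infection_exposures: Sequence[int]) -> pd.DataFrame:
    """Observed rows plus a truth column: infected at or before sampling."""
    obs = outputs.observed[outputs.observed["observed"].notna()].copy()
    z = outputs.immune_history
    t0 = outputs.t_start
    truth = np.zeros(len(obs), dtype=bool)
    for k, (i, t) in enumerate(zip(obs["i"].to_numpy(dtype=int),
                                   obs["t"].to_numpy(dtype=int))):
        for x in infection_exposures:
            zi = z[i - 1, : t - t0 + 1, x - 1]
            if np.nansum(zi) > 0:
                truth[k] = True
                break
    obs["truly_infected"] = truth
    return obs


def threshold_sweep(
    sim_config,
    thresholds: Sequence[float],
    n_replicates: int,
    rng_seed: int = 0,
    infection_exposures: Sequence[int] = (1,),
) -> pd.DataFrame:
    """Sweep seropositivity thresholds over replicate simulations.

    Parameters
    ----------
    sim_config:
        Either a :class:`~serotrace.config.RunConfig` or a callable
        ``seed -> SimulationOutputs`` that runs one replicate.
    thresholds:
        Observed-quantity cutoffs to score.
    n_replicates:
        Number of independent simulations; replicate seeds are derived
        deterministically from ``rng_seed``.
    infection_exposures:
        Exposure-type ids counted as true infections.

    Returns
    -------
    Tidy DataFrame with columns ``threshold, replicate, tp, tn, fp, fn,
    sensitivity, specificity``; one row per (threshold, replicate) plus a
    pooled (micro-averaged) row per threshold with ``replicate = "pooled"``.
    """
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    thresholds = list(thresholds)
    if not thresholds:
        raise InvalidInputError("at least one threshold is required")

    if callable(sim_config):
        simulate: Callable[[int], SimulationOutputs] = sim_config
    else:
        from .config import run_from_config
        simulate = lambda seed: run_from_config(sim_config, seed=seed)  # noqa: E731

    seeds = np.random.SeedSequence(rng_seed).generate_state(n_replicates)
    seeds = (seeds % np.uint32(2 ** 31)).astype(int)

    records = []
    totals = {thr: np.zeros(4, dtype=int) for thr in thresholds}  # tp,tn,fp,fn
    any_observed = False
    for rep, seed in enumerate(seeds, start=1):
        outputs = simulate(int(seed))
        labeled = _truth_labels(outputs, infection_exposures)
        if len(labeled) == 0:
            continue
        any_observed = True
        y = labeled["observed"].to_numpy(dtype=float)
        truth = labeled["truly_infected"].to_numpy(dtype=bool)
        for thr in thresholds:
            called = classify_serostatus(y, thr)
            tp = int((called & truth).sum())
            tn = int((~called & ~truth).sum())
            fp = int((called & ~truth).sum())
            fn = int((~called & truth).sum())
            totals[thr] += (tp, tn, fp, fn)
            records.append(_record(thr, rep, tp, tn, fp, fn))
    if not any_observed:
        raise InvalidInputError("no observed individuals in any replicate")
    for thr in thresholds:
        tp, tn, fp, fn = totals[thr]
        records.append(_record(thr, "pooled", tp, tn, fp, fn))
    return pd.DataFrame.from_records(records)


def _record(thr, rep, tp, tn, fp, fn) -> dict:
    sens = tp / (tp + fn) if tp + fn > 0 else np.nan
    spec = tn / (tn + fp) if tn + fp > 0 else np.nan
    return {"threshold": thr, "replicate": rep, "tp": tp, "tn": tn,
            "fp": fp, "fn": fn, "sensitivity": sens, "specificity": spec}
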