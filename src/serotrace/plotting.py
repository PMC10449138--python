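"""Minimal visualizations of the long output tables."""

from __future__ import annotations

import numpy as np

from .engine import SimulationOutputs


def plot_biomarker_trajectories(outputs: SimulationOutputs, biomarker: int = 1,
                                ax=None):
    """Latent biomarker trajectories, one line per individual."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    A = outputs.biomarker_states.values[:, :, biomarker - 1]
    t = np.arange(outputs.t_start, outputs.t_start + A.shape[1])
    for row in A:
        ax.plot(t, row, lw=0.6, alpha=0.5)
    ax.set_xlabel("time step")
    ax.set_ylabel(f"latent quantity, biomarker {biomarker}")
    return ax


def plot_immune_history_heatmap(outputs: SimulationOutputs, exposure: int = 1,
                                ax=None):
    """Immune-history heatmap (individual x time); NaN = not yet active."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    z = outputs.immune_history[:, :, exposure - 1]
    t0 = outputs.t_start
    im = ax.imshow(z, aspect="auto", interpolation="none",
                   extent=(t0 - 0.5, t0 + z.shape[1] - 0.5,
                           z.shape[0] + 0.5, 0.5))
    ax.figure.colorbar(im, ax=ax, label="successful exposure")
    ax.set_xlabel("time step")
    ax.set_ylabel("individual")
    return ax
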