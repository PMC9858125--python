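"""Convenience trajectory plots (requires the ``plot`` extra / matplotlib)."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .experiments import ci_band


def plot_fitness_bands(series_by_label, ax=None, level: float = 0.95, ylabel="best fitness"):
    """Mean trajectory with a confidence band per condition.

    ``series_by_label`` maps a label to a ``(repeats, generations)`` matrix.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, matrix in series_by_label.items():
        mean, lo, hi = ci_band(np.asarray(matrix), level=level)
        x = np.arange(1, mean.size + 1)
        (line,) = ax.plot(x, mean, label=label)
        ax.fill_between(x, lo, hi, alpha=0.25, color=line.get_color())
    ax.set_xlabel("generation")
    ax.set_ylabel(ylabel)
    ax.legend()
    return ax


def plot_competency_trajectory(result, ax=None):
    """Best-individual competency gene over time for an evolvable suite."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mean, lo, hi = ci_band(result.best_competency)
    x = np.arange(1, mean.size + 1)
    ax.plot(x, mean, color="tab:purple")
    ax.fill_between(x, lo, hi, alpha=0.25, color="tab:purple")
    ax.set_xlabel("generation")
    ax.set_ylabel("best competency gene")
    return ax
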