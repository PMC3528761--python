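"""Minimal plotting helpers for scenario outputs."""

from __future__ import annotations

import numpy as np


def plot_female_series(results, release_start: int, ax=None, **kwargs):
    """Daily adult-female counts for a set of replicates (mean ± envelope)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    series = np.vstack([r.female_series for r in results])
    days = np.arange(series.shape[1]) - release_start
    ax.fill_between(days, series.min(axis=0), series.max(axis=0), alpha=0.25, **kwargs)
    ax.plot(days, series.mean(axis=0), **kwargs)
    ax.axvline(0, color="k", lw=0.5, ls="--")
    ax.set_xlabel("days since release start")
    ax.set_ylabel("adult females")
    return ax


def plot_sweep(table, ax=None, **kwargs):
    """Elimination proportion ± SE against weekly release level."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        table.index,
        table["elimination_proportion"],
        yerr=table["elimination_se"],
        marker="o",
        **kwargs,
    )
    ax.set_xlabel("released males per site per week")
    ax.set_ylabel("proportion of replicates eliminated")
    ax.set_ylim(-0.05, 1.05)
    return ax
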