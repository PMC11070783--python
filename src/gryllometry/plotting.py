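"""Matplotlib renderings of actograms, periodograms and Q-Q diagnostics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .io import DAY_MIN
from .posture import normality_check
from .rhythm import Periodogram


def plot_actogram(matrix: np.ndarray, title: str = "", ax=None):
    """Render a double-plotted actogram matrix (days x 2880 minutes)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.35 * len(matrix) + 1))
    n_days = matrix.shape[0]
    binarised = np.nan_to_num(matrix, nan=0.0)
    for d in range(n_days):
        events = np.flatnonzero(binarised[d] > 0)
        ax.vlines(events / 60.0, n_days - d - 1, n_days - d - 0.15, lw=0.4, color="k")
    ax.set_xlim(0, 48)
    ax.set_ylim(0, n_days)
    ax.set_xticks(range(0, 49, 12))
    ax.set_xlabel("Zeitgeber Time (h, double-plotted)")
    ax.set_ylabel("day")
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    return ax


def plot_periodogram(pg: Periodogram, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(pg.periods / 60.0, pg.statistic, lw=1, label=pg.method)
    ax.plot(pg.periods / 60.0, pg.threshold, lw=1, ls="--", color="r",
            label=f"alpha={pg.alpha} ({pg.correction})")
    ax.axvline(pg.peak_period / 60.0, color="grey", lw=0.5)
    ax.set_xlabel("period (h)")
    ax.set_ylabel("statistic")
    ax.legend(fontsize=8)
    return ax


def plot_qq(values, ax=None):
    """Normal Q-Q plot of an angle sample."""
    res = normality_check(values)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if res["degenerate"]:
        ax.text(0.5, 0.5, "degenerate sample", ha="center")
        return ax
    qq = res["qq"]
    ax.plot(qq[:, 0], qq[:, 1], ".", ms=2)
    lims = [qq[:, 1].min(), qq[:, 1].max()]
    mean, sd = np.mean(values), np.std(values, ddof=1)
    ax.plot(qq[:, 0], mean + sd * qq[:, 0], "r-", lw=1)
    ax.set_xlabel("theoretical quantiles")
    ax.set_ylabel("sample quantiles")
    ax.set_ylim(lims)
    return ax
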