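"""Figure helpers: rate series, stratified series, duration distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_rate_series", "plot_duration_proportions", "plot_median_duration"]


def plot_rate_series(series: pd.DataFrame, path, title: str = "", ylabel: str = "rate per 1000 PY"):
    """Line plot of one or more rate series, one line per stratum."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for stratum, sub in series.groupby("stratum"):
        ax.plot(sub["year"], sub["rate_per_1000py"], marker="o", ms=3, label=str(stratum))
    ax.set_xlabel("year")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    if series["stratum"].nunique() > 1:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_duration_proportions(proportions: pd.DataFrame, path, title: str = ""):
    """Stacked-area chart of duration-category proportions by start year."""
    wide = proportions.pivot(index="start_year", columns="category", values="proportion").fillna(0)
    # preserve the natural short-to-long ordering present in the input
    order = proportions["category"].drop_duplicates().tolist()
    wide = wide[[c for c in order if c in wide.columns]]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.stackplot(wide.index, [wide[c] for c in wide.columns], labels=list(wide.columns))
    ax.set_xlabel("start year")
    ax.set_ylabel("proportion of incident episodes")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_median_duration(medians: pd.DataFrame, path, title: str = ""):
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(medians["start_year"], medians["median_duration_days"], marker="o")
    ax.set_xlabel("start year")
    ax.set_ylabel("median episode duration (days)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
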