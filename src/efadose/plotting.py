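"""Small plotting helpers for time courses and dose-response tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .simulate import TimeCourse

__all__ = ["plot_timecourse", "plot_dose_response"]


def plot_timecourse(tc: TimeCourse, species: list[str] | None = None, ax=None, logy: bool = True):
    """Concentration trajectories vs. time (dosing events as dotted lines)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    ids = species if species is not None else [sp.id for sp in tc.network.species]
    for sid in ids:
        ax.plot(tc.times / 24.0, tc.trace(sid), label=sid)
    for t_ev, _ in tc.events:
        ax.axvline(t_ev / 24.0, color="grey", ls=":", lw=0.7)
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("concentration (nM)")
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_dose_response(table: pd.DataFrame, threshold: float | None = None, ax=None):
    """Criterion metric vs. dose on a log-dose axis, one line per metric
    column of a dose-response table."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    cols = [c for c in table.columns if c.startswith("value")]
    for col in cols:
        label = col.removeprefix("value").lstrip("_") or table["metric"].iloc[0]
        ax.plot(table["dose_mg"], table[col], marker="o", ms=3, label=label)
    if threshold is not None:
        ax.axhline(threshold, color="k", ls="--", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("dose (mg)")
    ax.set_ylabel("metric (%)")
    ax.legend(fontsize=8)
    return ax
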