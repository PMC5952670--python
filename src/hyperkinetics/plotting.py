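"""Static figure helpers: trace panels, recovery curves, line rankings,
and the migration/recovery correlation scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort import CellLineProfile, CorrelationResult
from .kinetics import RecoveryResults
from .ratio import RatioTrace

__all__ = [
    "plot_ratio_traces",
    "plot_recovery_fit",
    "plot_pooled_recovery",
    "plot_line_ranking",
    "plot_migration_correlation",
]


def plot_ratio_traces(traces: list[RatioTrace], schedule=None, ax=None,
                      max_traces: int = 20):
    """Overlay per-cell ratio traces; pulse windows shaded if a schedule
    is given."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for rt in traces[:max_traces]:
        ax.plot(rt.time_min, rt.ratio, lw=0.8, alpha=0.7)
    if schedule is not None:
        for t0, t1, conc in schedule.pulses:
            ax.axvspan(t0, t1, color="0.85", zorder=0)
            ax.text(0.5 * (t0 + t1), ax.get_ylim()[1], f"{conc:g} µM",
                    ha="center", va="bottom", fontsize=8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("ratio F490/F420")
    return ax


def plot_recovery_fit(res: RecoveryResults, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(res.model.t, res.model.y, "o", ms=3, label="data")
    tt = np.linspace(res.model.t[0], res.model.t[-1], 200)
    ax.plot(tt, res.predict(tt), "-", label=f"fit: k={res.k:.3g}/min, r={res.r:.3f}")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("signal (% of dynamic range)")
    ax.legend(frameon=False)
    return ax


def plot_pooled_recovery(curve: pd.DataFrame, ax=None, label=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(curve["time_min"], curve["mean"], yerr=curve["se"], fmt="o-",
                ms=3, capsize=2, label=label)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("signal (% of dynamic range)")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_line_ranking(profiles: list[CellLineProfile],
                      metric: str = "recovery_rate_mean", ax=None):
    """Bar chart of per-line values sorted lowest to highest."""
    se_attr = metric.replace("_mean", "_se")
    prof = sorted(profiles, key=lambda p: getattr(p, metric))
    names = [p.line for p in prof]
    vals = [getattr(p, metric) for p in prof]
    errs = [getattr(p, se_attr, 0.0) for p in prof]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.bar(names, vals, yerr=errs, capsize=3, color="0.6")
    ax.set_ylabel(metric.replace("_", " "))
    ax.tick_params(axis="x", rotation=60)
    return ax


def plot_migration_correlation(rates, efficiencies, labels,
                               corr: CorrelationResult | None = None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    rates = np.asarray(rates, dtype=float)
    ax.plot(rates, efficiencies, "o")
    for x, y, lab in zip(rates, efficiencies, labels):
        ax.annotate(lab, (x, y), fontsize=7, xytext=(3, 3),
                    textcoords="offset points")
    if corr is not None:
        xx = np.linspace(rates.min(), rates.max(), 50)
        ax.plot(xx, corr.intercept + corr.slope * xx, "-",
                label=f"r={corr.pearson_r:.2f}, p={corr.p_value:.3g}")
        ax.legend(frameon=False)
    ax.set_xlabel("recovery rate (1/min)")
    ax.set_ylabel("migration efficiency (%)")
    return ax
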