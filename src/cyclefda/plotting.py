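"""Matplotlib views of cohort curves, summary bands and lag overlays."""

from __future__ import annotations

import numpy as np

from .summaries import SummaryCurve

__all__ = ["plot_cohort", "plot_summary_curve", "plot_lag_overlay"]


def _ax(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(7, 4))
    return ax


def plot_cohort(series, hormone: str, ax=None):
    """Raw day-indexed curves of a cohort, one line per cycle."""
    ax = _ax(ax)
    for cyc in series:
        ax.plot(cyc.day_index, cyc.values(hormone), marker="o", ms=3,
                label=cyc.cycle_id)
    ax.axvline(0, color="tab:pink", lw=1)
    ax.set_xlabel("day index (0 = ovulatory inhibin B peak)")
    ax.set_ylabel(hormone)
    ax.legend(fontsize=8)
    return ax


def plot_summary_curve(curve: SummaryCurve, ax=None):
    """Cross-sectional mean with its percentile-bootstrap band."""
    ax = _ax(ax)
    ax.plot(curve.day_index, curve.mean, lw=2, label=f"mean {curve.hormone}")
    if curve.ci_lower is not None:
        ax.fill_between(
            curve.day_index, curve.ci_lower, curve.ci_upper, alpha=0.25,
            label="95% CI",
        )
    ax.axvline(0, color="tab:pink", lw=1)
    ax.set_xlabel("day index")
    ylab = curve.hormone + (" (z)" if curve.standardized else "")
    ax.set_ylabel(ylab)
    ax.legend(fontsize=8)
    return ax


def plot_lag_overlay(leader: SummaryCurve, follower: SummaryCurve,
                     lag: int = 1, ax=None):
    """Leader curve translated forward by ``lag`` over the follower curve."""
    ax = _ax(ax)
    ax.plot(
        np.asarray(leader.day_index) - lag, leader.mean, lw=2,
        label=f"{leader.hormone}(t+{lag})",
    )
    ax.plot(follower.day_index, follower.mean, lw=2,
            label=f"{follower.hormone}(t)")
    ax.axvline(0, color="tab:pink", lw=1)
    ax.set_xlabel("day index")
    ax.set_ylabel("standardized level" if leader.standardized else "level")
    ax.legend(fontsize=8)
    return ax
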