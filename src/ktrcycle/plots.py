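"""Optional plotting helpers (PNG/SVG) for the report tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort_stats import AlignedMatrix, CumulativeCurve


def plot_cumulative_curves(curves: list[CumulativeCurve], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for c in curves:
        ax.plot(c.times, c.fraction, label=c.event_name)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cumulative fraction of cells")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_aligned_median(summary: pd.DataFrame, path: str | Path, label: str = "") -> None:
    """Median with 95% CI band from :func:`median_with_ci` output."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(summary["relative_time"], summary["ci_lo"], summary["ci_hi"],
                    alpha=0.3, lw=0)
    ax.plot(summary["relative_time"], summary["median"], label=label or None)
    ax.set_xlabel("time relative to anchor (h)")
    ax.set_ylabel("activity")
    if label:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_stress_bins(bins: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    sel = bins["n"] > 0
    ax.bar(np.arange(sel.sum()), 100 * bins.loc[sel, "fraction_low"],
           tick_label=[f"{lo:.2f}" for lo in bins.loc[sel, "bin_lo"]])
    ax.set_xlabel("CDK2 activity at stress addition")
    ax.set_ylabel("% cells inactivating CDK2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phase_plane(traj: pd.DataFrame, path: str | Path) -> None:
    """CDK2 vs corrected CDK4/6 trajectory, time color-coded."""
    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    sc = ax.scatter(traj["cdk46_corrected_median"], traj["cdk2_median"],
                    c=traj["time"], cmap="viridis", s=14)
    fig.colorbar(sc, ax=ax, label="time (h)")
    ax.set_xlabel("corrected CDK4/6 activity (median)")
    ax.set_ylabel("CDK2 activity (median)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
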