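"""Matplotlib figures for the standard outputs of the pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["dynamic_signal_plot", "bland_altman_plot", "error_distribution_plot"]


def dynamic_signal_plot(timeseries: pd.DataFrame, metric_name: str = "IQM"):
    """Dynamic-signal figure: M/J0/J45 traces plus the normalized metric,
    with the selected top-quantile frames highlighted."""
    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(8, 8))
    sel = timeseries["selected"].to_numpy()
    for ax, comp in zip(axes[:3], ("M", "J0", "J45")):
        ax.plot(timeseries["time"], timeseries[comp], "-", color="0.4", lw=0.8)
        ax.plot(timeseries["time"][sel], timeseries[comp][sel], "o", ms=4, color="tab:orange")
        ax.set_ylabel(f"{comp} (D)")
    ax = axes[3]
    ax.plot(timeseries["time"], timeseries["metric_norm"], "-", color="0.4", lw=0.8)
    ax.plot(timeseries["time"][sel], timeseries["metric_norm"][sel], "o", ms=4, color="tab:orange")
    ax.set_ylabel(f"{metric_name} (norm.)")
    ax.set_xlabel("time (s)")
    fig.tight_layout()
    return fig


def bland_altman_plot(table: pd.DataFrame):
    """Bland–Altman scatter with bias and 95 % limit lines."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.plot(table["mean"], table["difference"], "o", ms=4, alpha=0.7)
    for key, style in (("bias", "-"), ("loa_low", "--"), ("loa_high", "--")):
        ax.axhline(table.attrs[key], color="k", ls=style, lw=1)
    comp = table.attrs.get("component", "M")
    ax.set_xlabel(f"mean of methods, {comp} (D)")
    ax.set_ylabel(f"difference, {comp} (D)")
    fig.tight_layout()
    return fig


def error_distribution_plot(dist: dict[str, pd.DataFrame]):
    """Before/after error histograms per power-vector component."""
    fig, axes = plt.subplots(1, len(dist), figsize=(4 * len(dist), 4), squeeze=False)
    for ax, (comp, df) in zip(axes[0], dist.items()):
        width = 0.4 * (df["bin_center"].iloc[1] - df["bin_center"].iloc[0]) if len(df) > 1 else 0.1
        ax.bar(df["bin_center"] - width / 2, df["count_before"], width=width, label="before")
        ax.bar(df["bin_center"] + width / 2, df["count_after"], width=width, label="after")
        ax.set_xlabel(f"Δ{comp} (D)")
        ax.set_ylabel("eyes")
        ax.legend()
    fig.tight_layout()
    return fig
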