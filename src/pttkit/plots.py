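"""Minimal plotting: curve pairs and empirical ROC curves (PNG)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .curves import TimeSignalCurve
from .diagnostics import roc_auc, roc_curve_points
from .ptt import PTTMeasurement

__all__ = ["plot_curve_pair", "plot_roc"]


def plot_curve_pair(
    rv: TimeSignalCurve, lv: TimeSignalCurve, path, measurement: PTTMeasurement | None = None
) -> None:
    """Plot RV/LV time–signal curves, marking detected first-pass peaks."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(rv.times, rv.values, "o-", ms=3, label="RV", color="tab:blue")
    ax.plot(lv.times, lv.values, "o-", ms=3, label="LV", color="tab:red")
    if measurement is not None:
        for peak, color in ((measurement.rv_peak, "tab:blue"), (measurement.lv_peak, "tab:red")):
            ax.axvline(peak.peak_time, color=color, ls="--", lw=1)
        ax.set_title(f"PTT = {measurement.ptt_s:.2f} s, nPTT = {measurement.nptt:.2f}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("signal (a.u.)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(scores, labels, path) -> None:
    """Plot the empirical ROC curve with its AUC."""
    pts = roc_curve_points(scores, labels)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(pts["fpr"], pts["tpr"], "-", color="tab:blue")
    ax.plot([0, 1], [0, 1], ":", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc_auc(scores, labels):.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
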