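"""Plotting helpers for the evaluation battery (K-M, ROC, calibration,
decision curves).  Each function draws onto a fresh figure and returns it;
callers save with ``fig.savefig(path)``."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .survstats import KMCurve, TimeROC

__all__ = ["plot_km", "plot_time_roc", "plot_calibration",
           "plot_decision_curve"]


def _step(ax, curve: KMCurve, label=None):
    x = np.concatenate([[0.0], curve.times])
    y = np.concatenate([[1.0], curve.survival])
    ax.step(x, y, where="post", label=label)


def plot_km(curves: dict, title: str = "BCR-free survival"):
    """Kaplan-Meier curves; ``curves`` maps label -> KMCurve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        _step(ax, c, label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    return fig


def plot_time_roc(roc: TimeROC):
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    fpr = 1.0 - roc.specificity
    order = np.argsort(fpr)
    ax.plot(fpr[order], roc.sensitivity[order],
            label=f"AUC({roc.horizon:g} mo) = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_calibration(table, title: str = "calibration"):
    """``table`` rows: (group, n, mean predicted, observed fraction)."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    pred = [r[2] for r in table]
    obs = [r[3] for r in table]
    ax.plot(pred, obs, "o-")
    lim = max(max(pred), max(obs)) * 1.05
    ax.plot([0, lim], [0, lim], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("predicted event probability")
    ax.set_ylabel("observed event fraction")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_decision_curve(dca: dict):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(dca["thresholds"], dca["net_benefit"], label="model")
    ax.plot(dca["thresholds"], dca["treat_all"], ls="--", label="treat all")
    ax.plot(dca["thresholds"], dca["treat_none"], ls=":",
            label="treat none")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=min(-0.02, dca["net_benefit"].min() - 0.02))
    ax.legend()
    fig.tight_layout()
    return fig
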