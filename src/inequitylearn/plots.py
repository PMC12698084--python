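"""Plotting helpers (matplotlib): learning curves and recovery scatters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .task import OFFER_LABELS


def plot_learning_curves(
    observed: pd.DataFrame | None = None,
    predicted: pd.DataFrame | None = None,
    teacher_reject_prob: dict | None = None,
    ax_grid=None,
):
    """Rejection-rate curves per offer type and condition.

    Thin lines: observed (simulated-participant) choices; thick lines:
    model predictions; dashed horizontal lines: the Teacher's rejection
    preference. Both inputs use the curve schema (condition, offer_type,
    type_trial, mean_reject).
    """
    conditions = sorted(
        set()
        | (set(observed["condition"]) if observed is not None else set())
        | (set(predicted["condition"]) if predicted is not None else set())
    )
    fig, axes = plt.subplots(
        len(conditions), len(OFFER_LABELS), figsize=(3 * len(OFFER_LABELS), 2.5 * len(conditions)),
        sharey=True, squeeze=False,
    )
    for i, cond in enumerate(conditions):
        for j, lab in enumerate(OFFER_LABELS):
            ax = axes[i][j]
            if observed is not None:
                sel = observed[(observed["condition"] == cond) & (observed["offer_type"] == lab)]
                ax.plot(sel["type_trial"], sel["mean_reject"], lw=1, color="C0", label="observed")
            if predicted is not None:
                sel = predicted[(predicted["condition"] == cond) & (predicted["offer_type"] == lab)]
                ax.plot(sel["type_trial"], sel["mean_reject"], lw=2.5, color="C1", label="model")
            if teacher_reject_prob and cond in teacher_reject_prob:
                ax.axhline(teacher_reject_prob[cond].get(lab), ls="--", color="gray", lw=1)
            ax.set_ylim(-0.05, 1.05)
            if i == 0:
                ax.set_title(lab)
            if j == 0:
                ax.set_ylabel(f"{cond}\nP(reject)")
    axes[-1][len(OFFER_LABELS) // 2].set_xlabel("trial within offer type")
    handles, labels = axes[0][0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="upper right")
    fig.tight_layout()
    return fig


def plot_recovery(pairs: pd.DataFrame):
    """True-vs-recovered scatter per parameter."""
    names = list(pairs["parameter"].unique())
    fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 3), squeeze=False)
    for ax, name in zip(axes[0], names):
        sel = pairs[pairs["parameter"] == name]
        ax.scatter(sel["true"], sel["recovered"], s=8, alpha=0.5)
        lo = min(sel["true"].min(), sel["recovered"].min())
        hi = max(sel["true"].max(), sel["recovered"].max())
        ax.plot([lo, hi], [lo, hi], ls="--", color="gray", lw=1)
        ax.set_title(name)
        ax.set_xlabel("true")
    axes[0][0].set_ylabel("recovered")
    fig.tight_layout()
    return fig
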