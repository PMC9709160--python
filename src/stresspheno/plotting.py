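"""Simple diagnostic figures for the three analysis stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .motifs import TransitionMatrix
from .phenoscore import RocResult


def plot_roc(roc: RocResult, ax=None):
    """ROC curve with the chance diagonal and the Youden point marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(roc.fpr, roc.tpr, color="tab:blue", label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=1)
    i = int(np.argmax(roc.j))
    ax.plot([roc.fpr[i], roc.fpr[i]], [roc.fpr[i], roc.tpr[i]], color="tab:red",
            label=f"max J = {roc.max_j:.2f} @ {roc.youden_cutoff:.4g}")
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.set_title(roc.marker)
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_waveform_features(features: pd.DataFrame, ax=None):
    """Half-width vs trough-to-peak scatter, colored by assigned class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"MSN": "tab:gray", "interneuron": "tab:red"}
    for cls, sub in features.groupby(features.get("unit_class", "unclassified")):
        ax.scatter(sub["half_width_ms"], sub["trough_to_peak_ms"], s=12,
                   color=colors.get(cls, "tab:blue"), label=str(cls), alpha=0.7)
    ax.set_xlabel("half-width (ms)")
    ax.set_ylabel("trough-to-peak (ms)")
    ax.legend(fontsize=8)
    return ax


def plot_transition_matrix(tm: TransitionMatrix, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(tm.probs, cmap="viridis")
    ax.set_xlabel("to motif")
    ax.set_ylabel("from motif")
    ax.figure.colorbar(im, ax=ax, label="P(next | current)")
    return ax


def plot_community_usage(usage: pd.DataFrame, ax=None):
    """Mean community usage per (group, condition) as grouped bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    design = {"mouse_id", "group", "condition"}
    value_cols = [c for c in usage.columns if c not in design]
    means = usage.groupby(["group", "condition"])[value_cols].mean()
    x = np.arange(len(value_cols))
    width = 0.8 / max(len(means), 1)
    for i, (key, row) in enumerate(means.iterrows()):
        ax.bar(x + i * width, 100 * row.to_numpy(), width, label="/".join(key))
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(value_cols, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("usage (%)")
    ax.legend(fontsize=8)
    return ax
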