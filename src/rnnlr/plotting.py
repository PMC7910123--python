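"""Plotting helpers: learning curves, PR curves, attribution bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_learning_curve", "plot_pr_curves", "plot_attribution"]


def plot_learning_curve(history: pd.DataFrame, path) -> None:
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(history["epoch"], history["train_loss"], label="train loss")
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("training loss")
    if "val_mean_auc" in history:
        ax2 = ax1.twinx()
        ax2.plot(history["epoch"], history["val_mean_auc"], color="C1",
                 label="held-out mean AUC")
        ax2.set_ylabel("held-out mean AUC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pr_curves(curves: dict[str, list[tuple[float, float]]], path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, pts in curves.items():
        rec = [r for r, _ in pts]
        prec = [p for _, p in pts]
        ax.plot(rec, prec, label=label)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_attribution(table: pd.DataFrame, path, top: int = 20) -> None:
    sub = table.head(top).iloc[::-1]
    colors = {"clinical_indicator": "C0", "rnn_unit": "C1",
              "latent_regulator": "C2"}
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(sub) + 1))
    ax.barh(sub["feature"], sub["mean_abs_attribution"],
            color=[colors[g] for g in sub["group"]])
    ax.set_xlabel("mean |attribution|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
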