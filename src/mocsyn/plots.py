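"""Figure helpers: ROC curve, MDS embedding, E-I latency sweep summary."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_roc(roc_df, auc: float, path=None):
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc_df["fpr"], roc_df["tpr"], color="k")
    ax.plot([0, 1], [0, 1], ls=":", color="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"E/I classifier ROC (AUC = {auc:.3f})")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_mds(mds_df, path=None):
    fig, ax = plt.subplots(figsize=(4, 4))
    for label, g in mds_df.groupby("label"):
        ax.scatter(g["dim1"], g["dim2"], s=12, label=str(label), alpha=0.7)
    ax.legend(frameon=False)
    ax.set_xlabel("MDS dim 1")
    ax.set_ylabel("MDS dim 2")
    ax.set_title("RandomForest proximity (MDS)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_ei_sweep(sweep_df, weak_df=None, path=None):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(sweep_df["ei_diff_ms"], sweep_df["ap_rate_hz"], "o-", color="k",
            label="IPSP scale 1.0")
    if weak_df is not None:
        ax.plot(weak_df["ei_diff_ms"], weak_df["ap_rate_hz"], "s--",
                color="tab:purple", label="IPSP scale 0.51")
    ax.set_xlabel("E-I latency difference (ms)")
    ax.set_ylabel("AP rate (Hz)")
    ax.legend(frameon=False)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
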