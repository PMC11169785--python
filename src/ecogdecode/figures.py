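"""Optional renderings of the result CSVs.

Figures are conveniences over the exported tables, never the source of
truth: bar plots of per-feature accuracy and mean difference with 95%
CIs, participant-by-feature matrices, and incremental-ROI curves.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_feature_bars", "plot_meandiff_bars",
           "plot_participant_matrix", "plot_additivity_curves",
           "render_all"]


def _feature_order(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["roi", "band"]).reset_index(drop=True)


def plot_feature_bars(features: pd.DataFrame, chance: float | None,
                      path) -> None:
    df = _feature_order(features)
    x = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(max(8, 0.3 * len(df)), 4))
    err = np.vstack([df["mean_acc"] - df["ci95_lo"],
                     df["ci95_hi"] - df["mean_acc"]])
    ax.bar(x, df["mean_acc"], yerr=err, color="steelblue")
    for i, sig in enumerate(df["sig_acc"]):
        if sig:
            ax.annotate("*", (x[i], df["ci95_hi"].iloc[i] + 0.01),
                        ha="center", fontsize=11)
    if chance is not None:
        ax.axhline(chance, ls="--", color="k", lw=1, label="finite chance")
        ax.legend()
    ax.set_xticks(x)
    ax.set_xticklabels(df["roi"] + "\n" + df["band"], fontsize=6, rotation=90)
    ax.set_ylabel("classification accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_meandiff_bars(features: pd.DataFrame, path) -> None:
    df = _feature_order(features)
    x = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(max(8, 0.3 * len(df)), 4))
    ax.bar(x, df["mean_diff"], color="indianred")
    for i, sig in enumerate(df["sig_joint"]):
        if sig:
            ax.annotate("*", (x[i], df["mean_diff"].iloc[i]),
                        ha="center", color="darkred", fontsize=11)
    ax.axhline(0, color="k", lw=1)
    ax.set_xticks(x)
    ax.set_xticklabels(df["roi"] + "\n" + df["band"], fontsize=6, rotation=90)
    ax.set_ylabel("fitted mean difference (z-units)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_participant_matrix(table: pd.DataFrame, value: str, path) -> None:
    participants = sorted(table["participant"].unique())
    fig, axes = plt.subplots(1, len(participants),
                             figsize=(3.2 * len(participants), 3.2),
                             squeeze=False)
    for ax, p in zip(axes[0], participants):
        sub = table[table["participant"] == p].pivot(
            index="band", columns="roi", values=value)
        im = ax.imshow(sub.to_numpy(dtype=float), aspect="auto",
                       cmap="viridis")
        ax.set_title(f"participant {p}", fontsize=9)
        ax.set_xticks(range(len(sub.columns)))
        ax.set_xticklabels(sub.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(sub.index)))
        ax.set_yticklabels(sub.index, fontsize=6)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_additivity_curves(additivity: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for (p, band), sub in additivity.groupby(["participant", "band"]):
        sub = sub.sort_values("n_rois")
        ax.plot(sub["n_rois"], sub["accuracy"], marker="o",
                label=f"P{p} {band}")
    ax.set_xlabel("number of ROIs (best first)")
    ax.set_ylabel("test accuracy")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_all(outdir) -> list[str]:
    """Render every figure whose source CSV exists in ``outdir``."""
    outdir = Path(outdir)
    made = []
    feat = outdir / "features.csv"
    if feat.exists():
        df = pd.read_csv(feat)
        chance = None
        run = outdir / "run.json"
        if run.exists():
            import json
            chance = json.loads(run.read_text()).get("chance_level")
        plot_feature_bars(df, chance, outdir / "fig_accuracy.png")
        plot_meandiff_bars(df, outdir / "fig_meandiff.png")
        made += ["fig_accuracy.png", "fig_meandiff.png"]
    pacc = outdir / "participant_accuracy.csv"
    if pacc.exists():
        plot_participant_matrix(pd.read_csv(pacc), "accuracy",
                                outdir / "fig_participant_accuracy.png")
        made.append("fig_participant_accuracy.png")
    pdiff = outdir / "participant_meandiff.csv"
    if pdiff.exists():
        plot_participant_matrix(pd.read_csv(pdiff), "mean_diff",
                                outdir / "fig_participant_meandiff.png")
        made.append("fig_participant_meandiff.png")
    add = outdir / "additivity.csv"
    if add.exists():
        plot_additivity_curves(pd.read_csv(add), outdir / "fig_additivity.png")
        made.append("fig_additivity.png")
    return made
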