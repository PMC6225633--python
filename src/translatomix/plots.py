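"""Static report figures: volcano, multi-fraction heatmaps, regulation
scatter/barplot and the MDS QC plot.

Each figure is written in both vector (PDF) and raster (PNG) form, and the
plotted numbers are also written as a tab-delimited data file next to the
images so figures can be audited against the result tables.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .classify import CATEGORIES, Thresholds, select_significant

CATEGORY_COLORS = {
    "not_regulated": "#d62728",
    "transcription_only": "#2ca02c",
    "translation_only": "#9467bd",
    "both_same_direction": "#1f77b4",
    "opposite": "#ff7f0e",
}


def _save(fig: plt.Figure, stem: Path) -> list[Path]:
    paths = []
    for ext in ("pdf", "png"):
        path = stem.with_suffix(f".{ext}")
        fig.savefig(path, bbox_inches="tight", dpi=150)
        paths.append(path)
    plt.close(fig)
    return paths


def volcano(
    de: pd.DataFrame, thresholds: Thresholds, stem: Path, title: str = ""
) -> list[Path]:
    """logFC vs -log10 p with significant genes highlighted in blue."""
    pcol = thresholds.p_column
    sig = select_significant(de, thresholds)
    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(de[pcol])
    ax.scatter(de["logFC"], neglogp, s=4, c="0.7", label="not significant")
    if len(sig):
        ax.scatter(
            sig["logFC"], -np.log10(sig[pcol]), s=6, c="#1f77b4",
            label=f"significant (n={len(sig)})",
        )
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel(f"-log10 {'adj. ' if thresholds.use_adjusted else ''}p")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    de.to_csv(stem.with_suffix(".tsv"), sep="\t", float_format="%.6g")
    return _save(fig, stem)


def fraction_heatmap(data: pd.DataFrame, stem: Path, title: str = "") -> list[Path]:
    """Genes x fractions heatmap of log2 fold changes."""
    fig, ax = plt.subplots(figsize=(4, max(3, min(10, 0.02 * len(data) + 2))))
    if len(data):
        order = data.mean(axis=1).sort_values().index
        sns.heatmap(
            data.loc[order], cmap="RdBu_r", center=0, ax=ax,
            yticklabels=len(data) <= 40, cbar_kws={"label": "log2FC"},
        )
    else:
        ax.text(0.5, 0.5, "no significant genes", ha="center", va="center")
        ax.set_axis_off()
    ax.set_title(title)
    data.to_csv(stem.with_suffix(".tsv"), sep="\t", float_format="%.6g")
    return _save(fig, stem)


def regulation_scatter(calls: pd.DataFrame, stem: Path) -> list[Path]:
    """Transcription vs translation logFC colored by regulation category."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for cat in CATEGORIES:
        sub = calls[calls["category"] == cat]
        if len(sub) == 0:
            continue
        tl = sub["tl_logFC"].fillna(0.0)
        ax.scatter(
            sub["tx_logFC"], tl, s=6, c=CATEGORY_COLORS[cat],
            label=f"{cat} (n={len(sub)})", alpha=0.7,
        )
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("transcription log2FC")
    ax.set_ylabel("translation log2FC")
    ax.legend(frameon=False, fontsize=7)
    calls.to_csv(stem.with_suffix(".tsv"), sep="\t", float_format="%.6g")
    return _save(fig, stem)


def regulation_barplot(counts: pd.Series, stem: Path) -> list[Path]:
    """Number of genes per regulation category."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(
        counts.index, counts.to_numpy(),
        color=[CATEGORY_COLORS.get(c, "0.5") for c in counts.index],
    )
    ax.set_ylabel("genes")
    ax.tick_params(axis="x", rotation=30)
    counts.to_frame().to_csv(stem.with_suffix(".tsv"), sep="\t")
    return _save(fig, stem)


def mds_plot(coords: pd.DataFrame, groups: pd.Series | None, stem: Path) -> list[Path]:
    """2-D MDS of samples on leading-logFC distances, colored by group."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    if groups is None:
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=25)
    else:
        for grp in pd.unique(groups):
            sel = groups == grp
            ax.scatter(
                coords.loc[sel].iloc[:, 0], coords.loc[sel].iloc[:, 1],
                s=25, label=str(grp),
            )
        ax.legend(frameon=False, fontsize=8)
    for name, row in coords.iterrows():
        ax.annotate(str(name), (row.iloc[0], row.iloc[1]), fontsize=5, alpha=0.6)
    ax.set_xlabel("leading logFC dim 1")
    ax.set_ylabel("leading logFC dim 2")
    coords.to_csv(stem.with_suffix(".tsv"), sep="\t", float_format="%.6g")
    return _save(fig, stem)
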