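"""Plotting helpers (matplotlib, Agg backend).

All functions take pre-computed tables and write a PNG; nothing here computes
statistics. Waterfall plots render missing cells (reads with fewer CpGs than
the matrix width) as the background colour, distinct from a score of zero.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def _save(fig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)
    return path


def waterfall(matrix: pd.DataFrame, path, title: str = "") -> Path:
    """Reads-by-CpG heatmap, low scores white, high scores red."""
    fig, ax = plt.subplots(figsize=(8, max(2.0, 0.05 * len(matrix) + 1.5)))
    cmap = plt.get_cmap("Reds").copy()
    cmap.set_bad("#d9d9d9")
    masked = np.ma.masked_invalid(matrix.to_numpy(dtype=float))
    im = ax.imshow(masked, aspect="auto", cmap=cmap, vmin=0, vmax=255,
                   interpolation="nearest")
    ax.set_xlabel("CpG position within read (1-based ordinal)")
    ax.set_ylabel("reads (sorted by CpG count)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="5mC score (0-255)")
    return _save(fig, path)


def scatter_with_fit(x, y, path, xlabel="", ylabel="", title="") -> Path:
    """Scatterplot with an ordinary least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=25, color="#2c7fb8", alpha=0.85)
    if x.size >= 2 and np.ptp(x) > 0:
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, a + b * xs, color="#08306b")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.tight_layout()
    return _save(fig, path)


def allele_boxplot(sample_table: pd.DataFrame, value: str, path, ylabel="") -> Path:
    """Per-allele boxplot of a per-sample summary column."""
    groups = [g[value].dropna() for _, g in sample_table.groupby("allele")]
    labels = [str(a) for a, _ in sample_table.groupby("allele")]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(groups, tick_labels=labels)
    ax.set_ylabel(ylabel or value)
    fig.tight_layout()
    return _save(fig, path)


def longitudinal_dotplot(table: pd.DataFrame, value: str, path, ylabel="") -> Path:
    """Per-individual trajectories over timepoint_years."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for iid, grp in table.groupby("individual_id"):
        grp = grp.sort_values("timepoint_years")
        ax.plot(grp["timepoint_years"], grp[value], marker="o", label=str(iid))
    ax.set_xlabel("years from first draw")
    ax.set_ylabel(ylabel or value)
    if table["individual_id"].nunique() <= 8:
        ax.legend(fontsize=7)
    fig.tight_layout()
    return _save(fig, path)


def pedigree_barplot(familial: pd.DataFrame, path) -> Path:
    """Father vs offspring methylated-proportion bars per pedigree."""
    fig, ax = plt.subplots(figsize=(6, 4))
    xticks, xlabels, x = [], [], 0
    for ped, grp in familial.groupby("pedigree_id"):
        father = grp["father_prop"].iloc[0]
        ax.bar(x, father, color="#3182bd")
        xticks.append(x)
        xlabels.append(f"{ped}\nfather")
        x += 1
        for _, row in grp.iterrows():
            ax.bar(x, row["offspring_prop"], color="#74c476")
            xticks.append(x)
            xlabels.append(str(row["offspring_id"]))
            x += 1
        x += 1
    ax.set_xticks(xticks)
    ax.set_xticklabels(xlabels, fontsize=6)
    ax.set_ylabel("median proportion methylated (expanded allele)")
    fig.tight_layout()
    return _save(fig, path)
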