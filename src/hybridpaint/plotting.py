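"""Figure rendering: triangle plot, painted ideograms, window boxplots."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aims import TRIANGLE_VERTICES
from .formats_io import ChromosomeMap

__all__ = ["triangle_plot", "ideogram_plot", "window_boxplot"]


def triangle_plot(table: pd.DataFrame, path: str) -> None:
    """Hybrid index vs interspecific heterozygosity with the admissible triangle.

    Expectation marks: parentals at the base corners, F1 at the apex, F2 at
    (0.5, 0.5) and first-generation backcrosses at (0.25, 0.5) / (0.75, 0.5).
    """
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    tri = list(TRIANGLE_VERTICES) + [TRIANGLE_VERTICES[0]]
    ax.plot([p[0] for p in tri], [p[1] for p in tri], color="0.6", lw=1)
    for x, y, label in [(0.5, 1.0, "F1"), (0.5, 0.5, "F2"), (0.25, 0.5, "BC1B"), (0.75, 0.5, "BC1A")]:
        ax.scatter([x], [y], marker="+", color="0.4")
        ax.annotate(label, (x, y), textcoords="offset points", xytext=(4, 4), fontsize=8, color="0.4")
    ax.scatter(table["h"], table["H"], c="crimson", zorder=3)
    for _, row in table.iterrows():
        ax.annotate(str(row["id"]), (row["h"], row["H"]), textcoords="offset points",
                    xytext=(4, -8), fontsize=7)
    ax.set_xlabel("hybrid index h (parent-A allele fraction)")
    ax.set_ylabel("interspecific heterozygosity H")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ideogram_plot(ideogram: pd.DataFrame, cmap: ChromosomeMap, path: str) -> None:
    """One bar per chromosome, windows shaded by median Q_A; ILS windows hatched."""
    import matplotlib.pyplot as plt
    from matplotlib import colormaps
    from matplotlib.patches import Rectangle

    names = cmap.names
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(names) + 1.2))
    reds = colormaps["Reds"]
    for y, chrom in enumerate(names):
        rows = ideogram[ideogram["chrom"] == chrom]
        for _, row in rows.iterrows():
            width = row["end"] - row["start"]
            if row.get("ils_flag", False):
                face, hatch = "#9ecae1", "xx"
            elif not row.get("defined", True) or np.isnan(row["median_QA"]):
                face, hatch = "0.9", ""
            else:
                face, hatch = reds(float(row["median_QA"])), ""
            ax.add_patch(
                Rectangle((row["start"], y - 0.35), width, 0.7, facecolor=face,
                          edgecolor="0.3", hatch=hatch, lw=0.4)
            )
    ax.set_yticks(range(len(names)), names)
    ax.set_xlim(0, max(cmap.length(c) for c in names) * 1.02)
    ax.set_ylim(-0.8, len(names) - 0.2)
    ax.invert_yaxis()
    ax.set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def window_boxplot(box: pd.DataFrame, path: str) -> None:
    """Hybrid Q_A by window index, one panel per chromosome size class."""
    import matplotlib.pyplot as plt

    classes = [c for c in ("macro", "intermediate", "micro") if (box["size_class"] == c).any()]
    fig, axes = plt.subplots(1, max(len(classes), 1), figsize=(3.2 * max(len(classes), 1), 3.4),
                             squeeze=False)
    for ax, size_class in zip(axes[0], classes):
        sub = box[box["size_class"] == size_class]
        indices = sorted(sub["window"].unique())
        data = [sub.loc[sub["window"] == w, "Q_A"].to_numpy() for w in indices]
        ax.boxplot(data, tick_labels=[str(w) for w in indices])
        ax.set_title(size_class)
        ax.set_xlabel("window")
        ax.set_ylabel("hybrid $Q_A$")
        ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
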