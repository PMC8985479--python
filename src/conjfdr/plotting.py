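"""Figure rendering: conditional Q-Q curves and a conjFDR Manhattan plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .fdr import QQCurve


def plot_qq(curves: list[QQCurve], path, max_points: int = 2000) -> None:
    """Conditional Q-Q plot: one curve per conditioning stratum, with the
    no-association diagonal dashed."""
    fig, ax = plt.subplots(figsize=(5, 5))
    top = 0.0
    for c in sorted(curves, key=lambda c: -c.stratum_threshold):
        step = max(1, len(c.expected) // max_points)
        x, y = c.expected[::step], c.observed[::step]
        label = "all SNPs" if c.stratum_threshold >= 1 else f"p2 < {c.stratum_threshold:g}"
        ax.plot(x, y, lw=1.5, label=label)
        top = max(top, x.max(), y.max())
    ax.plot([0, top], [0, top], "k--", lw=1)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_manhattan(table: pd.DataFrame, threshold: float, path) -> None:
    """-log10 conjFDR by genomic position, one color band per chromosome."""
    fig, ax = plt.subplots(figsize=(9, 3.2))
    offset = 0
    ticks, labels = [], []
    chroms = sorted(table["chrom"].astype(str).unique(), key=lambda c: int(c))
    for k, chrom in enumerate(chroms):
        sub = table[table["chrom"].astype(str) == chrom]
        x = sub["pos"].to_numpy() + offset
        ax.scatter(
            x, -np.log10(sub["conjfdr"]),
            s=4, color=["#4477aa", "#ee7733"][k % 2], rasterized=True,
        )
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(chrom)
        offset += sub["pos"].max() + 1
    ax.axhline(-np.log10(threshold), color="k", ls="--", lw=1)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}$ conjFDR")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
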