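"""Optional figure rendering for the multiverse summaries.

Everything here is a thin view over data already exported as delimited text;
figures are rendered only when requested.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def pvalue_histogram(multiverse, path: Path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    p = multiverse.p_values
    ax.hist(p, bins=20, range=(0, 1), color="steelblue", edgecolor="white")
    ax.axvline(0.01, color="firebrick", linestyle="--", linewidth=1)
    ax.axvline(0.05, color="darkorange", linestyle="--", linewidth=1)
    ax.set_xlabel("interaction p-value")
    ax.set_ylabel("models")
    ax.set_title(
        f"{multiverse.moderator}: mean p = {multiverse.mean_p:.2f}, "
        f"{100 * multiverse.prop_le_01:.1f}% at p <= 0.01"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def volcano_plot(multiverse, path: Path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    v = multiverse.volcano
    ax.scatter(v.beta_std, v.neg_log10_p, s=12, alpha=0.6, color="slategray")
    for cut, color in ((0.01, "firebrick"), (0.05, "darkorange")):
        ax.axhline(-np.log10(cut), color=color, linestyle="--", linewidth=1)
    ax.set_xlabel("standardized interaction coefficient")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"{multiverse.moderator}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def heatmap_figure(bundle, path: Path) -> None:
    import pandas as pd

    plt = _mpl()
    table = pd.concat(
        [m.heatmap for m in bundle.multiverse.values()], ignore_index=True
    ).pivot(index="moderator", columns="outcome", values="percent_sig")
    fig, ax = plt.subplots(figsize=(max(8, 0.25 * table.shape[1]), 0.4 * len(table) + 2))
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="YlOrRd", vmin=0)
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(table.shape[0]), table.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="% of models with p <= 0.01")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_figures(bundle, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for moderator, m in bundle.multiverse.items():
        if len(m.p_values):
            pvalue_histogram(m, out_dir / f"pvalues_{moderator}.png")
        if len(m.volcano):
            volcano_plot(m, out_dir / f"volcano_{moderator}.png")
    heatmap_figure(bundle, out_dir / "heatmap.png")
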