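"""Optional matplotlib renderings (wavelet panels, mutability heatmaps).

Everything here is presentation only; the CSV/TSV writers in the analysis
modules are the canonical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_cross_wavelet(result, path: str | Path, title: str = "") -> None:
    """Four-panel figure: average power, cross power, coherence, phase, with COI shading."""
    plt = _mpl()
    fig, axes = plt.subplots(2, 2, figsize=(11, 7))
    extent = [result.positions[0], result.positions[-1],
              len(result.scales) - 1, 0]

    ax = axes[0, 0]
    ax.plot(result.avg_power, np.arange(len(result.scales)))
    ax.set_ylim(len(result.scales) - 1, 0)
    ax.set_xlabel("average power")
    ax.set_ylabel("scale index")

    panels = [
        (axes[0, 1], result.cross_power, "cross-wavelet power", "viridis"),
        (axes[1, 0], result.coherence, "coherence", "magma"),
        (axes[1, 1], result.phase, "phase difference", "twilight"),
    ]
    outside = result.outside_coi()
    for ax, mat, label, cmap in panels:
        im = ax.imshow(mat, aspect="auto", extent=extent, cmap=cmap)
        shade = np.ma.masked_where(~outside, np.ones_like(mat))
        ax.imshow(shade, aspect="auto", extent=extent, cmap="gray", alpha=0.35, vmin=0, vmax=1)
        ax.set_title(label)
        ax.set_xlabel("position")
        fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(table, path: str | Path, ordered: bool = True, title: str = "") -> None:
    """Render a mutability heatmap table (optionally in clustered order)."""
    plt = _mpl()
    df = table.as_frame(ordered=ordered)
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(df.columns)), 6))
    im = ax.imshow(df.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=90, fontsize=7)
    ax.set_ylabel("alignment position (clustered order)" if ordered else "alignment position")
    fig.colorbar(im, ax=ax, label="distance to reference")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
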