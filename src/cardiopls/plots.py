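"""Static figures: biplots, error histograms, correlation heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_biplot", "plot_error_histograms", "plot_correlation_heatmap"]


def plot_biplot(biplot, ax=None, title: str = ""):
    """Arrows for input (grey) and output (coloured) variable loadings
    on the first two latent variables."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for name, xy in biplot.input_points.items():
        ax.annotate("", xy=xy, xytext=(0, 0),
                    arrowprops=dict(arrowstyle="-", color="0.6", lw=0.8))
        ax.text(*xy, name, fontsize=6, color="0.4")
    for name, xy in biplot.output_points.items():
        ax.annotate("", xy=xy, xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:red", lw=1.2))
        ax.text(*xy, name, fontsize=8, color="tab:red", weight="bold")
    v1, v2 = biplot.axis_variance
    ax.set_xlabel(f"LV1 ({100 * v1:.1f}% Y variance)")
    ax.set_ylabel(f"LV2 ({100 * v2:.1f}% Y variance)")
    ax.axhline(0, color="0.85", lw=0.5)
    ax.axvline(0, color="0.85", lw=0.5)
    if title:
        ax.set_title(title)
    return ax


def plot_error_histograms(result, bins: int = 40, path=None):
    """Per-gene overlaid error histograms for the two tested strata."""
    genes = result.gene_names
    ncol = min(5, len(genes))
    nrow = int(np.ceil(len(genes) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.4 * nrow),
                             squeeze=False)
    colors = {"female": "tab:orange", "male": "tab:blue"}
    for j, g in enumerate(genes):
        ax = axes[j // ncol][j % ncol]
        for stratum, err in result.errors.items():
            ax.hist(err[:, j], bins=bins, alpha=0.5, density=True,
                    color=colors.get(stratum), label=stratum)
        ax.axvline(0, color="k", lw=0.6)
        ax.set_title(f"{g} (D={result.ashman[g]:.2f})", fontsize=8)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_correlation_heatmap(block, clustered: bool = True, path=None):
    """Heatmap of a correlation block, optionally in clustered order."""
    df = block.ordered() if clustered else block.r
    fig, ax = plt.subplots(
        figsize=(0.3 * df.shape[1] + 2, 0.3 * df.shape[0] + 2))
    im = ax.imshow(df.to_numpy(), cmap="RdYlGn", vmin=-1, vmax=1)
    ax.set_xticks(range(df.shape[1]), df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(df.shape[0]), df.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
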