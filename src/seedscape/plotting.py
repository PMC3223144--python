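"""Figure helpers: enrichment landscapes, resampling histograms, heat maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .census import ResamplingResult
from .seedscan import EnrichmentLandscape

__all__ = ["plot_landscape", "plot_resampling_histogram", "plot_expression_heatmap"]


def plot_landscape(
    landscapes: EnrichmentLandscape | list[EnrichmentLandscape],
    cutoff: float = 1e-4,
    ax=None,
):
    """Signed -log10 p against leading-window size; dashed line = cutoff."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if isinstance(landscapes, EnrichmentLandscape):
        landscapes = [landscapes]
    for lsc in landscapes:
        ax.plot(lsc.cutpoints, lsc.values, label=f"{lsc.word} ({lsc.comparison})")
    bound = -np.log10(cutoff)
    ax.axhline(bound, ls="--", c="grey", lw=0.8)
    ax.axhline(-bound, ls="--", c="grey", lw=0.8)
    ax.axhline(0, c="black", lw=0.8)
    ax.set_xlabel("genes in leading window")
    ax.set_ylabel("signed -log10 hypergeometric p")
    ax.legend(fontsize=7)
    return ax


def plot_resampling_histogram(result: ResamplingResult, ax=None):
    """Null trio-count histogram with the observed count marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    hist = result.histogram()
    ax.bar(hist.index, hist.to_numpy(), width=0.9, color="steelblue")
    ax.axvline(result.observed, c="firebrick", ls="--", label=f"observed = {result.observed}")
    ax.set_xlabel("instances credited to a random 3-miRNA draw")
    ax.set_ylabel(f"draws (of {result.n_draws})")
    ax.legend()
    return ax


def plot_expression_heatmap(ordered_values: pd.DataFrame, ax=None):
    """Feature x sample heat map in dendrogram leaf order."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    centered = ordered_values.sub(ordered_values.mean(axis=1), axis=0)
    im = ax.imshow(centered.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(ordered_values.columns)))
    ax.set_xticklabels(ordered_values.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    plt.colorbar(im, ax=ax, label="log2 (row-centered)")
    return ax
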