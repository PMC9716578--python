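"""Minimal static plots for the main artifacts (network, running score,
specificity heatmap). Rendering niceties are out of scope; these are
diagnostic views, not figure reproductions."""

from __future__ import annotations

import networkx as nx
import numpy as np


def plot_running_score(result, ax=None):
    """Plot a weighted-KS running enrichment profile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    run = np.asarray(result.running_score)
    ax.plot(np.arange(1, run.size + 1), run, lw=1.0)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("rank")
    ax.set_ylabel("running ES")
    ax.set_title(f"ES={result.es:.3f}  NES={result.nes:.2f}  p={result.p_perm:.3g}")
    return ax


def plot_network(g: nx.Graph, target_label: str, ax=None, seed: int = 0):
    """Spring-layout view of the thresholded correlation network."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pos = nx.spring_layout(g, seed=seed)
    colors = [
        "tab:red" if d.get("type_label") == target_label else "tab:grey"
        for _, d in g.nodes(data=True)
    ]
    widths = [2.0 * d.get("weight", 0.5) for _, _, d in g.edges(data=True)]
    nx.draw_networkx_nodes(g, pos, node_color=colors, node_size=30, ax=ax)
    nx.draw_networkx_edges(g, pos, width=widths, alpha=0.5, ax=ax)
    ax.set_axis_off()
    return ax


def plot_specificity_heatmap(result, ax=None, cap: float = 10.0):
    """Heatmap of -log10 p per (gene, type), capped for display."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    mat = result.neglog10p.to_numpy(float)
    im = ax.imshow(np.minimum(mat, cap), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(result.neglog10p.columns)))
    ax.set_xticklabels(result.neglog10p.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(result.neglog10p.index)))
    ax.set_yticklabels(result.neglog10p.index, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="-log10 p")
    return ax
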