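"""Figures and tables: network plots, the two-cohort triangular matrix, TSVs."""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .edges import (
    AMBIGUOUS,
    ASSOCIATED,
    DISCORDANT,
    REPLICATED_ASSOCIATION,
    REPLICATED_INDEPENDENCE,
    EdgeDecision,
    ReplicationSummary,
)
from .schema import DEPRESSION_BLOCK, STRESSOR_BLOCK, TRAIT_BLOCK

__all__ = ["FigureSpec", "compute_layout", "plot_network", "triangular_matrix"]

_BLOCK_COLORS = {
    TRAIT_BLOCK: "#7fb3d5",
    STRESSOR_BLOCK: "#f5cba7",
    DEPRESSION_BLOCK: "#d98880",
}

_CELL_COLORS = {
    "replicated": "#a9dfbf",
    "discordant": "#f8c471",
    "white": "#ffffff",
}


@dataclass(frozen=True)
class FigureSpec:
    """Layout and styling knobs for network plots."""

    layout_seed: int = 42
    layout_mode: str = "averaged_fixed"  # or "per_cohort"
    edge_width_scale: float = 12.0
    node_colors: dict = field(default_factory=dict)


def _supported_edges(decisions: list[EdgeDecision]) -> list[tuple[str, str, float]]:
    return [
        (d.pair[0], d.pair[1], d.rho_mean) for d in decisions if d.status == ASSOCIATED
    ]


def compute_layout(
    labels: tuple[str, ...],
    adjacency: np.ndarray,
    seed: int,
) -> dict[str, np.ndarray]:
    """Force-directed (Fruchterman-Reingold) coordinates on |weight| edges."""
    g = nx.Graph()
    g.add_nodes_from(labels)
    p = len(labels)
    for i in range(p):
        for j in range(i + 1, p):
            w = abs(adjacency[i, j])
            if w > 0:
                g.add_edge(labels[i], labels[j], weight=w)
    return nx.spring_layout(g, seed=seed, weight="weight")


def average_absolute_adjacency(
    rho_a: np.ndarray, rho_b: np.ndarray
) -> np.ndarray:
    """Element-wise mean absolute weighted adjacency of the two cohorts."""
    out = (np.abs(rho_a) + np.abs(rho_b)) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


def plot_network(
    decisions: list[EdgeDecision],
    labels: tuple[str, ...],
    spec: FigureSpec,
    path,
    layout: dict[str, np.ndarray] | None = None,
    block_of: dict[str, str] | None = None,
    title: str = "",
) -> dict[str, np.ndarray]:
    """Draw the supported-edge network; returns the coordinates used.

    In averaged-fixed mode the caller passes a shared ``layout`` computed
    from the mean absolute adjacency of both cohorts, so node coordinates
    are identical across the two cohort figures.
    """
    edges = _supported_edges(decisions)
    if layout is None:
        p = len(labels)
        adj = np.zeros((p, p))
        idx = {n: i for i, n in enumerate(labels)}
        for a, b, w in edges:
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = w
        layout = compute_layout(labels, adj, spec.layout_seed)

    fig, ax = plt.subplots(figsize=(7, 6))
    if block_of:
        colors = [
            spec.node_colors.get(n, _BLOCK_COLORS.get(block_of.get(n, ""), "#cccccc"))
            for n in labels
        ]
    else:
        colors = [spec.node_colors.get(n, "#cccccc") for n in labels]
    g = nx.Graph()
    g.add_nodes_from(labels)
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    widths = [abs(g.edges[e]["weight"]) * spec.edge_width_scale for e in g.edges]
    ecolors = ["#2e6da4" if g.edges[e]["weight"] > 0 else "#c0392b" for e in g.edges]
    nx.draw_networkx_nodes(g, layout, node_color=colors, node_size=900, ax=ax)
    nx.draw_networkx_edges(g, layout, width=widths, edge_color=ecolors, ax=ax)
    nx.draw_networkx_labels(
        g, layout, labels={n: n.replace("_", "\n") for n in labels}, font_size=6, ax=ax
    )
    ax.set_title(title)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    base = str(path)
    if base.endswith(".png"):
        fig.savefig(base[:-4] + ".svg")
    plt.close(fig)
    return layout


def _cell_text(d: EdgeDecision) -> str:
    lo, hi = d.rho_cri
    return f"{d.rho_mean:.3f} ({lo:.3f}, {hi:.3f})"


def triangular_matrix(
    replication: list[ReplicationSummary],
    decisions_a: list[EdgeDecision],
    decisions_b: list[EdgeDecision],
    labels: tuple[str, ...],
    tsv_path=None,
    image_path=None,
) -> pd.DataFrame:
    """13x13 display: cohort A in the lower triangle, cohort B in the upper.

    Cell colors follow the replication verdict: green for replicated (either
    direction), orange for discordant, white when at least one cohort is
    ambiguous.
    """
    idx = {n: i for i, n in enumerate(labels)}
    text = pd.DataFrame("", index=list(labels), columns=list(labels), dtype=object)
    color = np.full((len(labels), len(labels)), _CELL_COLORS["white"], dtype=object)
    repl_of = {frozenset(r.pair): r.replication for r in replication}

    for d in decisions_a:  # lower triangle = cohort A
        i, j = idx[d.pair[0]], idx[d.pair[1]]
        lo, hi = sorted((i, j))
        text.iloc[hi, lo] = _cell_text(d)
    for d in decisions_b:  # upper triangle = cohort B
        i, j = idx[d.pair[0]], idx[d.pair[1]]
        lo, hi = sorted((i, j))
        text.iloc[lo, hi] = _cell_text(d)
    for pair, verdict in repl_of.items():
        i, j = sorted(idx[n] for n in pair)
        if verdict in (REPLICATED_ASSOCIATION, REPLICATED_INDEPENDENCE):
            c = _CELL_COLORS["replicated"]
        elif verdict == DISCORDANT:
            c = _CELL_COLORS["discordant"]
        else:
            c = _CELL_COLORS["white"]
        color[i, j] = color[j, i] = c

    if tsv_path is not None:
        text.to_csv(tsv_path, sep="\t")
    if image_path is not None:
        fig, ax = plt.subplots(figsize=(13, 8))
        ax.axis("off")
        table = ax.table(
            cellText=text.to_numpy(),
            rowLabels=list(labels),
            colLabels=list(labels),
            cellColours=color,
            loc="center",
        )
        table.auto_set_font_size(False)
        table.set_fontsize(5)
        fig.savefig(image_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return text
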