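"""Network figures: force-directed layout and qgraph-style rendering.

Node positions come from the Fruchterman–Reingold force-directed algorithm
with |edge weight| as attraction strength. For paired group figures the
layout is computed once (on the school network) and reused, keeping the two
panels visually comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .centrality import CentralityProfile
from .ggm import SymptomNetwork
from .survey import ITEM_NAMES

CLUSTER_COLORS = {"depression": "#4C72B0", "anxiety": "#DD8452",
                  "covariate": "#8C8C8C"}
POSITIVE_EDGE = "#2E7D32"
NEGATIVE_EDGE = "#C62828"


@dataclass(frozen=True)
class LayoutPositions:
    positions: dict[str, tuple[float, float]]
    iterations: int
    seed: int


def layout_fruchterman_reingold(net: SymptomNetwork, seed: int = 0,
                                iterations: int = 200) -> LayoutPositions:
    """Deterministic force-directed layout, rescaled to the unit square."""
    if net.p == 0:
        raise ValueError("cannot lay out an empty network")
    g = nx.Graph()
    g.add_nodes_from(net.labels)
    iu = np.triu_indices(net.p, 1)
    for i, j in zip(*iu):
        w = abs(net.weights[i, j])
        if w > 0:
            g.add_edge(net.labels[i], net.labels[j], weight=w)
    if net.p == 1:
        return LayoutPositions({net.labels[0]: (0.5, 0.5)}, iterations, seed)
    pos = nx.spring_layout(g, weight="weight", seed=seed, iterations=iterations)
    xy = np.array([pos[l] for l in net.labels])
    span = xy.max(axis=0) - xy.min(axis=0)
    span[span == 0] = 1.0
    xy = (xy - xy.min(axis=0)) / span
    return LayoutPositions({l: (float(x), float(y)) for l, (x, y) in zip(net.labels, xy)},
                           iterations, seed)


@dataclass
class RenderedNetwork:
    figure: plt.Figure
    edge_order: list[tuple[str, str]]
    edge_widths: list[float]
    edge_weights: list[float]

    def save(self, path: str | Path, dpi: int = 200) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.figure.savefig(path, dpi=dpi, bbox_inches="tight")
        plt.close(self.figure)


def render_network(net: SymptomNetwork, layout: LayoutPositions,
                   title: str | None = None,
                   max_width: float = 6.0) -> RenderedNetwork:
    """Draw the network: edge width proportional to |weight|, colour by sign,
    node colour by cluster. Inputs are not modified."""
    fig, ax = plt.subplots(figsize=(6, 6))
    iu = np.triu_indices(net.p, 1)
    wmax = max(float(np.abs(net.weights[iu]).max()), 1e-12) if net.p > 1 else 1.0
    order, widths, weights = [], [], []
    for i, j in zip(*iu):
        w = float(net.weights[i, j])
        if w == 0:
            continue
        a, b = net.labels[i], net.labels[j]
        (x1, y1), (x2, y2) = layout.positions[a], layout.positions[b]
        lw = max_width * abs(w) / wmax
        ax.plot([x1, x2], [y1, y2], lw=lw,
                color=POSITIVE_EDGE if w > 0 else NEGATIVE_EDGE,
                alpha=0.75, zorder=1)
        order.append((a, b))
        widths.append(lw)
        weights.append(w)
    for lab in net.labels:
        x, y = layout.positions[lab]
        ax.scatter([x], [y], s=700,
                   color=CLUSTER_COLORS.get(net.cluster_of[lab], "#999999"),
                   edgecolors="black", zorder=2)
        ax.annotate(lab, (x, y), ha="center", va="center", fontsize=8, zorder=3)
    ax.set_xlim(-0.1, 1.1)
    ax.set_ylim(-0.1, 1.1)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    return RenderedNetwork(fig, order, widths, weights)


def plot_centrality_bars(profiles: dict[str, CentralityProfile],
                         which: str = "standardized_strength") -> plt.Figure:
    """Side-by-side standardized centrality profiles (one line per group)."""
    fig, ax = plt.subplots(figsize=(5, 7))
    first = next(iter(profiles.values()))
    labels = [f"{l} {ITEM_NAMES.get(l, '')}".strip() for l in first.labels]
    for name, prof in profiles.items():
        ax.plot(getattr(prof, which), range(len(prof.labels)), marker="o",
                label=name)
    ax.set_yticks(range(len(first.labels)))
    ax.set_yticklabels(labels)
    ax.invert_yaxis()
    ax.set_xlabel(which.replace("_", " "))
    ax.legend()
    fig.tight_layout()
    return fig
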