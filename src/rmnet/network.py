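"""Directed signed interaction networks and their post-processing.

An :class:`InteractionNetwork` holds directed edges signed ``cooperative``
(regulator promotes the target) or ``competitive`` (regulator impedes the
target), as inferred by the triplet rule model.  Nodes carry a site-presence
category and a maximum observed relative abundance.  The container wraps a
:class:`networkx.MultiDiGraph` keyed by sign, so at most one edge exists per
(source, target, sign); merging duplicate evidence keeps the maximum score
and counts contributing triplets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

COOPERATIVE = "cooperative"
COMPETITIVE = "competitive"
SIGNS = (COOPERATIVE, COMPETITIVE)

__all__ = [
    "InteractionNetwork",
    "Edge",
    "COOPERATIVE",
    "COMPETITIVE",
    "mutual_negative_pairs",
    "unilateral_positive_edges",
    "network_summary",
    "render",
]


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: str
    weight: float
    n_triplets: int


class InteractionNetwork:
    """Directed graph of signed microbial interactions."""

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction -----------------------------------------------------
    def add_node(
        self,
        name: str,
        category: str | None = None,
        max_abundance: float | None = None,
    ) -> None:
        attrs = {}
        if category is not None:
            attrs["category"] = category
        if max_abundance is not None:
            attrs["max_abundance"] = float(max_abundance)
        self._g.add_node(name, **attrs)

    def add_interaction(self, source: str, target: str, sign: str, score: float) -> None:
        """Add (or merge into) the edge source→target with the given sign.

        Merging keeps the maximum score among contributing triplets and
        increments the triplet count.
        """
        if sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}, got {sign!r}")
        if source == target:
            raise ValueError(f"self-edge not allowed: {source!r}")
        if self._g.has_edge(source, target, key=sign):
            data = self._g[source][target][sign]
            data["weight"] = max(data["weight"], float(score))
            data["n_triplets"] += 1
        else:
            self._g.add_edge(
                source, target, key=sign, sign=sign, weight=float(score), n_triplets=1
            )

    # -- accessors --------------------------------------------------------
    @property
    def graph(self) -> nx.MultiDiGraph:
        return self._g

    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def node_attrs(self, name: str) -> dict:
        return dict(self._g.nodes[name])

    def edges(self) -> list[Edge]:
        """All edges, deterministically sorted by (source, target, sign)."""
        out = [
            Edge(u, v, k, d["weight"], d["n_triplets"])
            for u, v, k, d in self._g.edges(keys=True, data=True)
        ]
        return sorted(out, key=lambda e: (e.source, e.target, e.sign))

    def has_edge(self, source: str, target: str, sign: str) -> bool:
        return self._g.has_edge(source, target, key=sign)

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(e.source, e.target, e.sign) for e in self.edges()}

    def n_edges(self, sign: str | None = None) -> int:
        if sign is None:
            return self._g.number_of_edges()
        return sum(1 for e in self.edges() if e.sign == sign)

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for e in self.edges():
            if e.source == e.target:
                raise ValueError(f"self-edge at {e.source!r}")
            if not -1 - 1e-9 <= e.weight <= 1 + 1e-9:
                raise ValueError(f"edge weight out of [-1,1]: {e}")
            if e.n_triplets < 1:
                raise ValueError(f"edge with no supporting triplets: {e}")
        # the rule model's structural guarantee: a cooperative in-edge can
        # only come from an accepted triplet, which also names a competitor
        for node in self._g.nodes:
            in_signs = {k for _, _, k in self._g.in_edges(node, keys=True)}
            if COOPERATIVE in in_signs and COMPETITIVE not in in_signs:
                raise ValueError(
                    f"node {node!r} has a cooperative in-edge but no competitive one"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return set(self._g.nodes) == set(other._g.nodes) and self.edges() == other.edges()


# -- post-processing -------------------------------------------------------

def mutual_negative_pairs(network: InteractionNetwork) -> list[tuple[str, str]]:
    """Unordered taxon pairs linked by competitive edges in both directions.

    The reciprocal competitive motif is the rule model's signature of two
    taxa each impeding the other.  Pairs are returned sorted, each pair
    ordered lexicographically.
    """
    comp = {(e.source, e.target) for e in network.edges() if e.sign == COMPETITIVE}
    pairs = {tuple(sorted((a, b))) for (a, b) in comp if (b, a) in comp}
    return sorted(pairs)


def unilateral_positive_edges(network: InteractionNetwork) -> list[Edge]:
    """Cooperative edges whose reverse cooperative edge is absent."""
    coop = {(e.source, e.target): e for e in network.edges() if e.sign == COOPERATIVE}
    return [e for (a, b), e in sorted(coop.items()) if (b, a) not in coop]


def network_summary(network: InteractionNetwork) -> dict[str, int]:
    """Node/edge tallies: nodes, cooperative edges, competitive edges,
    mutual-negative pairs."""
    return {
        "n_nodes": len(network.nodes()),
        "n_coop_edges": network.n_edges(COOPERATIVE),
        "n_comp_edges": network.n_edges(COMPETITIVE),
        "n_mutual_negative": len(mutual_negative_pairs(network)),
    }


DEFAULT_NODE_COLORS = {
    "both": "#9467bd",  # purple: present at both regions
    "regionA_only": "#e377c2",  # pink
    "regionB_only": "#2ca02c",  # green
    "below_threshold": "#c7c7c7",
    None: "#aec7e8",
}
EDGE_COLORS = {COOPERATIVE: "#1f77b4", COMPETITIVE: "#d62728"}


def layout(network: InteractionNetwork, seed: int) -> dict[str, tuple[float, float]]:
    """Deterministic spring layout; same seed ⇒ identical coordinates."""
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes())
    for e in network.edges():
        g.add_edge(e.source, e.target)
    pos = nx.spring_layout(g, seed=seed)
    return {n: (float(x), float(y)) for n, (x, y) in sorted(pos.items())}


def render(
    network: InteractionNetwork,
    seed: int,
    path: str,
    node_colors: Mapping[str | None, str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Draw the network to an image file; returns the layout used.

    Node color encodes site-presence category (both sites / one region only),
    edge color encodes sign (cooperative blue, competitive red).  The layout
    is seeded, so repeated renders with the same seed are identical.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = dict(DEFAULT_NODE_COLORS)
    if node_colors:
        cmap.update(node_colors)
    pos = layout(network, seed)

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.set_axis_off()
    g = network.graph
    nodes = network.nodes()
    colors = [cmap.get(g.nodes[n].get("category"), cmap[None]) for n in nodes]
    nx.draw_networkx_nodes(g, pos, nodelist=nodes, node_color=colors, ax=ax)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    for sign in SIGNS:
        edges = [(e.source, e.target) for e in network.edges() if e.sign == sign]
        if edges:
            nx.draw_networkx_edges(
                g,
                pos,
                edgelist=edges,
                edge_color=EDGE_COLORS[sign],
                connectionstyle="arc3,rad=0.08",
                ax=ax,
            )
    fig.savefig(path, dpi=150, metadata={"Software": None} if path.endswith(".png") else None)
    plt.close(fig)
    return pos
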