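"""Gland tracing through a layered peak graph.

Each profile line is a layer; each detected peak a node.  Nodes of adjacent
layers are fully connected by edges weighted with the Euclidean pixel
distance between the peaks, nodes within a layer are not connected, and
virtual supersource/supersink nodes attach to the top and bottom layers with
zero-weight edges.  A gland is a minimum-weight supersource-to-supersink path
(Dijkstra); its length is the sum of the real edge weights.

Extraction is iterative and phased.  Phase 1 runs on all four layers:
shortest paths are accepted as long (L) glands while their length stays at or
below the 100 px cap, with accepted nodes removed from the graph.  Because
glands shorten upward from the lid margin, the top layer is then removed and
the same extraction over the remaining three layers yields medium (M) glands.
With two layers left, every remaining adjacent-layer edge shorter than 60 px,
taken greedily shortest-first with node removal, is a short (S) gland.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .config import TraceConfig
from .peaks import Peak

logger = logging.getLogger(__name__)

SOURCE = "supersource"
SINK = "supersink"

LABELS = {0: "L", 1: "M"}  # by number of layers removed; 2-node glands are "S"


@dataclass
class Gland:
    """An ordered chain of peaks, one per consecutive layer."""

    nodes: list[Peak]
    path_length: float
    label: str

    @property
    def n_layers(self) -> int:
        return len(self.nodes)

    @property
    def widths(self) -> list[float]:
        return [p.width for p in self.nodes]

    def to_record(self) -> dict:
        return {
            "label": self.label,
            "n_layers": self.n_layers,
            "path_length": round(self.path_length, 3),
            "nodes": [
                {"layer": p.layer_index, "x": p.x, "y": round(p.y, 2),
                 "width": round(p.width, 2)}
                for p in self.nodes
            ],
        }


@dataclass
class LayeredGraph:
    """Layered peak graph with virtual supersource/supersink."""

    graph: nx.DiGraph
    layers: list[list[tuple[int, int]]]  # node ids (layer, index) per layer
    peaks: dict[tuple[int, int], Peak] = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def _dist(a: Peak, b: Peak) -> float:
    return math.hypot(a.x - b.x, a.y - b.y)


def build_layered_graph(peak_layers: list[list[Peak]]) -> LayeredGraph:
    """Build the full bipartite-between-adjacent-layers graph.

    Edge count between consecutive layers is the product of their sizes; the
    supersource connects to every top-layer node and every bottom-layer node
    connects to the supersink, all with weight 0.
    """
    g = nx.DiGraph()
    layers: list[list[tuple[int, int]]] = []
    peaks: dict[tuple[int, int], Peak] = {}
    for li, layer in enumerate(peak_layers):
        ids = []
        for pi, p in enumerate(sorted(layer, key=lambda q: q.x)):
            nid = (li, pi)
            g.add_node(nid)
            peaks[nid] = p
            ids.append(nid)
        layers.append(ids)
    for li in range(len(layers) - 1):
        for a in layers[li]:
            for b in layers[li + 1]:
                g.add_edge(a, b, weight=_dist(peaks[a], peaks[b]))
    g.add_node(SOURCE)
    g.add_node(SINK)
    if layers:
        for a in layers[0]:
            g.add_edge(SOURCE, a, weight=0.0)
        for b in layers[-1]:
            g.add_edge(b, SINK, weight=0.0)
    return LayeredGraph(graph=g, layers=layers, peaks=peaks)


def shortest_path(lg: LayeredGraph) -> tuple[list[tuple[int, int]], float] | None:
    """Minimum-weight supersource-to-supersink chain via Dijkstra.

    Returns the real node chain and its length (virtual zero-weight edges
    excluded, which leaves the value unchanged), or ``None`` when no path
    remains.  Ties are broken lexicographically by node id for determinism.
    """
    g = lg.graph
    if SOURCE not in g or SINK not in g:
        return None
    try:
        best = min(
            nx.all_shortest_paths(g, SOURCE, SINK, weight="weight"),
            key=lambda p: p[1:-1],
        )
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None
    chain = best[1:-1]
    length = nx.path_weight(g, chain, weight="weight") if len(chain) > 1 else 0.0
    return chain, length


def classify(n_layers: int, total_layers: int = 4) -> str:
    """Label a gland by how many layers it spans: all -> L, all-1 -> M, 2 -> S."""
    if not 2 <= n_layers <= total_layers:
        raise ValueError(
            f"a gland spans between 2 and {total_layers} layers, got {n_layers}"
        )
    if n_layers == total_layers:
        return "L"
    if n_layers == total_layers - 1:
        return "M"
    return "S"


def _accepts(length: float, cap: float, mode: str) -> bool:
    return length < cap if mode == "lt" else length <= cap


def trace_glands(
    lg: LayeredGraph,
    full_max_len: float = 100.0,
    pair_max_len: float = 60.0,
    accept: str = "leq",
    total_layers: int | None = None,
) -> list[Gland]:
    """Iteratively extract glands from the layered graph.

    Multi-layer phases accept the current shortest path while its length is
    within ``full_max_len`` (accepted nodes removed), stopping when the
    minimal path first exceeds the cap or no path exists; the top layer is
    then dropped and extraction repeats while at least three layers remain.
    On the final two layers every remaining edge strictly shorter than
    ``pair_max_len``, greedily shortest-first and node-disjoint, is a 2-node
    gland.  Glands are labeled by the number of layers they span and returned
    sorted by leftmost column, then layer.
    """
    total = total_layers if total_layers is not None else lg.n_layers
    if total < 2:
        logger.warning("fewer than 2 layers: no glands can be traced")
        return []
    g = lg.graph
    glands: list[Gland] = []

    top = 0
    while lg.n_layers - top >= 3:
        # (re)connect the supersource to the current top layer
        for u in list(g.successors(SOURCE)):
            g.remove_edge(SOURCE, u)
        for a in lg.layers[top]:
            if a in g:
                g.add_edge(SOURCE, a, weight=0.0)
        while True:
            sp = shortest_path(lg)
            if sp is None:
                break
            chain, length = sp
            if not _accepts(length, full_max_len, accept):
                break
            peaks = [lg.peaks[n] for n in chain]
            glands.append(Gland(peaks, length, classify(len(chain), total)))
            g.remove_nodes_from(chain)
        top += 1

    # two layers left: short glands from remaining sub-threshold edges
    if lg.n_layers - top == 2:
        upper = [n for n in lg.layers[top] if n in g]
        lower = [n for n in lg.layers[top + 1] if n in g]
        candidates = sorted(
            ((g.edges[a, b]["weight"], a, b) for a in upper for b in lower
             if g.has_edge(a, b)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        used: set[tuple[int, int]] = set()
        for w, a, b in candidates:
            if w >= pair_max_len:
                break
            if a in used or b in used:
                continue
            used.update((a, b))
            glands.append(
                Gland([lg.peaks[a], lg.peaks[b]], w, classify(2, total))
            )

    glands.sort(key=lambda gl: (min(p.x for p in gl.nodes), gl.nodes[0].layer_index))
    return glands


def trace_from_peaks(
    peak_layers: list[list[Peak]], config: TraceConfig | None = None
) -> list[Gland]:
    """Convenience wrapper: build the graph and trace glands in one call."""
    cfg = config or TraceConfig()
    non_empty = sum(1 for l in peak_layers if l)
    if non_empty < 2:
        logger.warning("fewer than 2 non-empty peak layers: no glands")
        return []
    lg = build_layered_graph(peak_layers)
    return trace_glands(lg, cfg.full_max_len, cfg.pair_max_len, cfg.accept)
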