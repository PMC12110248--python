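"""Layered-graph gland tracing, shown on hand-placed peaks.

Peaks become nodes in a layered graph (one layer per profile line, adjacent
layers fully connected, edges weighted by Euclidean distance, zero-weight
supersource/supersink).  Glands are extracted as repeated shortest paths:
4-layer paths within 100 px are long glands, after dropping the top layer
3-layer paths are medium, and remaining bottom-pair edges under 60 px are
short.
"""

from meiboscan import Peak, build_layered_graph, shortest_path, trace_from_peaks

ROWS = [14.0, 64.0, 78.0, 106.0]  # depth rows of a 142-px-deep eyelid band


def column(x, layers):
    return [Peak(l, x, ROWS[l], 0.8, 0.8, 20.0) for l in layers]


peaks = [[], [], [], []]
for x, layers in [(100, (0, 1, 2, 3)),   # full-length gland
                  (160, (0, 1, 2, 3)),   # full-length gland
                  (220, (1, 2, 3)),      # shortened: missing at depth 0.10
                  (280, (2, 3))]:        # short stub near the lid margin
    for p in column(x, layers):
        peaks[p.layer_index].append(p)

lg = build_layered_graph(peaks)
chain, length = shortest_path(lg)
print("first shortest path: "
      f"{[(layer, lg.peaks[n].x) for (layer, _), n in zip(chain, chain)]} "
      f"length {length:.1f} px")

for g in trace_from_peaks(peaks):
    xs = [n.x for n in g.nodes]
    print(f"gland at x~{xs[0]}: label {g.label}, {g.n_layers} layers, "
          f"path length {g.path_length:.1f} px")

# Expected: two L glands (4 layers, ~92 px), one M (3 layers), one S
# (2 layers, 28 px edge < 60 px).
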