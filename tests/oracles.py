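"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy.signal and networkx: peaks and prominences
are computed from their definitions by scanning, and shortest paths by
exhaustive enumeration of every source-to-sink combination.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_peaks(
    v: np.ndarray, min_prominence: float, min_width: float
) -> list[dict]:
    """All interior strict local maxima with prominence and width at half
    prominence, computed by definition (no plateaus expected in ``v``)."""
    v = np.asarray(v, dtype=float)
    out = []
    for i in range(1, len(v) - 1):
        if not (v[i - 1] < v[i] > v[i + 1]):
            continue
        # prominence: walk outward until a strictly higher sample or border,
        # track the minimum on each side; prominence is peak minus the
        # higher of the two side minima
        left_min = v[i]
        j = i - 1
        left_base = i
        while j >= 0 and v[j] <= v[i]:
            if v[j] < left_min:
                left_min = v[j]
                left_base = j
            j -= 1
        right_min = v[i]
        j = i + 1
        right_base = i
        while j < len(v) and v[j] <= v[i]:
            if v[j] < right_min:
                right_min = v[j]
                right_base = j
            j += 1
        prominence = v[i] - max(left_min, right_min)

        def width_at(height: float) -> float:
            # interpolated crossings bounded by the prominence bases
            j = i
            while j > left_base and v[j] > height:
                j -= 1
            if v[j] > height:
                left_x = float(j)
            else:
                left_x = j + (height - v[j]) / (v[j + 1] - v[j])
            j = i
            while j < right_base and v[j] > height:
                j += 1
            if v[j] > height:
                right_x = float(j)
            else:
                right_x = j - (height - v[j]) / (v[j - 1] - v[j])
            return right_x - left_x

        gate_width = width_at(v[i] - 0.5 * prominence)
        half_height_width = width_at(0.5 * v[i])
        if prominence >= min_prominence and gate_width >= min_width:
            out.append(
                {"index": i, "prominence": prominence,
                 "gate_width": gate_width, "width": half_height_width,
                 "left_base": left_base, "right_base": right_base}
            )
    return out


def enumerate_shortest_chain(
    layer_positions: list[list[tuple[float, float]]]
) -> tuple[tuple[int, ...], float] | None:
    """Minimum-total-Euclidean-length chain taking one node per layer,
    by exhaustive enumeration; ties broken lexicographically by node index.

    ``layer_positions[l][i]`` is the (x, y) of node i in layer l.  Returns
    (node indices per layer, length) or None when a layer is empty.
    """
    if any(len(layer) == 0 for layer in layer_positions) or not layer_positions:
        return None
    best = None
    for combo in itertools.product(*(range(len(l)) for l in layer_positions)):
        length = 0.0
        for l in range(len(combo) - 1):
            ax, ay = layer_positions[l][combo[l]]
            bx, by = layer_positions[l + 1][combo[l + 1]]
            length += math.hypot(ax - bx, ay - by)
        key = (length, combo)
        if best is None or key < best:
            best = key
    return best[1], best[0]
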