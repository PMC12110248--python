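"""Eyelid-following profile lines and gray-value sampling.

The everted lower eyelid appears as a curved horizontal band; glands run
roughly vertically through it.  Four profile lines are laid across the band
at fixed depth fractions (0.10, 0.45, 0.55, 0.75 of the local vertical
extent, measured downward from the band's top).  Each line is piecewise
linear: the mask's bounding columns are split into 5 equal vertical zones, an
anchor is placed at the depth point of each zone's foreground extent at the
zone's horizontal center, consecutive anchors are joined by straight
segments, and the line is extended flat to the foreground's left and right
ends.

Coordinates are 0-based ``(x=column, y=row)`` with row 0 at the top, so
"downward" means increasing row index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidMaskError

logger = logging.getLogger(__name__)

DEFAULT_DEPTHS = (0.10, 0.45, 0.55, 0.75)


@dataclass
class ProfileLine:
    """One eyelid-following polyline at a fractional depth.

    ``xs`` are consecutive integer columns spanning the mask foreground left
    to right; ``ys`` the (float) row of the line at each column.
    """

    layer_index: int
    depth_fraction: float
    xs: np.ndarray
    ys: np.ndarray

    @property
    def points(self) -> np.ndarray:
        """(N, 2) array of (x, y) points."""
        return np.stack([self.xs, self.ys], axis=1)

    def y_at(self, x: int) -> float:
        return float(np.interp(x, self.xs, self.ys))

    def to_record(self) -> dict:
        return {
            "layer_index": self.layer_index,
            "depth_fraction": self.depth_fraction,
            "xs": self.xs.tolist(),
            "ys": [round(float(y), 3) for y in self.ys],
        }


@dataclass
class GrayProfile:
    """Gray values sampled along one profile line, ordered by column."""

    layer_index: int
    xs: np.ndarray
    values: np.ndarray
    ys: np.ndarray  # row of the line at each column (for peak positions)
    normalized: bool = False


def build_profile_lines(
    mask: np.ndarray,
    depths: tuple[float, ...] = DEFAULT_DEPTHS,
    n_zones: int = 5,
) -> list[ProfileLine]:
    """Construct one piecewise-linear profile line per depth fraction.

    Zones partition the foreground's bounding columns (not the full frame)
    into ``n_zones`` equal-width strips; a zone with no foreground is skipped
    and the line interpolated across it.  Line rows are clamped into the
    per-column foreground extent so every point lies on the eyelid.
    """
    fg = np.asarray(mask) > 0
    if not fg.any():
        raise InvalidMaskError("mask foreground is empty")
    col_any = fg.any(axis=0)
    x0, x1 = int(np.argmax(col_any)), int(len(col_any) - 1 - np.argmax(col_any[::-1]))
    edges = np.linspace(x0, x1 + 1, n_zones + 1)

    # per-zone vertical extent of the foreground
    anchors_x: list[float] = []
    tops: list[float] = []
    extents: list[float] = []
    skipped = 0
    for z in range(n_zones):
        lo, hi = int(edges[z]), int(edges[z + 1])
        sub = fg[:, lo:max(hi, lo + 1)]
        rows = np.nonzero(sub.any(axis=1))[0]
        if rows.size == 0:
            skipped += 1
            continue
        anchors_x.append((edges[z] + edges[z + 1]) / 2.0)
        tops.append(float(rows[0]))
        extents.append(float(rows[-1] - rows[0]))
    if not anchors_x:
        raise InvalidMaskError("all zones have empty foreground")
    if skipped:
        logger.warning("%d empty zone(s) skipped; line interpolated across", skipped)

    # per-column foreground bounds, for clamping
    col_top = np.full(fg.shape[1], np.nan)
    col_bot = np.full(fg.shape[1], np.nan)
    any_cols = np.nonzero(col_any)[0]
    first = np.argmax(fg[:, any_cols], axis=0)
    last = fg.shape[0] - 1 - np.argmax(fg[::-1, any_cols], axis=0)
    col_top[any_cols] = first
    col_bot[any_cols] = last

    xs = np.arange(x0, x1 + 1)
    lines = []
    ax = np.asarray(anchors_x)
    at = np.asarray(tops)
    ae = np.asarray(extents)
    for layer, depth in enumerate(sorted(depths)):
        anchor_y = at + depth * ae
        ys = np.interp(xs, ax, anchor_y)  # flat extension beyond end anchors
        # clamp into the foreground where it exists
        ct, cb = col_top[xs], col_bot[xs]
        ok = ~np.isnan(ct)
        ys[ok] = np.clip(ys[ok], ct[ok], cb[ok])
        lines.append(ProfileLine(layer, float(depth), xs.copy(), ys))
    return lines


def extract_profile(img: np.ndarray, line: ProfileLine) -> GrayProfile:
    """Sample the gray value beneath a profile line, one value per column."""
    img = np.asarray(img)
    h = img.shape[0]
    rows = np.rint(line.ys).astype(int)
    if (rows < 0).any() or (rows >= h).any():
        logger.warning("profile line exits image bounds; clamping to border rows")
        rows = np.clip(rows, 0, h - 1)
    values = img[rows, line.xs].astype(float)
    return GrayProfile(line.layer_index, line.xs.copy(), values, rows.astype(float))


def export_lines_json(lines: list[ProfileLine], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([ln.to_record() for ln in lines], indent=1)
    )
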