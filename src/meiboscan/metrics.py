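"""Per-image gland census: class counts, AveWidth, and the atrophy index.

The atrophy index condenses the gland-length census into one number:

    atrophy_index = (N_L - (N_M + N_S)) / N_T,   N_T = N_L + N_M + N_S

It spans [-1, 1]: +1 when every detected gland is long (healthy, covering the
full eyelid depth), -1 when every gland is shortened.

AveWidth_x is the mean width (at 50% of peak height, px) of the glands in
class x; a gland's own width is summarized from its per-layer peak widths
(arithmetic mean by default, median as an option).  Classes with no glands
have no AveWidth — an absent value, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, median

from .config import MetricsConfig
from .tracing import Gland

LABELS = ("L", "M", "S")


def count_glands(glands: list[Gland]) -> tuple[int, int, int, int]:
    """Tally glands per class: returns (N_L, N_M, N_S, N_T)."""
    n_l = sum(1 for g in glands if g.label == "L")
    n_m = sum(1 for g in glands if g.label == "M")
    n_s = sum(1 for g in glands if g.label == "S")
    return n_l, n_m, n_s, n_l + n_m + n_s


def gland_width(gland: Gland, how: str = "mean") -> float:
    """One width per gland, summarizing its per-layer peak widths."""
    return float(median(gland.widths) if how == "median" else mean(gland.widths))


def ave_width(glands: list[Gland], label: str, how: str = "mean") -> float:
    """AveWidth of one class: mean of the class members' gland widths.

    Raises ``ValueError`` for an empty class (the value is undefined, not 0).
    """
    widths = [gland_width(g, how) for g in glands if g.label == label]
    if not widths:
        raise ValueError(f"no glands of class {label!r}: AveWidth undefined")
    return float(sum(widths) / len(widths))


def atrophy_index(n_l: int, n_m: int, n_s: int) -> float:
    """(N_L - (N_M + N_S)) / N_T; undefined (error) when no glands exist."""
    n_t = n_l + n_m + n_s
    if n_t <= 0:
        raise ValueError("atrophy index undefined for an empty census")
    return (n_l - (n_m + n_s)) / n_t


@dataclass
class GlandCensus:
    """Per-image summary of the traced glands."""

    n_l: int
    n_m: int
    n_s: int
    ave_width: dict[str, float] = field(default_factory=dict)

    @property
    def n_t(self) -> int:
        return self.n_l + self.n_m + self.n_s

    @property
    def atrophy_index(self) -> float | None:
        if self.n_t == 0:
            return None
        return atrophy_index(self.n_l, self.n_m, self.n_s)

    def to_dict(self) -> dict:
        return {
            "N_L": self.n_l,
            "N_M": self.n_m,
            "N_S": self.n_s,
            "N_T": self.n_t,
            "AveWidth": {k: round(v, 3) for k, v in sorted(self.ave_width.items())},
            "atrophy_index": (
                None if self.atrophy_index is None else round(self.atrophy_index, 6)
            ),
        }

    def to_csv_row(self, image_id: str = "") -> dict:
        row = {"image_id": image_id, "N_L": self.n_l, "N_M": self.n_m,
               "N_S": self.n_s, "N_T": self.n_t}
        for lab in LABELS:
            row[f"AveWidth_{lab}"] = self.ave_width.get(lab)
        row["atrophy_index"] = self.atrophy_index
        return row


def summarize(glands: list[Gland], config: MetricsConfig | None = None) -> GlandCensus:
    """Build the census from a traced gland list."""
    cfg = config or MetricsConfig()
    n_l, n_m, n_s, _ = count_glands(glands)
    widths = {}
    for lab in LABELS:
        try:
            widths[lab] = ave_width(glands, lab, cfg.gland_width)
        except ValueError:
            pass  # empty class: AveWidth absent
    return GlandCensus(n_l, n_m, n_s, widths)
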