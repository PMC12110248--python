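"""Peak detection on gray-value profiles.

Bright gland bodies appear as peaks in the gray-value swing along a profile
line; the tarsus between glands forms the valleys.  Each profile is smoothed
with a linear (order-1) Savitzky-Golay filter of window 11, normalized to
[0, 1] by dividing by 255, and local maxima with prominence >= 0.1 and width
at half prominence >= 2 px are kept as gland candidates.  Near-duplicate
detections of one gland (apexes closer than 10 px) are fused, and peaks wider
than 90 px — illumination artifacts, not glands — are discarded.

Two widths play different roles: the *validity gate* uses the width at half
prominence (the scipy convention), while the *reported* gland width is the
width at 50% of the peak's absolute height, measured on the unsmoothed
normalized profile so the order-1 smoothing (a moving average) does not
inflate narrow glands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import PeakConfig
from .errors import ProfileTooShortError
from .profiles import GrayProfile


@dataclass
class Peak:
    """A gland candidate on one profile line."""

    layer_index: int
    x: int  # column of the apex
    y: float  # row of the profile line at the apex
    height: float  # smoothed normalized gray value at the apex
    prominence: float  # on the [0, 1] scale
    width: float  # width at 50% of peak height, px

    @property
    def position(self) -> tuple[float, float]:
        return (float(self.x), float(self.y))


def smooth_profile(
    profile: GrayProfile,
    window: int = 11,
    order: int = 1,
    mode: str = "savgol",
    moving_average_window: int = 200,
) -> GrayProfile:
    """Smooth a profile and normalize it to [0, 1].

    ``mode="savgol"`` is the production smoother; ``mode="moving_average"``
    (window 200) is the exploratory variant kept for comparison.
    """
    v = np.asarray(profile.values, dtype=float)
    if mode == "moving_average":
        window = min(moving_average_window, len(v))
        if window < 1:
            raise ProfileTooShortError("empty profile")
        from scipy.ndimage import uniform_filter1d

        sm = uniform_filter1d(v, size=window, mode="nearest")
    else:
        if len(v) < window:
            raise ProfileTooShortError(
                f"profile length {len(v)} is below the smoothing window {window}"
            )
        sm = signal.savgol_filter(v, window_length=window, polyorder=order)
    scale = 1.0 if profile.normalized else 255.0
    return GrayProfile(
        profile.layer_index, profile.xs.copy(), sm / scale, profile.ys.copy(),
        normalized=True,
    )


def detect_peaks(
    profile: GrayProfile,
    prominence: float = 0.1,
    min_width: float = 2.0,
    raw_profile: GrayProfile | None = None,
) -> list[Peak]:
    """Detect gland-candidate peaks on a smoothed, normalized profile.

    If ``raw_profile`` (unsmoothed, 0-255) is given, the reported width at
    50% of peak height is measured on it; otherwise on the smoothed signal.
    Half-height crossings are linearly interpolated and bounded by the peak's
    prominence bases.
    """
    if not profile.normalized:
        raise ValueError("detect_peaks expects a smoothed, normalized profile")
    v = np.asarray(profile.values, dtype=float)
    idx, props = signal.find_peaks(v, prominence=prominence, width=min_width)
    if idx.size == 0:
        return []

    if raw_profile is not None:
        raw = np.asarray(raw_profile.values, dtype=float) / 255.0
        # re-center each apex on the raw signal within the smoothing ripple
        ridx = idx.copy()
        for k, i in enumerate(idx):
            lo = max(0, i - 5)
            hi = min(len(raw), i + 6)
            ridx[k] = lo + int(np.argmax(raw[lo:hi]))
        heights = raw[ridx]
        widths = signal.peak_widths(
            raw, ridx, rel_height=0.5,
            prominence_data=(heights, props["left_bases"], props["right_bases"]),
        )[0]
    else:
        heights = v[idx]
        widths = signal.peak_widths(
            v, idx, rel_height=0.5,
            prominence_data=(heights, props["left_bases"], props["right_bases"]),
        )[0]

    peaks = []
    for k, i in enumerate(idx):
        peaks.append(
            Peak(
                layer_index=profile.layer_index,
                x=int(profile.xs[i]),
                y=float(profile.ys[i]),
                height=float(v[i]),
                prominence=float(props["prominences"][k]),
                width=float(widths[k]),
            )
        )
    return peaks


def fuse_close_peaks(
    peaks: list[Peak], min_separation: float = 10.0, fused_height: str = "max"
) -> list[Peak]:
    """Fuse double detections: apexes strictly closer than ``min_separation``
    become one peak at the rounded midpoint with the summed width.

    Fusion is applied pairwise left-to-right and repeated until no pair
    violates the separation; chains of mutually close peaks therefore
    accumulate their widths.  The fused height is the max of the pair
    (configurable to the mean).
    """
    out = sorted(peaks, key=lambda p: p.x)
    changed = True
    while changed:
        changed = False
        merged: list[Peak] = []
        i = 0
        while i < len(out):
            if i + 1 < len(out) and abs(out[i + 1].x - out[i].x) < min_separation:
                a, b = out[i], out[i + 1]
                if fused_height == "mean":
                    h = (a.height + b.height) / 2.0
                else:
                    h = max(a.height, b.height)
                merged.append(
                    Peak(
                        layer_index=a.layer_index,
                        x=int(round((a.x + b.x) / 2.0)),
                        y=(a.y + b.y) / 2.0,
                        height=h,
                        prominence=max(a.prominence, b.prominence),
                        width=a.width + b.width,
                    )
                )
                i += 2
                changed = True
            else:
                merged.append(out[i])
                i += 1
        out = merged
    return out


def drop_wide_peaks(peaks: list[Peak], max_width: float = 90.0) -> list[Peak]:
    """Remove peaks strictly wider than ``max_width`` px (not gland-like)."""
    return [p for p in peaks if not p.width > max_width]


def find_gland_peaks(profile: GrayProfile, config: PeakConfig | None = None) -> list[Peak]:
    """Full peak stage for one profile: smooth, detect, fuse, drop wide."""
    cfg = config or PeakConfig()
    sm = smooth_profile(
        profile, cfg.smooth_window, cfg.smooth_order, cfg.smoothing,
        cfg.moving_average_window,
    )
    raw = profile if cfg.width_on_raw else None
    pk = detect_peaks(sm, cfg.prominence, cfg.min_width, raw_profile=raw)
    pk = fuse_close_peaks(pk, cfg.fuse_separation, cfg.fused_height)
    return drop_wide_peaks(pk, cfg.max_width)


def peaks_to_records(peaks: list[Peak]) -> list[dict]:
    """Flatten peaks for CSV/JSON export (layer, x, y, height, prominence, width)."""
    return [
        {
            "layer": p.layer_index,
            "x": p.x,
            "y": round(p.y, 2),
            "height": round(p.height, 4),
            "prominence": round(p.prominence, 4),
            "width": round(p.width, 2),
        }
        for p in peaks
    ]
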