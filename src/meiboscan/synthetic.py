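"""Synthetic meibography scenes with known ground truth.

Real meibography of the everted lower eyelid shows bright, quasi-vertical
gland bodies (high infrared response of the lipid-filled acini) on a darker
tarsus, inside a curved eyelid band, often with saturated specular
reflections from the moist surface and a mild illumination gradient.  This
module renders that phenomenology from an explicit truth record so every
pipeline stage can be tested without clinical images.

Default study conditions: a 1280x720 canvas, an eyelid band of vertical
extent 142 px with a gentle parabolic bow, tarsus base gray 40 (below the
pipeline's dark cut of 50 — in infrared meibography the tarsus is genuinely
dark next to the bright lipid-filled glands, and the cut exists to flatten it
to pure black), gland amplitude ~120 with Gaussian cross-section sigma in
[5, 15] px, additive sensor noise (sd 2), and at least 40 px horizontal
clearance between glands.  At this scale a full-length gland's 4-layer path
is ~92 px, so the 100 px and 60 px tracing caps act as the intended screens
against implausible diagonal connections.

Rendering is a pure function of the truth (same seed, same image).  What the
generator does *not* emulate: tissue texture inside glands and tarsus, gland
tortuosity, conjunctival prolapse, and partial eversion — results on clean
synthetic scenes bound algorithmic correctness, not clinical accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .metrics import GlandCensus
from .profiles import DEFAULT_DEPTHS

GAUSSIAN_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.355


@dataclass
class EyelidBand:
    """Curved eyelid band geometry: top boundary bows by ``sag`` px at the
    flanks, vertical extent is constant."""

    y_top: float = 240.0  # top-boundary row at the center column
    depth: float = 142.0  # vertical extent, px
    sag: float = 6.0  # parabolic bow of both boundaries, px
    x_left: int = 90
    x_right: int = 1189

    def _u(self, x):
        cx = (self.x_left + self.x_right) / 2.0
        half = (self.x_right - self.x_left) / 2.0
        return (np.asarray(x, dtype=float) - cx) / half

    def top_row(self, x):
        return self.y_top + self.sag * self._u(x) ** 2

    def bottom_row(self, x):
        return self.top_row(x) + self.depth

    def depth_row(self, x, fraction: float):
        return self.top_row(x) + fraction * self.depth


@dataclass
class GlandSpec:
    """One synthetic gland: a near-vertical Gaussian-profile bright stripe.

    ``top_extent`` is the fraction of the band depth the gland reaches,
    measured upward from the lid margin (band bottom): 1.0 is a full-length
    gland, smaller values are shortened glands.  The stripe is hard-truncated
    at its top row, and a row exactly on a profile line counts as crossed.
    """

    x_center: float
    sigma: float = 8.0
    amplitude: float = 120.0
    top_extent: float = 1.0
    tilt: float = 0.0  # horizontal drift of the center path over the band depth, px

    @property
    def start_fraction(self) -> float:
        """Depth fraction of the gland's top end (0 = band top)."""
        return 1.0 - self.top_extent


@dataclass
class SyntheticTruth:
    """Complete, renderable description of one synthetic scene."""

    width: int = 1280
    height: int = 720
    band: EyelidBand = field(default_factory=EyelidBand)
    glands: list[GlandSpec] = field(default_factory=list)
    base_gray: float = 40.0
    noise_sd: float = 1.5
    reflections: list[tuple[float, float, float]] = field(default_factory=list)
    illumination: tuple[str, float] | None = None  # ("lr"|"tb", strength)
    seed: int = 0
    min_clearance: float = 40.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["band"] = EyelidBand(**d["band"])
        d["glands"] = [GlandSpec(**g) for g in d["glands"]]
        d["reflections"] = [tuple(r) for r in d["reflections"]]
        if d.get("illumination"):
            d["illumination"] = tuple(d["illumination"])
        return cls(**d)


def _validate(truth: SyntheticTruth) -> None:
    band = truth.band
    xs = sorted(g.x_center for g in truth.glands)
    for g in truth.glands:
        if not band.x_left + 2 * g.sigma <= g.x_center <= band.x_right - 2 * g.sigma:
            raise ValueError(
                f"gland at x={g.x_center} lies outside the eyelid band"
            )
        if not 0.0 <= g.top_extent <= 1.0:
            raise ValueError("top_extent must be a fraction in [0, 1]")
    for a, b in zip(xs, xs[1:]):
        if b - a < truth.min_clearance:
            raise ValueError(
                f"gland clearance {b - a:.1f} px below minimum {truth.min_clearance}"
            )


def generate(truth: SyntheticTruth) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Render a truth record into (image, eyelid mask, truth).

    Deterministic for a fixed truth (the noise seed is part of the record).
    """
    _validate(truth)
    h, w = truth.height, truth.width
    band = truth.band
    cols = np.arange(w)
    rows = np.arange(h)
    top = band.top_row(cols)
    bot = band.bottom_row(cols)
    in_band = (rows[:, None] >= top[None, :]) & (rows[:, None] <= bot[None, :])
    in_band &= (cols[None, :] >= band.x_left) & (cols[None, :] <= band.x_right)

    img = np.zeros((h, w), dtype=float)
    img[in_band] = truth.base_gray

    for g in truth.glands:
        half = int(np.ceil(4 * g.sigma + abs(g.tilt))) + 2
        x0 = max(0, int(g.x_center) - half)
        x1 = min(w, int(g.x_center) + half + 1)
        X = cols[None, x0:x1].astype(float)
        Y = rows[:, None].astype(float)
        t = band.top_row(X)
        start = t + g.start_fraction * band.depth
        frac_down = np.clip((Y - t) / band.depth, 0.0, 1.0)
        xc = g.x_center + g.tilt * frac_down
        stripe = g.amplitude * np.exp(-((X - xc) ** 2) / (2.0 * g.sigma ** 2))
        # hard truncation at the top end; a row exactly at the start counts
        stripe[Y < start - 1e-9] = 0.0
        stripe[~in_band[:, x0:x1]] = 0.0
        img[:, x0:x1] += stripe

    if truth.illumination is not None:
        axis, strength = truth.illumination
        if axis == "lr":
            ramp = np.linspace(1.0 - strength, 1.0 + strength, w)[None, :]
        else:
            ramp = np.linspace(1.0 - strength, 1.0 + strength, h)[:, None]
        img = img * ramp

    rng = np.random.default_rng(truth.seed)
    if truth.noise_sd > 0:
        img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)

    for cx, cy, r in truth.reflections:
        yy, xx = np.ogrid[:h, :w]
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
        img[disc] = 255.0

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    mask = in_band.astype(np.uint8)
    return img, mask, truth


def expected_class(gland: GlandSpec, band: EyelidBand,
                   depths: tuple[float, ...] = DEFAULT_DEPTHS) -> str | None:
    """Ground-truth class from which profile depths the stripe crosses.

    A gland crossing all depths is L, all but the top one M, the bottom two
    S; a stripe crossing fewer than two lines is below the detector's reach
    and has no class.  A top end exactly on a line counts as crossing it.
    """
    start_row = band.depth_row(gland.x_center, gland.start_fraction)
    n = sum(start_row <= band.depth_row(gland.x_center, d) + 1e-9 for d in depths)
    if n == len(depths):
        return "L"
    if n == len(depths) - 1:
        return "M"
    if n == 2:
        return "S"
    return None


def expected_census(truth: SyntheticTruth,
                    depths: tuple[float, ...] = DEFAULT_DEPTHS) -> GlandCensus:
    """Ground-truth census of a scene, using the same formulas as `metrics`.

    Expected per-class widths come from the Gaussian stripes' closed-form
    FWHM (~2.355 sigma).
    """
    labels = []
    widths: dict[str, list[float]] = {"L": [], "M": [], "S": []}
    for g in truth.glands:
        lab = expected_class(g, truth.band, depths)
        if lab is None:
            continue
        labels.append(lab)
        widths[lab].append(GAUSSIAN_FWHM * g.sigma)
    ave = {k: float(np.mean(v)) for k, v in widths.items() if v}
    return GlandCensus(
        n_l=labels.count("L"), n_m=labels.count("M"), n_s=labels.count("S"),
        ave_width=ave,
    )


def random_scene(
    seed: int,
    n_glands: int | None = None,
    width: int = 1280,
    height: int = 720,
    class_probs: tuple[float, float, float] = (0.6, 0.25, 0.15),
    sigma_range: tuple[float, float] = (5.0, 15.0),
    clearance: float = 40.0,
    noise_sd: float = 1.5,
    n_reflections: int = 0,
    illumination: tuple[str, float] | None = None,
) -> SyntheticTruth:
    """Draw a plausible random scene: 6-12 glands of mixed classes.

    Glands tile the band at a realistic pitch (centers ``clearance`` to
    ``clearance + 25`` px apart, i.e. a gland area fraction around 40-50% as
    in real lids) and the eyelid band is sized to the gland field — large
    bare-tarsus stretches are not a feature of a usable meibography and would
    let the contrast enhancement amplify noise instead of gland structure.
    Shortened glands get top ends well clear of the profile depths so their
    intended class is unambiguous.
    """
    rng = np.random.default_rng(seed)
    if n_glands is None:
        n_glands = int(rng.integers(6, 13))

    base_gray = 40.0
    exposure_target = 105.0  # auto-exposure calibration point of the device
    amplitude_cap = 202.0  # keeps gland cores clear of the saturation floor

    glands: list[GlandSpec] = []
    band = None
    start_ranges = {"L": (0.0, 0.04), "M": (0.20, 0.38), "S": (0.49, 0.52)}
    for _attempt in range(12):
        pitches = rng.uniform(clearance + 5.0, clearance + 25.0,
                              size=max(n_glands - 1, 0))
        margin = 45.0
        x_left = int(rng.uniform(90, 140))
        first = x_left + margin
        positions = first + np.concatenate([[0.0], np.cumsum(pitches)])
        x_right = int(positions[-1] + margin)
        if x_right > width - 60:
            raise ValueError("too many glands for the requested clearance and canvas")
        band = EyelidBand(
            y_top=float(rng.uniform(200, 280)),
            depth=float(rng.uniform(138, 146)),
            sag=float(rng.uniform(2, 6)),
            x_left=x_left, x_right=x_right,
        )
        glands = []
        for x in positions:
            lab = rng.choice(["L", "M", "S"],
                             p=np.asarray(class_probs) / sum(class_probs))
            s0, s1 = start_ranges[str(lab)]
            start = float(rng.uniform(s0, s1))
            glands.append(
                GlandSpec(
                    x_center=float(x),
                    sigma=float(rng.uniform(*sigma_range)),
                    amplitude=float(rng.uniform(0.9, 1.1)),  # relative; scaled below
                    top_extent=1.0 - start,
                    tilt=float(rng.uniform(-3, 3)),
                )
            )
        # auto-exposure: scale amplitudes so the eyelid's mean brightness
        # sits at the device's calibration point
        band_w = band.x_right - band.x_left
        load = sum(
            g.amplitude * g.sigma * np.sqrt(2 * np.pi) * g.top_extent for g in glands
        ) / band_w
        scale = (exposure_target - base_gray) / load
        for g in glands:
            g.amplitude = float(min(g.amplitude * scale, amplitude_cap))
        achieved = base_gray + sum(
            g.amplitude * g.sigma * np.sqrt(2 * np.pi) * g.top_extent for g in glands
        ) / band_w
        if achieved >= 98.0:
            break
        # gland load too thin to expose properly: not a usable meibography,
        # redraw (mirrors the study's good-quality-image requirement)
    assert band is not None

    truth = SyntheticTruth(
        width=width, height=height, band=band, glands=glands,
        noise_sd=noise_sd, illumination=illumination,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    if n_reflections:
        place_reflections(truth, n_reflections, rng)
    return truth


def place_reflections(
    truth: SyntheticTruth, n: int, rng: np.random.Generator | int
) -> SyntheticTruth:
    """Add up to ``n`` saturated discs in gland-free tarsus patches.

    The moist-surface light reflex lands wherever the lid bulges; in a
    densely glanded scene the only stripe-free patches are above shortened
    glands, so discs are placed there (radius <= 15 px, clear of stripe tops
    and the band boundary).  Mutates and returns ``truth``; if no patch fits,
    fewer discs are placed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    band = truth.band
    shortened = [g for g in truth.glands if g.start_fraction > 0.15]
    for _ in range(n):
        for _attempt in range(50):
            if not shortened:
                break
            g = shortened[int(rng.integers(len(shortened)))]
            r = float(rng.uniform(6, 14))
            cx = g.x_center + float(rng.uniform(-8, 8))
            ymin = band.top_row(cx) + r + 4
            ymax = band.depth_row(cx, g.start_fraction) - r - 6
            if ymax <= ymin:
                continue
            cy = float(rng.uniform(ymin, ymax))
            truth.reflections.append((cx, cy, r))
            break
    return truth


def save_scene(truth: SyntheticTruth, out_dir: str | Path, stem: str = "scene") -> dict:
    """Write (image PNG, mask PNG, truth JSON) and return the paths."""
    from .imgio import save_gray, save_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img, mask, _ = generate(truth)
    paths = {
        "image": out / f"{stem}.png",
        "mask": out / f"{stem}_mask.png",
        "truth": out / f"{stem}_truth.json",
    }
    save_gray(paths["image"], img)
    save_mask(paths["mask"], mask)
    paths["truth"].write_text(truth.to_json())
    return {k: str(v) for k, v in paths.items()}
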