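"""Contrast-enhancement chain applied to a raw meibography image.

The working image that profiles are sampled from is produced by, in order:

1. histogram centering — dark images are brightened so the eyelid foreground
   averages gray value 100;
2. specular-reflection removal — saturated connected components (the light
   reflex on the moist eyelid) are located, with a Canny edge response at the
   extreme thresholds computed as a locator, and inpainted with the mean of
   their contour ring;
3. dark cut — pixels below 50 go to pure black;
4. CLAHE — contrast-limited adaptive histogram equalization, clip 12 over a
   20x20 tile grid, to flatten the illumination gradient;
5. gray-value morphological closing with a 5 px disc, removing small dark
   holes inside gland bodies;
6. global histogram equalization, stretching the result over the full 8-bit
   range.

All functions take and return 2-D uint8 arrays of unchanged shape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, feature, morphology

from .config import PreprocessConfig
from .errors import InvalidMaskError

logger = logging.getLogger(__name__)

#: number of histogram bins on an 8-bit image
_NBINS = 256


def _as_u8(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=np.uint8)


def center_histogram(
    img: np.ndarray,
    mask: np.ndarray,
    target: int = 100,
    only_dark: bool = True,
) -> np.ndarray:
    """Shift the histogram so the mask-foreground mean sits at ``target``.

    The shift is a single integer added to every pixel (background included)
    and the result is clipped to [0, 255].  With ``only_dark`` (default),
    images whose foreground is already at or above the target pass through
    unchanged — the correction exists to rescue under-exposed images, not to
    darken bright ones.  Clipping can leave the achieved mean slightly off
    target; without clipping it lands within +-1 of integer rounding.
    """
    img = _as_u8(img)
    fg = np.asarray(mask) > 0
    if not np.any(fg):
        raise InvalidMaskError("cannot center histogram: mask foreground is empty")
    mean = float(img[fg].mean())
    shift = int(round(target - mean))
    if shift == 0 or (only_dark and shift < 0):
        return img.copy()
    out = np.clip(img.astype(np.int16) + shift, 0, 255).astype(np.uint8)
    logger.debug("center_histogram: mean %.2f -> shift %+d", mean, shift)
    return out


@dataclass
class ReflectionComponents:
    """Connected components of saturated (specular-reflection) pixels.

    ``components`` holds one ``(rows, cols)`` index pair per 8-connected
    component; ``edges`` is the Canny response used to localize the light
    reflex (kept for QC overlays, never substituted for the image).
    """

    components: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    edges: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.components)

    @property
    def n_pixels(self) -> int:
        return sum(len(rows) for rows, _ in self.components)


def detect_reflections(
    img: np.ndarray,
    aperture: int = 3,
    lo: int = 0,
    hi: int = 255,
    saturation_floor: int = 250,
) -> ReflectionComponents:
    """Find specular-reflection blobs as 8-connected saturated components.

    A Canny edge response with thresholds at the two extremes of the gray
    range is computed to localize the light reflex; the burned (saturated)
    pixels themselves — everything at or above ``saturation_floor`` — are
    what gets extracted and later inpainted.
    """
    img = _as_u8(img)
    # sigma ~ aperture/3 approximates an aperture-3 derivative kernel's scale
    edges = feature.canny(
        img.astype(float) / 255.0,
        sigma=aperture / 3.0,
        low_threshold=lo / 255.0,
        high_threshold=hi / 255.0,
    )
    saturated = img >= saturation_floor
    labels, n = ndimage.label(saturated, structure=np.ones((3, 3), dtype=int))
    comps = []
    if n:
        objs = ndimage.find_objects(labels)
        for i, sl in enumerate(objs, start=1):
            rows, cols = np.nonzero(labels[sl] == i)
            comps.append((rows + sl[0].start, cols + sl[1].start))
    return ReflectionComponents(components=comps, edges=edges)


def fill_reflections(
    img: np.ndarray, components: ReflectionComponents | list
) -> np.ndarray:
    """Inpaint each saturated component with the mean of its contour ring.

    The contour is the 8-neighbour ring of pixels immediately outside the
    component.  A degenerate component with no ring (e.g. covering the whole
    image) is filled with the global mean instead, with a warning.
    """
    img = _as_u8(img)
    comp_list = (
        components.components
        if isinstance(components, ReflectionComponents)
        else list(components)
    )
    if not comp_list:
        return img.copy()
    out = img.copy()
    h, w = img.shape
    struct = np.ones((3, 3), dtype=bool)
    for rows, cols in comp_list:
        comp_mask = np.zeros((h, w), dtype=bool)
        comp_mask[rows, cols] = True
        ring = ndimage.binary_dilation(comp_mask, structure=struct) & ~comp_mask
        if not np.any(ring):
            fill = int(round(float(img.mean())))
            logger.warning(
                "reflection component with no contour ring; filling with "
                "global mean %d", fill,
            )
        else:
            fill = int(round(float(img[ring].mean())))
        out[rows, cols] = fill
    return out


def black_out_dark(img: np.ndarray, threshold: int = 50, strict: bool = True) -> np.ndarray:
    """Set pixels strictly below ``threshold`` to pure black (0)."""
    img = _as_u8(img)
    out = img.copy()
    dark = (img < threshold) if strict else (img <= threshold)
    out[dark] = 0
    return out


def enhance_local_contrast(
    img: np.ndarray,
    clip_limit: float = 12.0,
    grid: tuple[int, int] = (20, 20),
) -> np.ndarray:
    """CLAHE over a ``grid`` of tiles with an OpenCV-convention clip limit.

    ``clip_limit`` is expressed as a multiple of the mean histogram bin count
    per tile (so 12 means no bin may exceed 12x the uniform level); it is
    converted to the fraction-of-tile convention used by
    ``skimage.exposure.equalize_adapthist`` by dividing by the bin count.
    """
    img = _as_u8(img)
    if img.min() == img.max():
        return img.copy()  # flat histogram: nothing to equalize
    h, w = img.shape
    gy, gx = grid
    kernel = (max(1, math.ceil(h / gy)), max(1, math.ceil(w / gx)))
    if kernel[0] > h or kernel[1] > w:  # pragma: no cover - defensive
        logger.warning("image smaller than one CLAHE tile; using a single tile")
        kernel = (h, w)
    out = exposure.equalize_adapthist(
        img, kernel_size=kernel, clip_limit=clip_limit / _NBINS, nbins=_NBINS
    )
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def close_gray(img: np.ndarray, diameter: int = 5) -> np.ndarray:
    """Gray-value morphological closing with a disc of the given diameter.

    Fills dark holes smaller than the structuring element inside bright gland
    bodies; the output dominates the input pointwise.
    """
    img = _as_u8(img)
    footprint = morphology.disk(diameter // 2)
    return morphology.closing(img, footprint)


def equalize_global(img: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Global histogram equalization stretching gray values over [0, 255].

    Uses the classic integer mapping ``(cdf - cdf_min) / (N - cdf_min) * 255``
    so that the darkest occupied bin maps to 0 and the brightest to 255.
    With ``mask`` the histogram is built from the eyelid foreground only (the
    black frame outside the lid would otherwise dominate the ranks and crush
    the gland/tarsus contrast into the top of the range); the LUT is still
    applied to every pixel.  Constant images are returned unchanged.
    """
    img = _as_u8(img)
    pixels = img if mask is None else img[np.asarray(mask) > 0]
    if pixels.size == 0 or pixels.min() == pixels.max():
        logger.debug("equalize_global: constant image, returned unchanged")
        return img.copy()
    hist = np.bincount(pixels.ravel(), minlength=_NBINS)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    lut = np.rint((cdf - cdf_min) / (cdf[-1] - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[img]


def stretch_global(img: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Linear full-range contrast stretch: foreground min -> 0, max -> 255.

    The rank-based alternative (:func:`equalize_global`) can amplify
    single-gray-level quantization terraces left by CLAHE in blacked-out
    regions into large jumps (their histogram mass is huge), which reads as
    false gland peaks; the linear stretch reaches the same stated goal —
    values spread over the full range, background separated from foreground —
    without manufacturing contrast.  Constant images are returned unchanged.
    """
    img = _as_u8(img)
    pixels = img if mask is None else img[np.asarray(mask) > 0]
    if pixels.size == 0 or pixels.min() == pixels.max():
        logger.debug("stretch_global: constant image, returned unchanged")
        return img.copy()
    lo, hi = int(pixels.min()), int(pixels.max())
    lut = np.clip(np.rint((np.arange(_NBINS) - lo) * 255.0 / (hi - lo)), 0, 255)
    return lut.astype(np.uint8)[img]


@dataclass
class PreprocessInfo:
    """Per-stage summary statistics and warnings from a pipeline run."""

    stages: list[dict] = field(default_factory=list)
    n_reflection_components: int = 0
    n_reflection_pixels: int = 0

    def record(self, name: str, img: np.ndarray) -> None:
        self.stages.append(
            {
                "stage": name,
                "min": int(img.min()),
                "mean": round(float(img.mean()), 3),
                "max": int(img.max()),
            }
        )


def preprocess_pipeline(
    img: np.ndarray,
    mask: np.ndarray,
    config: PreprocessConfig | None = None,
    with_info: bool = False,
):
    """Run the full enhancement chain and return the working image.

    Deterministic: identical (image, mask, config) give identical output.
    With ``with_info`` a :class:`PreprocessInfo` of per-stage statistics is
    returned alongside the image.
    """
    cfg = config or PreprocessConfig()
    img = _as_u8(img)
    if img.shape != np.asarray(mask).shape:
        raise InvalidMaskError(
            f"image {img.shape} and mask {np.asarray(mask).shape} differ in shape"
        )
    info = PreprocessInfo()
    info.record("input", img)
    out = img
    if cfg.enable_center:
        out = center_histogram(out, mask, cfg.center_target, cfg.center_only_dark)
        info.record("center_histogram", out)
    if cfg.enable_reflections:
        comps = detect_reflections(
            out, cfg.canny_aperture, cfg.canny_low, cfg.canny_high,
            cfg.saturation_floor,
        )
        info.n_reflection_components = len(comps)
        info.n_reflection_pixels = comps.n_pixels
        out = fill_reflections(out, comps)
        info.record("fill_reflections", out)
    if cfg.enable_dark:
        out = black_out_dark(out, cfg.dark_threshold, cfg.dark_strict)
        info.record("black_out_dark", out)
    if cfg.enable_clahe:
        out = enhance_local_contrast(out, cfg.clahe_clip_limit, cfg.clahe_grid)
        info.record("clahe", out)
    if cfg.enable_closing:
        out = close_gray(out, cfg.closing_diameter)
        info.record("close_gray", out)
    if cfg.enable_equalize:
        if cfg.equalize_method == "histogram":
            out = equalize_global(out, mask)
        else:
            out = stretch_global(out, mask)
        info.record("equalize_global", out)
    for s in info.stages:
        logger.debug("preprocess %s: min=%d mean=%.2f max=%d",
                     s["stage"], s["min"], s["mean"], s["max"])
    if with_info:
        return out, info
    return out
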