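"""Reading and writing 8-bit grayscale images and binary eyelid masks.

PNG, TIFF and JPEG are supported through Pillow; color inputs are converted
to gray by luminance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DimensionMismatchError, InputError, InvalidMaskError


def load_gray(path: str | Path) -> np.ndarray:
    """Load an image as a 2-D uint8 array (luminance conversion if color)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"image not found: {path}")
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("L"), dtype=np.uint8)
    except InputError:
        raise
    except Exception as exc:  # pragma: no cover - depends on file corruption mode
        raise InputError(f"cannot read image {path}: {exc}") from exc


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask: any nonzero pixel is foreground (1)."""
    arr = load_gray(path)
    return (arr > 0).astype(np.uint8)


def save_gray(path: str | Path, img: np.ndarray) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(path)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    save_gray(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def validate_pair(img: np.ndarray, mask: np.ndarray) -> None:
    """Check image/mask compatibility before analysis."""
    if img.ndim != 2 or mask.ndim != 2:
        raise InputError("image and mask must be 2-D grayscale arrays")
    if img.shape != mask.shape:
        raise DimensionMismatchError(
            f"image {img.shape} and mask {mask.shape} dimensions differ"
        )
    if not np.any(mask):
        raise InvalidMaskError("eyelid mask has an empty foreground")
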