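import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from meiboscan.profiles import GrayProfile
from meiboscan.synthetic import EyelidBand, GlandSpec, SyntheticTruth, generate


def make_profile(values, layer=0, normalized=False):
    """Wrap a plain value sequence as a GrayProfile on row 0."""
    v = np.asarray(values, dtype=float)
    xs = np.arange(len(v))
    return GrayProfile(layer, xs, v, np.zeros_like(v), normalized=normalized)


@pytest.fixture
def rect_mask():
    """Rectangular eyelid foreground: rows 100-299, cols 50-449."""
    m = np.zeros((400, 500), dtype=np.uint8)
    m[100:300, 50:450] = 1
    return m


@pytest.fixture
def clean_scene():
    """A small deterministic scene with one gland of each class."""
    band = EyelidBand(y_top=100.0, depth=142.0, sag=3.0, x_left=40, x_right=360)
    truth = SyntheticTruth(
        width=400, height=400, band=band,
        glands=[
            GlandSpec(x_center=90.0, sigma=8.0, amplitude=180.0, top_extent=1.0),
            GlandSpec(x_center=150.0, sigma=9.0, amplitude=180.0, top_extent=0.70),
            GlandSpec(x_center=210.0, sigma=8.0, amplitude=180.0, top_extent=0.49),
            GlandSpec(x_center=265.0, sigma=7.0, amplitude=180.0, top_extent=1.0),
            GlandSpec(x_center=318.0, sigma=8.0, amplitude=180.0, top_extent=1.0),
        ],
        base_gray=40.0, noise_sd=1.0, seed=7,
    )
    img, mask, _ = generate(truth)
    return img, mask, truth
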