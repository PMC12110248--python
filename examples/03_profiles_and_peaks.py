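"""Profile lines and gland-peak detection on one eyelid.

Four piecewise-linear lines follow the eyelid band at depth fractions
0.10 / 0.45 / 0.55 / 0.75; the gray values under each line are smoothed with
a linear Savitzky-Golay filter (window 11) and peaks with prominence >= 0.1
and width >= 2 px mark gland candidates.
"""

from meiboscan import build_profile_lines, extract_profile, find_gland_peaks
from meiboscan import generate, random_scene
from meiboscan.preprocess import preprocess_pipeline

truth = random_scene(seed=5)
img, mask, _ = generate(truth)
work = preprocess_pipeline(img, mask)

print(f"scene has {len(truth.glands)} glands at columns "
      f"{[round(g.x_center) for g in truth.glands]}")
for line in build_profile_lines(mask):
    profile = extract_profile(work, line)
    peaks = find_gland_peaks(profile)
    print(f"layer {line.layer_index} (depth {line.depth_fraction:.2f}): "
          f"{len(peaks)} peaks at x = {[p.x for p in peaks]}")

# A full-length gland shows up on all four layers; shortened glands are
# missing from the shallow (small-depth) lines -- that difference is what
# the gland tracer turns into length classes.
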