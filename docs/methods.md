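# Methods

## The measurement model

An everted lower eyelid imaged in the near infrared shows the meibomian
glands as bright quasi-vertical stripes against a darker tarsus.  Scanning a
horizontal path across the lid therefore produces an alternating gray-value
signal whose peaks are glands and whose valleys are tarsus.  `meiboscan`
samples that signal along four lines placed at fixed depth fractions of the
eyelid band (0.10, 0.45, 0.55, 0.75 measured downward from the band's upper
boundary) and decides, per gland, how many of the four depths it reaches.
Because glands atrophy by shortening upward from the lid margin, the set of
depths a gland crosses discretizes its length: all four layers → long (L),
the lower three → medium (M), only the lower two → short (S).

Two per-image summaries follow from the labeled census.  `AveWidth_x` is the
mean width of class-`x` glands, each gland summarized by the arithmetic mean
(configurable to median) of its per-layer peak widths measured at 50% of
peak height.  The atrophy index

    (N_L − (N_M + N_S)) / N_T,     N_T = N_L + N_M + N_S,

lies in [−1, 1]; it is +1 exactly when every detected gland is long and −1
exactly when none is, is invariant under rescaling all counts, and is
undefined (an error, not 0) for an empty census.

## Pipeline stages and the parameters that matter

All defaults are carried in `PipelineConfig` and echoed into every analysis
report; units are 8-bit gray levels and pixels at the nominal 1280×720
resolution.

**Histogram centering** (`center_target=100`, dark images only).  The shift
is one integer applied to every pixel; the foreground mean is computed over
the eyelid mask.  Images already at or above the target pass through — the
step is a rescue for under-exposure, not a normalizer.

**Reflection removal** (`saturation_floor=250`).  The specular light reflex
of the moist lid saturates the sensor.  Saturated 8-connected components are
located (a Canny response at the extreme thresholds 0/255, aperture 3, is
computed as a locator and kept for QC, never substituted for the image) and
each component is filled with the rounded mean of its 8-neighbour contour
ring; a degenerate component with no ring falls back to the global mean with
a warning.

**Dark cut** (`dark_threshold=50`, strict `<`).  Pixels below 50 become pure
black.  This stage does real work: the tarsus of a properly exposed
meibography sits below the cut, so the subsequent local contrast enhancement
has a noise-free black background and cannot fabricate structure in
gland-free (dropout) regions.  The boundary is implemented strictly
(`49 → 0`, `50` kept) and is configurable.

**CLAHE** (`clip 12`, `20×20` grid).  The clip is expressed in the
convention where it multiplies the mean histogram bin count per tile
(clip count = 12 × tileArea/256); it is converted to
`skimage.exposure.equalize_adapthist`'s fraction-of-tile convention by
dividing by the 256 bins.  Its role is to flatten the illumination gradient
across the lid.

**Gray-value closing** (disc diameter 5).  Removes small dark holes inside
gland bodies so one gland yields one peak.

**Full-range stage** (`equalize_method`, default `"stretch"`).  The working
image is finally spread over [0, 255] using the eyelid-foreground histogram
(the black frame outside the lid would otherwise dominate the mapping).  Two
methods are implemented.  `"histogram"` is classic equalization with the
cdf-min rule (darkest occupied bin → 0, brightest → 255).  It has a failure
mode on this kind of image: CLAHE leaves the blacked-out tarsus at slightly
different low levels per tile (single-gray-level terraces after uint8
rounding), and because a large share of the foreground mass sits in those
two or three bins, rank equalization stretches the terrace steps into
40–70-gray jumps that read as gland peaks with prominence 0.1–0.25.  The
default `"stretch"` is the linear min–max map over the foreground: it
reaches the same goal — values spread across the full range, background
separated from foreground — while preserving relative contrast, so it cannot
manufacture structure.  Both are exposed; all quantitative checks in the
test suite run with the default.

**Profile lines** (`n_zones=5`, depths above).  The mask's bounding columns
are split into five equal-width zones; in each zone the foreground's
vertical extent is measured and an anchor placed at the depth point of the
zone's horizontal center; anchors are joined by straight segments and
extended flat to the foreground ends, then clamped per column into the
foreground.  Coordinates are 0-based (x = column, y = row, row 0 at top).
Sampling is one value per integer column (the signal is a function of x, not
of arc length); the line's row at each column is linearly interpolated and
rounded.

**Peak stage** (`smooth window 11, order 1`; `prominence 0.1`;
`min_width 2`; `fuse_separation 10`; `max_width 90`).  Smoothing uses a
linear Savitzky–Golay filter — with order 1 and window 11 this is exactly an
11-sample moving average — and the profile is normalized by 255 so the
prominence threshold lives on a [0, 1] scale.  Validity gating uses scipy's
width at half prominence (≥ 2 px).  The *reported* width is the width at 50%
of absolute peak height, measured on the **unsmoothed** normalized profile
(apex re-centered within ±5 samples, interpolated crossings bounded by the
prominence bases): an 11-px moving average widens a σ = 5 px Gaussian
stripe's apparent FWHM by ~20%, so measuring on the raw signal is what keeps
reported widths faithful to the underlying stripe (verified to within a few
tenths of a percent of 2.355σ on rendered stripes, σ ∈ [5, 15]).  Peaks
closer than 10 px (strict) are fused left-to-right to the rounded midpoint
with summed widths and max height, repeating until stable; peaks wider than
90 px (strict) are dropped as illumination artifacts.  An exploratory
moving-average smoother (window 200) is kept behind `smoothing =
"moving_average"` for comparison; Savitzky–Golay is the production default.

**Tracing** (`full_max_len=100`, `pair_max_len=60`).  Peaks are nodes,
profiles are layers; adjacent layers are fully bipartitely connected with
Euclidean weights, and zero-weight supersource/supersink nodes bracket the
top and bottom layers.  Extraction is phased: with all four layers active,
the minimum-weight source→sink path is accepted as an L gland while its
length (virtual edges excluded, which changes nothing numerically) is ≤ 100
px, its nodes are removed, and the search repeats; when the minimal path
first exceeds the cap (or none exists) the top layer is dropped, the
supersource re-attached, and the 3-layer phase yields M glands under the
same cap; with two layers left, remaining edges strictly shorter than 60 px
are taken greedily shortest-first, node-disjointly, as S glands.  The
100/60 caps are maxima screening out implausibly long diagonal connections;
read the other way ("accept only above") the procedure would keep exactly
the diagonal artifacts and discard every vertically coherent gland, so the
screen-maximum reading is the default (`accept="leq"`, with `"lt"`
available).  Equal-length ties break lexicographically by node index for
determinism; returned glands sort by leftmost column.  At the nominal scale
the caps imply an eyelid band of roughly 150 px vertical extent or less (a
full-depth 4-layer path spans 0.65 × extent).

## The synthetic scene generator

`meiboscan.synthetic` renders the phenomenology the detector relies on: a
curved eyelid band (parabolic bow 2–6 px, vertical extent 138–146 px — the
scale at which the 100/60 px caps are meaningful screens), gland stripes
with Gaussian cross-section (σ 5–15 px) hard-truncated at their top end,
tarsus base gray 40 — deliberately below the dark cut, because the cut's job
is to flatten the dark tarsus to black — additive sensor noise (sd 1.5),
optional saturated reflection discs and illumination gradients.  Glands tile
the band at 45–65 px pitch (gland area fraction ≈ 40–50%, as in real lids)
and the band is sized to the gland field.  Scene brightness is
auto-exposed: per-scene gland amplitudes are solved analytically so the
eyelid foreground mean sits at the device calibration point (105), capped at
202 to stay clear of the saturation floor; scenes whose gland load cannot
reach mean ≥ 98 are redrawn, mirroring the quality screening any usable
meibography undergoes.  Shortened glands draw their top ends away from the
profile depths (start fractions [0.20, 0.38] for M, [0.49, 0.52] for S) so
the intended class is unambiguous; a stripe ending exactly on a line counts
as crossing it, matching the renderer's inclusive truncation.  All
randomness flows from explicit seeds; rendering is a pure function of the
truth record.

What the generator does **not** emulate: tissue texture inside glands and
tarsus, gland tortuosity and branching, conjunctival prolapse, incomplete
eversion, and motion blur.  Clean-scene recovery results therefore bound
algorithmic correctness — the chain of filters, detectors and the tracer do
what they claim on images matching the model — not clinical accuracy on
degraded acquisitions, where the published failure modes (heavy reflections,
poor eversion) apply.

## Numerical choices and degenerate inputs

Constant images pass unchanged through both full-range stages; an image
smaller than one CLAHE tile falls back to a single tile.  Empty masks, empty
zones, and profiles shorter than the smoothing window raise typed errors
(`InvalidMaskError`, `ProfileTooShortError`); a zone without foreground is
interpolated across with a warning.  Fewer than two non-empty peak layers
yield an empty gland list, and an empty census has `AveWidth` absent (never
0) and an undefined atrophy index.  The whole pipeline is deterministic:
identical image, mask and config give byte-identical JSON reports.

Verification in the test suite is dual-route throughout: peak detection is
checked against a from-definition prominence scanner, and the Dijkstra
extraction against exhaustive path enumeration, on random inputs; census
arithmetic is checked against closed forms; end-to-end recovery is checked
against the generator's analytic ground truth (problem sizes: 100 random
graphs ≤ 4×5 nodes, 100 profiles ≤ 500 samples, 20 full-resolution scenes).

## Known limitations

Four profile lines discretize gland length into three classes — a gland
must shorten past the 0.10-depth line before its class changes, and nothing
distinguishes a gland ending at depth 0.40 from one ending at 0.12.  The
tracer assumes glands are vertically coherent; strongly tortuous or
branching glands may be split or merged.  Fixed pixel thresholds (100/60/90
px) tie the method to the nominal imaging scale and eyelid size; other
optics require re-tuning via the config.  The eyelid mask is an input — its
quality bounds everything downstream.
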