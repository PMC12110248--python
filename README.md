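# meiboscan

Automated detection and quantification of meibomian glands in infrared
meibography of the everted lower eyelid.

Meibomian glands secrete the lipid layer of the tear film; their shortening
and dropout (meibomian gland dysfunction) drives evaporative dry eye.  In
infrared meibography the glands appear as bright, quasi-vertical stripes on a
darker tarsus.  Manual grading of these images is slow and observer-dependent;
`meiboscan` replaces it with a deterministic gray-value-profile pipeline that
runs in well under a second per image and needs no training data:

1. **Contrast enhancement** — histogram centering at gray value 100 for dark
   images; specular-reflection (light reflex) removal by inpainting saturated
   connected components with their contour mean; dark cut at 50; CLAHE
   (clip 12, 20×20 grid); gray-value closing with a 5 px disc; full-range
   stretch.
2. **Profile sampling** — four piecewise-linear lines follow the eyelid band
   at depth fractions 0.10 / 0.45 / 0.55 / 0.75 (five vertical zones anchor
   the lines to the local foreground extent); the gray value under each line
   is read per column.
3. **Peak detection** — each profile is smoothed with a linear
   Savitzky–Golay filter (window 11) and normalized to [0, 1]; local maxima
   with prominence ≥ 0.1 and width ≥ 2 px are gland candidates; peaks closer
   than 10 px are fused, peaks wider than 90 px discarded.
4. **Gland tracing** — peaks become nodes of a layered graph (adjacent
   layers fully connected, Euclidean edge weights, zero-weight
   supersource/supersink); glands are extracted as repeated Dijkstra shortest
   paths: 4-layer paths within 100 px are **long (L)** glands, after removing
   the top layer 3-layer paths are **medium (M)**, and remaining bottom-pair
   edges under 60 px are **short (S)**.
5. **Census** — per-class counts `N_L, N_M, N_S` (`N_T` total), the mean
   gland width at 50% of peak height per class,

   ```
   AveWidth_x = Σᵢ Width_{x,i} / N_x ,
   ```

   and the **atrophy index**

   ```
   atrophy index = (N_L − (N_M + N_S)) / N_T  ∈ [−1, 1],
   ```

   +1 when every gland spans the full eyelid depth (healthy), −1 when every
   gland is shortened.

No clinical images ship with the package; a first-class synthetic generator
(`meiboscan.synthetic`) renders meibography-like scenes — curved eyelid band,
Gaussian-cross-section gland stripes with known length classes, device
auto-exposure, sensor noise, saturated reflection discs — with exact ground
truth, so every stage is testable end to end.

## Worked example

```python
from meiboscan import analyze_arrays, expected_census, generate, random_scene

truth = random_scene(seed=42)          # 6-12 glands, mixed length classes
img, mask, _ = generate(truth)         # 1280x720 image + eyelid mask
report = analyze_arrays(img, mask)
print(report.census.to_dict())
```

prints

```
{'N_L': 4, 'N_M': 2, 'N_S': 0, 'N_T': 6,
 'AveWidth': {'L': 21.483, 'M': 30.082}, 'atrophy_index': 0.333333}
```

Four long and two medium glands were recovered (matching
`expected_census(truth)` exactly); the atrophy index (4 − 2)/6 ≈ +0.33
describes a mildly atrophic lid; the long glands average 21.5 px width at
half height.  The scripts in `examples/` walk through each capability
(preprocessing stages, profile lines and peaks, graph tracing, atrophy index
and batch stability) and print the numbers they compute.

The same pipeline is available from the shell:

```bash
meiboscan synth --random --seed 3 --out-dir demo        # image+mask+truth
meiboscan analyze --image demo/scene.png --mask demo/scene_mask.png \
    --out-dir results --overlay                         # report + QC overlay
meiboscan batch --images imgs/ --masks masks/ --out cohort.csv
```

`analyze` writes a JSON report (config snapshot, per-layer peak table,
per-gland records, census, warnings), a census CSV row, and an optional
overlay PNG with profile lines, peak markers and gland skeletons.  All
thresholds live in a TOML/JSON config (see `meiboscan.config`) with the
values above as defaults; exit codes are 0 (success), 2 (input error),
3 (no glands found).

## Layout

```
src/meiboscan/
  preprocess.py   contrast-enhancement chain
  profiles.py     eyelid-following profile lines + sampling
  peaks.py        smoothing, peak detection, fusion, width filters
  tracing.py      layered graph, shortest-path gland extraction, L/M/S labels
  metrics.py      census, AveWidth, atrophy index
  synthetic.py    ground-truth scene generator
  report.py       analyze/batch, JSON/CSV reports, QC overlays
  cli.py          thin click CLI (`meiboscan`)
docs/methods.md   model, assumptions, parameter choices, limitations
examples/         one runnable script per capability
```
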