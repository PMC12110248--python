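"""End-to-end analysis, reporting, and QC overlays.

``analyze_arrays`` ties the pipeline together on in-memory arrays;
``analyze`` wraps it with file I/O and writes a JSON report (config snapshot,
per-layer peak table, per-gland records, census, warnings) plus a one-row
census CSV and an optional overlay PNG.  ``batch`` runs matched image/mask
pairs and collects a cohort CSV.  Everything is deterministic: identical
inputs and config give byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import EmptyResultError
from .imgio import load_gray, load_mask, validate_pair
from .metrics import GlandCensus, summarize
from .peaks import find_gland_peaks, peaks_to_records
from .preprocess import preprocess_pipeline
from .profiles import build_profile_lines, extract_profile
from .tracing import Gland, trace_from_peaks

logger = logging.getLogger(__name__)


@dataclass
class AnalysisReport:
    """Everything needed to audit and reproduce one image's analysis."""

    image_id: str
    config: dict
    peaks: list[dict]
    glands: list[dict]
    census: GlandCensus
    warnings: list[str] = field(default_factory=list)
    gland_objects: list[Gland] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "config": self.config,
            "census": self.census.to_dict(),
            "glands": self.glands,
            "peaks": self.peaks,
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def analyze_arrays(
    img: np.ndarray,
    mask: np.ndarray,
    config: PipelineConfig | None = None,
    image_id: str = "",
) -> AnalysisReport:
    """Run preprocess -> profiles -> peaks -> tracing -> census on arrays."""
    cfg = config or PipelineConfig()
    validate_pair(img, mask)
    warnings: list[str] = []

    work, info = preprocess_pipeline(img, mask, cfg.preprocess, with_info=True)
    if info.n_reflection_pixels:
        warnings.append(
            f"filled {info.n_reflection_pixels} reflection pixels in "
            f"{info.n_reflection_components} component(s)"
        )
    lines = build_profile_lines(mask, cfg.profiles.depths, cfg.profiles.n_zones)
    peak_layers = []
    for line in lines:
        profile = extract_profile(work, line)
        peak_layers.append(find_gland_peaks(profile, cfg.peaks))
    glands = trace_from_peaks(peak_layers, cfg.tracing)
    census = summarize(glands, cfg.metrics)
    if not glands:
        warnings.append("no glands detected")
    return AnalysisReport(
        image_id=image_id,
        config=cfg.to_dict(),
        peaks=[r for layer in peak_layers for r in peaks_to_records(layer)],
        glands=[g.to_record() for g in glands],
        census=census,
        warnings=warnings,
        gland_objects=glands,
    )


def render_overlay(
    img: np.ndarray,
    mask: np.ndarray,
    report: AnalysisReport,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """QC overlay: profile lines (blue), peaks (red), gland skeletons (green)
    with width ticks, on the input image.  Returns an (H, W, 3) uint8 array."""
    from PIL import Image, ImageDraw

    cfg = config or PipelineConfig()
    rgb = Image.fromarray(np.asarray(img, dtype=np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(rgb)
    for line in build_profile_lines(mask, cfg.profiles.depths, cfg.profiles.n_zones):
        pts = [(int(x), int(round(y))) for x, y in zip(line.xs[::4], line.ys[::4])]
        draw.line(pts, fill=(60, 120, 255), width=1)
    for p in report.peaks:
        x, y = int(p["x"]), int(round(p["y"]))
        draw.ellipse([x - 2, y - 2, x + 2, y + 2], outline=(255, 60, 60))
    for g in report.glands:
        pts = [(n["x"], int(round(n["y"]))) for n in g["nodes"]]
        if len(pts) >= 2:
            draw.line(pts, fill=(60, 220, 60), width=2)
        for n in g["nodes"]:
            hw = int(round(n["width"] / 2.0))
            y = int(round(n["y"]))
            draw.line([(n["x"] - hw, y), (n["x"] + hw, y)], fill=(60, 220, 60))
    return np.asarray(rgb)


def analyze(
    image_path: str | Path,
    mask_path: str | Path,
    config_path: str | Path | None = None,
    out_dir: str | Path | None = None,
    overlay: bool = False,
) -> AnalysisReport:
    """File-level analysis; writes report JSON / census CSV / overlay PNG."""
    cfg = PipelineConfig.from_file(config_path) if config_path else PipelineConfig()
    img = load_gray(image_path)
    mask = load_mask(mask_path)
    image_id = Path(image_path).stem
    report = analyze_arrays(img, mask, cfg, image_id=image_id)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{image_id}_report.json").write_text(report.to_json())
        pd.DataFrame([report.census.to_csv_row(image_id)]).to_csv(
            out / f"{image_id}_census.csv", index=False
        )
        if overlay:
            from PIL import Image

            arr = render_overlay(img, mask, report, cfg)
            Image.fromarray(arr).save(out / f"{image_id}_overlay.png")
    return report


def batch(
    images_dir: str | Path,
    masks_dir: str | Path,
    config_path: str | Path | None = None,
    out_csv: str | Path | None = None,
    exclude_percentiles: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Analyze all image/mask pairs matched by shared filename stem.

    The mask for ``foo.png`` is ``foo*.png`` in ``masks_dir`` (e.g.
    ``foo_mask.png`` or ``foo.png``).  Unmatched or failing files are skipped
    with a warning.  ``exclude_percentiles`` optionally drops rows whose
    atrophy index falls outside the given cohort percentiles before the
    summary (a cohort-statistics convenience, off by default).
    """
    cfg = PipelineConfig.from_file(config_path) if config_path else PipelineConfig()
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    rows = []
    exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    images = sorted(p for p in images_dir.iterdir()
                    if p.suffix.lower() in exts) if images_dir.exists() else []
    for img_path in images:
        candidates = [
            p for p in sorted(masks_dir.glob(img_path.stem + "*"))
            if p.suffix.lower() in exts
        ] if masks_dir.exists() else []
        if not candidates:
            logger.warning("no mask for %s; skipped", img_path.name)
            continue
        try:
            report = analyze_arrays(
                load_gray(img_path), load_mask(candidates[0]), cfg,
                image_id=img_path.stem,
            )
        except Exception as exc:
            logger.warning("skipping %s: %s", img_path.name, exc)
            continue
        rows.append(report.census.to_csv_row(img_path.stem))
    df = pd.DataFrame(
        rows,
        columns=["image_id", "N_L", "N_M", "N_S", "N_T",
                 "AveWidth_L", "AveWidth_M", "AveWidth_S", "atrophy_index"],
    )
    if exclude_percentiles and len(df):
        lo, hi = np.nanpercentile(df["atrophy_index"].astype(float),
                                  exclude_percentiles)
        df = df[(df["atrophy_index"] >= lo) & (df["atrophy_index"] <= hi)]
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if not len(df):
        logger.warning("batch produced no census rows")
    return df


def require_glands(report: AnalysisReport) -> AnalysisReport:
    """Raise :class:`EmptyResultError` when an analysis found no glands."""
    if report.census.n_t == 0:
        raise EmptyResultError(f"no glands detected in {report.image_id!r}")
    return report
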