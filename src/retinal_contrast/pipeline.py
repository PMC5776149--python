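"""End-to-end pipeline: input map + conversion table -> retinal contrast files.

Chains the stages: synthesize linear scene luminance, build the glare
kernel for the raster geometry, convolve, then write the linear rasters,
their 8-bit log-range encodings, pseudocolor renderings (fixed input range
and output-scaled) and optional horizontal scan profiles.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .convolve import GlareConvolver
from .luminance import map_to_luminance, save_luminance
from .visualize import (
    apply_pseudocolor,
    build_cmap,
    horizontal_scan,
    log_range_scale,
    rescale_to_output,
    save_gray,
    save_rgb,
)

__all__ = ["run_pipeline", "OUTPUT_FILES"]

logger = logging.getLogger(__name__)

#: Files every pipeline run writes to the output directory.
OUTPUT_FILES = (
    "sceneLuminance.tif",
    "retinalContrast.tif",
    "sceneLuminanceLogRange.tiff",
    "retinalContrastLogRange.tiff",
    "retinalContrastLogRange.png",
    "retinalContrastLogRangeOut.png",
)


def run_pipeline(
    input_map: np.ndarray,
    conversion_table: np.ndarray,
    outdir,
    age: float = 25.0,
    pigment: float = 0.5,
    degrees_per_pixel: float = 15.5 / 600.0,
    range_log10: float = 5.4,
    kernel_radius: int | None = None,
    scan_rows: tuple[int, int] | None = None,
) -> dict:
    """Run the full glare calculation and write all analysis files.

    Returns a dict of summary statistics (sums, extrema, log-range digit
    spans) that is also logged.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scene = map_to_luminance(input_map, conversion_table)
    convolver = GlareConvolver(
        age=age, pigment=pigment,
        degrees_per_pixel=degrees_per_pixel, kernel_radius=kernel_radius,
    ).fit(scene)
    retinal = convolver.transform(scene)

    save_luminance(outdir / "sceneLuminance.tif", scene)
    save_luminance(outdir / "retinalContrast.tif", retinal)

    scene_log = log_range_scale(scene, range_log10)
    retinal_log = log_range_scale(retinal, range_log10)
    save_gray(outdir / "sceneLuminanceLogRange.tiff", scene_log)
    save_gray(outdir / "retinalContrastLogRange.tiff", retinal_log)

    cmap = build_cmap()
    save_rgb(outdir / "sceneLuminanceLogRange.png", apply_pseudocolor(scene_log, cmap))
    save_rgb(outdir / "retinalContrastLogRange.png", apply_pseudocolor(retinal_log, cmap))
    retinal_out = rescale_to_output(retinal_log)
    save_rgb(outdir / "retinalContrastLogRangeOut.png", apply_pseudocolor(retinal_out, cmap))

    if scan_rows is not None:
        a, b = scan_rows
        scan_in = horizontal_scan(scene, a, b).rename(
            columns={"log10_relative": "scene_log10_relative"})
        scan_out = horizontal_scan(retinal, a, b)
        scan_in["retinal_log10_relative"] = scan_out["log10_relative"]
        scan_in.to_csv(outdir / "scanProfiles.csv", index=False)

    stats = {
        "input_sum": float(scene.sum()),
        "output_sum": float(retinal.sum()),
        "sum_ratio": float(retinal.sum() / scene.sum()),
        "input_min": float(scene.min()),
        "input_max": float(scene.max()),
        "output_min": float(retinal.min()),
        "output_max": float(retinal.max()),
        "input_digit_span": int(np.ptp(scene_log.digits)),
        "output_digit_span": int(np.ptp(retinal_log.digits)),
        "output_range_log10": float(retinal_out.range_log10),
        "kernel_side": int(convolver.kernel_.shape[0]),
    }
    logger.info("pipeline stats: %s", stats)
    return stats
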