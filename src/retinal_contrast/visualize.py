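"""Log-range scaling, pseudocolor rendering, and scan profiles for HDR rasters.

HDR rasters exceed the range of any display, so inspection goes through an
8-bit log-scaled encoding: digit 255 is the raster maximum (log10 relative
0.0) and digit 0 is ``range_log10`` decades below it (``parameter.range`` in
the pipeline, 5.4 for the reference targets). Pseudocolor then quantizes the
256 digits into 64 ordered colors - 8 progressions of 8 colors ending at
dark brown, red, magenta, blue (the mid-range anchor), cyan, green, yellow
and white - turning hard-to-see smooth glare gradients into countable bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_away

__all__ = [
    "LogRangeImage",
    "log_range_scale",
    "build_cmap",
    "apply_pseudocolor",
    "rescale_to_output",
    "horizontal_scan",
    "save_gray",
    "save_rgb",
    "CMAP_ANCHORS",
]

#: (position in 0..63, RGB) anchors: black start, then the end color of each
#: of the 8 progressions of 8 colors.
CMAP_ANCHORS = (
    (0, (0, 0, 0)),        # black
    (7, (102, 51, 0)),     # dark brown
    (15, (255, 0, 0)),     # red
    (23, (255, 0, 255)),   # magenta
    (31, (0, 0, 255)),     # blue - mid-range anchor (digit 128)
    (39, (0, 255, 255)),   # cyan
    (47, (0, 255, 0)),     # green
    (55, (255, 255, 0)),   # yellow
    (63, (255, 255, 255)), # white = raster maximum
)


@dataclass(frozen=True)
class LogRangeImage:
    """8-bit log-scaled encoding of a linear raster over ``range_log10`` decades."""

    digits: np.ndarray
    range_log10: float


def log_range_scale(raster, range_log10: float) -> LogRangeImage:
    """Scale a linear raster to 8-bit log-range digits.

    ``digit = round(255 * (1 + log10(v / v_max) / range_log10))`` clipped to
    [0, 255]; the raster maximum always lands on digit 255.
    """
    if not np.isfinite(range_log10) or range_log10 <= 0:
        raise ValueError("range_log10 must be positive")
    v = np.asarray(raster, dtype=np.float64)
    if not np.all(v > 0):
        raise ValueError("raster values must be strictly positive to take logarithms")
    rel = np.log10(v / v.max())
    digits = round_half_away(255.0 * (1.0 + rel / range_log10))
    digits = np.clip(digits, 0, 255).astype(np.uint8)
    return LogRangeImage(digits=digits, range_log10=float(range_log10))


def build_cmap() -> np.ndarray:
    """Build the 64-entry pseudocolor palette, shape (64, 3) uint8.

    Piecewise-linear interpolation through the 9 anchors in
    :data:`CMAP_ANCHORS`; deterministic across runs.
    """
    positions = np.array([p for p, _ in CMAP_ANCHORS], dtype=np.float64)
    colors = np.array([c for _, c in CMAP_ANCHORS], dtype=np.float64)
    idx = np.arange(64, dtype=np.float64)
    out = np.stack(
        [np.interp(idx, positions, colors[:, ch]) for ch in range(3)], axis=1
    )
    return round_half_away(out).astype(np.uint8)


def apply_pseudocolor(img, cmap: np.ndarray | None = None) -> np.ndarray:
    """Render a log-range image through the 64-color palette.

    Digits are binned 4 per color with the blue anchor (palette entry 31)
    covering the mid-range digit 128 and entry 63 covering digit 255:
    ``index = clip(ceil(digit / 4) - 1, 0, 63)``.
    """
    if cmap is None:
        cmap = build_cmap()
    cmap = np.asarray(cmap, dtype=np.uint8)
    if cmap.shape != (64, 3):
        raise ValueError(f"cmap must have shape (64, 3), got {cmap.shape}")
    digits = img.digits if isinstance(img, LogRangeImage) else np.asarray(img)
    index = np.clip((digits.astype(np.int64) + 3) // 4 - 1, 0, 63)
    return cmap[index]


def rescale_to_output(img: LogRangeImage) -> LogRangeImage:
    """Re-anchor a log-range image to its own observed digit span.

    The observed minimum digit is reassigned 0 and the maximum 255 (affine,
    round-half-away), and ``range_log10`` shrinks to the spanned sub-range.
    Idempotent; a constant image has no span and is rejected.
    """
    digits = img.digits.astype(np.float64)
    lo, hi = digits.min(), digits.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant image (no digit span)")
    out = round_half_away(255.0 * (digits - lo) / (hi - lo)).astype(np.uint8)
    new_range = img.range_log10 * (hi - lo) / 255.0
    return LogRangeImage(digits=out, range_log10=float(new_range))


def horizontal_scan(raster, row_start: int, row_end: int) -> pd.DataFrame:
    """Per-column mean of a horizontal row band, as log10 relative values.

    Averages the linear values over rows ``row_start..row_end`` (inclusive)
    and reports ``log10(mean / raster_max)`` per column.
    """
    v = np.asarray(raster, dtype=np.float64)
    if not (0 <= row_start <= row_end < v.shape[0]):
        raise ValueError(
            f"row band [{row_start}, {row_end}] out of bounds for height {v.shape[0]}"
        )
    band = v[row_start:row_end + 1].mean(axis=0)
    return pd.DataFrame(
        {
            "column": np.arange(v.shape[1]),
            "log10_relative": np.log10(band / v.max()),
        }
    )


def save_gray(path, img: LogRangeImage | np.ndarray) -> None:
    """Write an 8-bit grayscale TIFF/PNG."""
    import imageio.v3 as iio

    digits = img.digits if isinstance(img, LogRangeImage) else np.asarray(img)
    iio.imwrite(path, digits.astype(np.uint8))


def save_rgb(path, rgb: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(rgb, dtype=np.uint8))
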