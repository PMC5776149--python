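"""Input-map / conversion-table IO and synthesis of linear scene luminance.

An HDR scene is represented losslessly by two small artifacts: an 8-bit
"paint-by-numbers" raster (the input map, digits 0-255 giving the spatial
pattern) and a 256-entry calibration table mapping each digit to a measured
log10 relative luminance. Raising the table entries to the power of ten and
indexing by the map yields the linear, double-precision scene-luminance
array. Digit 0 is reserved for the opaque border / darkroom floor
(log10 = -100, i.e. effectively zero but strictly positive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FLOOR_LOG10",
    "load_input_map",
    "save_input_map",
    "load_conversion_table",
    "save_conversion_table",
    "validate_input_map",
    "validate_conversion_table",
    "map_to_luminance",
    "luminance_to_map",
    "save_luminance",
    "load_luminance",
]

#: log10 relative luminance assigned to the opaque floor (digit 0).
FLOOR_LOG10 = -100.0


def validate_input_map(digits) -> np.ndarray:
    digits = np.asarray(digits)
    if digits.ndim != 2:
        raise ValueError(f"input map must be a single-channel 2-D raster, got shape {digits.shape}")
    if digits.dtype != np.uint8:
        if not np.issubdtype(digits.dtype, np.integer):
            raise ValueError(f"input map must be 8-bit integer, got dtype {digits.dtype}")
        if digits.min() < 0 or digits.max() > 255:
            raise ValueError("input map values must lie in [0, 255]")
        digits = digits.astype(np.uint8)
    return digits


def load_input_map(path) -> np.ndarray:
    """Read an 8-bit single-channel TIFF/PNG input map.

    Multi-channel or >8-bit files are rejected: the map is a paint-by-numbers
    index raster, not a photograph.
    """
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel image, got shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit image, got dtype {arr.dtype}")
    return arr


def save_input_map(path, digits) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, validate_input_map(digits))


def validate_conversion_table(log_lum) -> np.ndarray:
    table = np.asarray(log_lum, dtype=np.float64)
    if table.shape != (256,):
        raise ValueError(f"conversion table must have exactly 256 entries, got {table.size}")
    if not np.all(np.isfinite(table)):
        raise ValueError("conversion table entries must be finite")
    if np.any(table[0] > table[1:]):
        raise ValueError("conversion table entry 0 must be the floor (<= all other entries)")
    if np.any(np.diff(table[1:]) < 0):
        raise ValueError("conversion table entries 1..255 must be monotone non-decreasing")
    return table


def load_conversion_table(path) -> np.ndarray:
    """Read a 256-row ``digit,log10_luminance`` CSV conversion table."""
    df = pd.read_csv(path)
    if "log10_luminance" not in df.columns or "digit" not in df.columns:
        raise ValueError(f"{path}: expected columns 'digit,log10_luminance'")
    if len(df) != 256:
        raise ValueError(f"{path}: conversion table must have 256 rows, got {len(df)}")
    if not np.array_equal(df["digit"].to_numpy(), np.arange(256)):
        raise ValueError(f"{path}: digit column must be 0..255 in order")
    return validate_conversion_table(df["log10_luminance"].to_numpy())


def save_conversion_table(path, log_lum) -> None:
    table = validate_conversion_table(log_lum)
    pd.DataFrame({"digit": np.arange(256), "log10_luminance": table}).to_csv(path, index=False)


def map_to_luminance(digits, table) -> np.ndarray:
    """Synthesize linear scene luminance: ``L[i,j] = 10**table[M[i,j]]``."""
    digits = validate_input_map(digits)
    table = validate_conversion_table(table)
    return np.power(10.0, table)[digits]


def luminance_to_map(luminance, table) -> np.ndarray:
    """Invert :func:`map_to_luminance` for a strictly increasing table.

    Each luminance is matched to the digit whose table entry equals its
    log10; exact for values actually produced by the forward mapping.
    """
    table = validate_conversion_table(table)
    if np.any(np.diff(table) <= 0):
        raise ValueError("inversion requires a strictly increasing table")
    log_v = np.log10(np.asarray(luminance, dtype=np.float64))
    idx = np.searchsorted(table, log_v)
    idx = np.clip(idx, 0, 255)
    # searchsorted returns the left insertion point; snap to the nearer entry
    lower = np.clip(idx - 1, 0, 255)
    pick_lower = np.abs(table[lower] - log_v) < np.abs(table[idx] - log_v)
    return np.where(pick_lower, lower, idx).astype(np.uint8)


def save_luminance(path, values) -> None:
    """Write a linear luminance raster as 64-bit float TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(values, dtype=np.float64))


def load_luminance(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path).astype(np.float64)
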