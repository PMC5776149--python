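"""Synthetic HDR transparency targets.

Emulates the laser-printed double-transparency displays used to study
intraocular glare: a 750x600 px field subtending ~15.5 x 19.1 deg, an
opaque border, 20 pairs of gray test squares, and one of three
backgrounds - uniform white (100% White, maximal glare), uniform black
(0% White, minimal glare), or an equal-area mosaic of white and black
squares sized 1-64 px (50% White).

Luminances are defined through film optical density (OD): one film spans
``film_od_span`` log10 units (default 2.7, a 501:1 range) and two
superimposed identical films double every density (5.4 log10 units,
251,189:1). The generator emits the 8-bit input map, the matching
digit -> log10 luminance conversion table (digit 255 = 0.0 log, digit 0 =
the opaque floor), and a layout record with every square's position, size,
digit and role so region masks are exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .luminance import FLOOR_LOG10, map_to_luminance, save_conversion_table, save_input_map

__all__ = [
    "TargetSpec",
    "Target",
    "TargetSummary",
    "build_conversion_table",
    "generate_target",
    "summarize_target",
    "region_mask",
    "save_target",
]

WHITE_DIGIT = 255  # clear film, OD 0
BLACK_DIGIT = 1    # full film density, OD = film_od_span


@dataclass(frozen=True)
class TargetSpec:
    """Construction parameters of a synthetic transparency target."""

    background: str = "half"  # 'black' (0% White), 'half' (50%), 'white' (100%)
    width_px: int = 750
    height_px: int = 600
    n_test_pairs: int = 20
    film_od_span: float = 2.7
    double_density: bool = True
    mosaic_sizes: tuple = (1, 2, 4, 8, 16, 32, 64)
    pair_od_step: float = 0.15
    test_square_px: int = 24
    border_px: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.background not in ("black", "half", "white"):
            raise ValueError(f"background must be black|half|white, got {self.background!r}")
        if self.film_od_span <= 0:
            raise ValueError("film_od_span must be positive")
        if self.n_test_pairs < 1:
            raise ValueError("n_test_pairs must be >= 1")
        if any(s < 1 for s in self.mosaic_sizes):
            raise ValueError("mosaic sizes must be >= 1")
        if self.pair_od_step < 0 or self.pair_od_step >= self.film_od_span:
            raise ValueError("pair_od_step must lie in [0, film_od_span)")

    @property
    def total_od_span(self) -> float:
        return self.film_od_span * (2.0 if self.double_density else 1.0)


@dataclass
class Target:
    """A generated target: input map raster, conversion table, layout record."""

    input_map: np.ndarray
    conversion_table: np.ndarray
    layout: dict


@dataclass(frozen=True)
class TargetSummary:
    """Max/min/range/average statistics of a target region, in linear units."""

    max_rel: float
    min_rel: float
    range_ratio: float
    range_log10: float
    pct_average: float


def build_conversion_table(film_od_span: float = 2.7, double_density: bool = True) -> np.ndarray:
    """Digit -> log10 relative luminance table for a film target.

    Digit 0 is the opaque floor (-100). Digits 1..255 are linear in optical
    density: digit 255 is clear film (log10 = 0) and digit 1 carries the full
    span, so one film covers exactly ``film_od_span`` decades and two
    superimposed films double every density.
    """
    factor = 2.0 if double_density else 1.0
    table = np.empty(256, dtype=np.float64)
    table[0] = FLOOR_LOG10
    digits = np.arange(1, 256, dtype=np.float64)
    table[1:] = -factor * film_od_span * (255.0 - digits) / 254.0
    return table


def _digit_for_od(od_per_film: float, film_od_span: float) -> int:
    """Nearest digit whose per-film OD equals ``od_per_film`` (1..255)."""
    d = int(round(255.0 - 254.0 * od_per_film / film_od_span))
    return int(np.clip(d, 1, 255))


def _tile_region(occ: np.ndarray, sizes, rng) -> list:
    """Greedily tile the free cells of ``occ`` with squares from ``sizes``.

    Scans top-left to bottom-right; at each uncovered cell places a random
    feasible square. Returns (x, y, size) triples; raises if no size fits
    (the size set cannot tile the region).
    """
    ih, iw = occ.shape
    sizes = sorted(set(int(s) for s in sizes))
    flat = occ.reshape(-1)
    squares = []
    ptr = 0
    n = flat.size
    while ptr < n:
        if flat[ptr]:
            ptr += 1
            continue
        y, x = divmod(ptr, iw)
        feasible = [
            s for s in sizes
            if x + s <= iw and y + s <= ih and not occ[y:y + s, x:x + s].any()
        ]
        if not feasible:
            raise ValueError(
                f"mosaic sizes {sizes} cannot tile the background region: "
                f"no square fits at ({x}, {y})"
            )
        s = feasible[int(rng.integers(len(feasible)))]
        occ[y:y + s, x:x + s] = True
        squares.append((x, y, s))
    return squares


def _balance_colors(squares: list, sizes, rng) -> list:
    """Assign white/black to mosaic squares with equal areas per size class.

    Odd counts are fixed by splitting one square of that size into four of
    half the size (possible for the default power-of-two set); a leftover
    odd count at size 1 leaves at most one smallest square of imbalance.
    Returns (x, y, size, digit) tuples.
    """
    sizes = sorted(set(int(s) for s in sizes), reverse=True)
    by_size = {s: [] for s in sizes}
    for sq in squares:
        by_size[sq[2]].append(sq)
    for s in sizes:
        if len(by_size[s]) % 2 == 0:
            continue
        half = s // 2
        if s > 1 and half in by_size and half * 2 == s:
            x, y, _ = by_size[s].pop(int(rng.integers(len(by_size[s]))))
            by_size[half] += [
                (x, y, half), (x + half, y, half),
                (x, y + half, half), (x + half, y + half, half),
            ]
        elif s > 1:
            raise ValueError(
                f"cannot balance white/black areas: odd number of size-{s} squares "
                "and no half-size square available to split into"
            )
    colored = []
    for s in sizes:
        group = by_size[s]
        order = rng.permutation(len(group))
        for rank, idx in enumerate(order):
            x, y, _ = group[idx]
            digit = WHITE_DIGIT if rank % 2 == 0 else BLACK_DIGIT
            colored.append((x, y, s, digit))
    return colored


def _test_square_layout(spec: TargetSpec, rng):
    """Place the test-square pairs on a grid of slots inside the border."""
    b = spec.border_px
    iw, ih = spec.width_px - 2 * b, spec.height_px - 2 * b
    n = spec.n_test_pairs
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    ts, gap = spec.test_square_px, max(2, spec.test_square_px // 6)
    slot_w, slot_h = iw / cols, ih / rows
    if 2 * ts + gap > slot_w - 2 or ts > slot_h - 2:
        raise ValueError(
            f"{n} test pairs of {ts}px squares do not fit a "
            f"{iw}x{ih}px interior ({cols}x{rows} slots)"
        )
    # pair luminances: bright members log-spaced over the film span, the dark
    # member of the last pair reaching full density
    if n > 1:
        bright_od = np.linspace(0.0, spec.film_od_span - spec.pair_od_step, n)
    else:
        bright_od = np.array([0.0])
    slots = [(c, r) for r in range(rows) for c in range(cols)][:n]
    slot_of_pair = rng.permutation(n)  # scatter luminance pairs over locations
    squares = []
    for pair in range(n):
        c, r = slots[slot_of_pair[pair]]
        x0 = b + int(c * slot_w + (slot_w - 2 * ts - gap) / 2)
        y0 = b + int(r * slot_h + (slot_h - ts) / 2)
        flip = bool(rng.integers(2))  # which member sits left
        for k, member in enumerate(("bright", "dark")):
            od = bright_od[pair] + (spec.pair_od_step if member == "dark" else 0.0)
            digit = _digit_for_od(od, spec.film_od_span)
            if spec.background == "white":
                digit = min(digit, WHITE_DIGIT - 1)  # strictly darker than background
            x = x0 + (ts + gap if (k == 1) != flip else 0)
            squares.append(
                {
                    "id": f"pair{pair:02d}_{member}",
                    "pair": pair,
                    "member": member,
                    "x": x,
                    "y": y0,
                    "size": ts,
                    "digit": digit,
                    "od_per_film": float(od),
                }
            )
    return squares


def generate_target(spec: TargetSpec) -> Target:
    """Generate a synthetic transparency target; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    w, h, b = spec.width_px, spec.height_px, spec.border_px
    if w - 2 * b < 1 or h - 2 * b < 1:
        raise ValueError("border leaves no interior")

    digits = np.zeros((h, w), dtype=np.uint8)  # digit 0 = opaque border
    test_squares = _test_square_layout(spec, rng)

    mosaic = []
    if spec.background == "white":
        digits[b:h - b, b:w - b] = WHITE_DIGIT
    elif spec.background == "black":
        digits[b:h - b, b:w - b] = BLACK_DIGIT
    else:
        occ = np.zeros((h - 2 * b, w - 2 * b), dtype=bool)
        for sq in test_squares:  # keep the mosaic clear of the test patches
            occ[sq["y"] - b:sq["y"] - b + sq["size"],
                sq["x"] - b:sq["x"] - b + sq["size"]] = True
        tiles = _tile_region(occ, spec.mosaic_sizes, rng)
        mosaic = _balance_colors(tiles, spec.mosaic_sizes, rng)
        for x, y, s, digit in mosaic:
            digits[b + y:b + y + s, b + x:b + x + s] = digit

    for sq in test_squares:
        digits[sq["y"]:sq["y"] + sq["size"], sq["x"]:sq["x"] + sq["size"]] = sq["digit"]

    table = build_conversion_table(spec.film_od_span, spec.double_density)
    layout = {
        "spec": asdict(spec),
        "range_log10": spec.total_od_span,
        "test_squares": test_squares,
        "mosaic_squares": [
            {"x": b + x, "y": b + y, "size": s, "digit": d} for x, y, s, d in mosaic
        ],
    }
    return Target(input_map=digits, conversion_table=table, layout=layout)


def region_mask(input_map: np.ndarray, layout: dict, region: str) -> np.ndarray:
    """Boolean mask for ``region`` in {'background', 'test_squares', 'all'}.

    'all' covers every non-border pixel (digit > 0); 'background' excludes
    the test squares; 'test_squares' is their union.
    """
    tests = np.zeros(input_map.shape, dtype=bool)
    for sq in layout["test_squares"]:
        tests[sq["y"]:sq["y"] + sq["size"], sq["x"]:sq["x"] + sq["size"]] = True
    nonborder = np.asarray(input_map) > 0
    if region == "all":
        return nonborder
    if region == "background":
        return nonborder & ~tests
    if region == "test_squares":
        return tests
    raise ValueError(f"unknown region {region!r}")


def summarize_target(
    input_map: np.ndarray,
    conversion_table: np.ndarray,
    layout: dict,
    region: str = "all",
) -> TargetSummary:
    """Max/min/range/%-average statistics of a target region (linear units)."""
    mask = region_mask(input_map, layout, region)
    if not mask.any():
        raise ValueError(f"region {region!r} selects no pixels")
    lum = map_to_luminance(input_map, conversion_table)[mask]
    vmax, vmin = float(lum.max()), float(lum.min())
    return TargetSummary(
        max_rel=vmax,
        min_rel=vmin,
        range_ratio=vmax / vmin,
        range_log10=math.log10(vmax / vmin),
        pct_average=100.0 * float(lum.mean()) / vmax,
    )


def save_target(target: Target, outdir) -> None:
    """Write map TIFF, table CSV, layout JSON and per-region summary CSV."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_input_map(outdir / "inputMap.tif", target.input_map)
    save_conversion_table(outdir / "conversionTable.csv", target.conversion_table)
    with open(outdir / "layout.json", "w") as fh:
        json.dump(target.layout, fh, indent=1)
    rows = []
    for region in ("all", "background", "test_squares"):
        s = summarize_target(target.input_map, target.conversion_table, target.layout, region)
        rows.append({"region": region, **asdict(s)})
    pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False)
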