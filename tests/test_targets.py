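"""Synthetic transparency-target generator and its summary arithmetic."""

import numpy as np
import pytest

from retinal_contrast.targets import (
    TargetSpec,
    build_conversion_table,
    generate_target,
    region_mask,
    save_target,
    summarize_target,
)

SMALL = dict(width_px=120, height_px=100, n_test_pairs=4, test_square_px=8,
             mosaic_sizes=(1, 2, 4, 8, 16))


class TestConversionTableConstruction:
    def test_single_film_spans_2p7_decades(self):
        t = build_conversion_table(2.7, double_density=False)
        assert t[255] == 0.0
        assert t[1] == pytest.approx(-2.7)
        assert t[0] == -100.0

    def test_double_density_doubles_every_entry(self):
        single = build_conversion_table(2.7, False)
        double = build_conversion_table(2.7, True)
        np.testing.assert_allclose(double[1:], 2.0 * single[1:], rtol=1e-15)


class TestGenerateTarget:
    def test_deterministic_for_fixed_seed(self):
        a = generate_target(TargetSpec(background="half", seed=3, **SMALL))
        b = generate_target(TargetSpec(background="half", seed=3, **SMALL))
        np.testing.assert_array_equal(a.input_map, b.input_map)
        assert a.layout == b.layout

    def test_different_seed_changes_layout(self):
        a = generate_target(TargetSpec(background="half", seed=3, **SMALL))
        b = generate_target(TargetSpec(background="half", seed=4, **SMALL))
        assert not np.array_equal(a.input_map, b.input_map)

    def test_border_is_opaque_digit_zero(self, half_target_small):
        m = half_target_small.input_map
        b = half_target_small.layout["spec"]["border_px"]
        assert m[:b].max() == 0 and m[-b:].max() == 0
        assert m[:, :b].max() == 0 and m[:, -b:].max() == 0
        assert m[b:-b, b:-b].min() >= 1

    def test_half_background_mosaic_areas_balance(self, half_target_small):
        mask = region_mask(half_target_small.input_map, half_target_small.layout,
                           "background")
        white = int(((half_target_small.input_map == 255) & mask).sum())
        black = int(((half_target_small.input_map == 1) & mask).sum())
        assert abs(white - black) <= 1  # within one smallest (1 px) square
        assert white + black == int(mask.sum())  # mosaic is only white/black

    def test_white_background_and_darker_test_squares(self):
        tgt = generate_target(TargetSpec(background="white", seed=1, **SMALL))
        bg = region_mask(tgt.input_map, tgt.layout, "background")
        assert np.all(tgt.input_map[bg] == 255)
        assert max(sq["digit"] for sq in tgt.layout["test_squares"]) < 255

    def test_black_background_uniform(self):
        tgt = generate_target(TargetSpec(background="black", seed=1, **SMALL))
        bg = region_mask(tgt.input_map, tgt.layout, "background")
        assert np.all(tgt.input_map[bg] == 1)

    def test_layout_squares_match_raster(self, half_target_small):
        for sq in half_target_small.layout["test_squares"]:
            patch = half_target_small.input_map[sq["y"]:sq["y"] + sq["size"],
                                                sq["x"]:sq["x"] + sq["size"]]
            assert np.all(patch == sq["digit"])

    def test_untileable_mosaic_rejected(self):
        spec = TargetSpec(background="half", mosaic_sizes=(16,), seed=0, **{
            k: v for k, v in SMALL.items() if k != "mosaic_sizes"})
        with pytest.raises(ValueError, match="tile"):
            generate_target(spec)

    def test_oversized_test_squares_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            generate_target(TargetSpec(background="half", width_px=60, height_px=50,
                                       n_test_pairs=20, test_square_px=24))

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="background"):
            TargetSpec(background="plaid")
        with pytest.raises(ValueError, match="film_od_span"):
            TargetSpec(film_od_span=-1)


@pytest.fixture(scope="module")
def single():
    return generate_target(TargetSpec(background="half", double_density=False,
                                      seed=5, **SMALL))


@pytest.fixture(scope="module")
def double():
    return generate_target(TargetSpec(background="half", double_density=True,
                                      seed=5, **SMALL))


class TestSummarizeTarget:
    def test_single_film_test_range_rounds_to_501(self, single):
        s = summarize_target(single.input_map, single.conversion_table,
                             single.layout, "test_squares")
        assert round(s.range_ratio) == 501
        assert s.range_log10 == pytest.approx(2.7)

    def test_double_film_test_range_rounds_to_251189(self, double):
        s = summarize_target(double.input_map, double.conversion_table,
                             double.layout, "test_squares")
        assert round(s.range_ratio) == 251189
        assert s.range_log10 == pytest.approx(5.4)

    def test_double_range_is_square_of_single(self, single, double):
        a = summarize_target(single.input_map, single.conversion_table,
                             single.layout, "all")
        b = summarize_target(double.input_map, double.conversion_table,
                             double.layout, "all")
        assert b.range_log10 == pytest.approx(2 * a.range_log10, rel=1e-12)

    def test_half_double_background_average_is_50_percent(self, double):
        s = summarize_target(double.input_map, double.conversion_table,
                             double.layout, "background")
        assert round(s.pct_average, 2) == 50.00

    def test_darker_blacks_barely_move_the_average(self, single, double):
        """Squaring the black half's density changes the average by <0.1 points:
        the white half carries essentially all the light."""
        a = summarize_target(single.input_map, single.conversion_table,
                             single.layout, "background")
        b = summarize_target(double.input_map, double.conversion_table,
                             double.layout, "background")
        assert abs(a.pct_average - b.pct_average) < 0.1

    def test_empty_region_rejected(self, double):
        layout = dict(double.layout, test_squares=[])
        with pytest.raises(ValueError, match="no pixels"):
            summarize_target(double.input_map, double.conversion_table,
                             layout, "test_squares")


def test_save_target_writes_all_artifacts(tmp_path, half_target_small):
    save_target(half_target_small, tmp_path / "tgt")
    for name in ("inputMap.tif", "conversionTable.csv", "layout.json", "summary.csv"):
        assert (tmp_path / "tgt" / name).exists()
    from retinal_contrast.luminance import load_conversion_table, load_input_map

    np.testing.assert_array_equal(load_input_map(tmp_path / "tgt" / "inputMap.tif"),
                                  half_target_small.input_map)
    load_conversion_table(tmp_path / "tgt" / "conversionTable.csv")
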