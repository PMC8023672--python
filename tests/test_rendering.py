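import numpy as np
import pandas as pd
import pytest

from cytoviz import (
    CategoricalPalette,
    CellTable,
    ChannelDisplay,
    ColorSpec,
    ImageStack,
    RenderedImage,
    SegmentationMask,
    add_scale_bar,
    colorize_mask_by_feature,
    colorize_mask_by_metadata,
    composite_pixels,
    hex_to_rgb,
    outline_cells,
    render_grid,
)
from cytoviz.rendering import boundary_pixels


def cells_for(values, image_name="A", ids=None, extra=None):
    ids = ids if ids is not None else list(range(1, len(values) + 1))
    df = pd.DataFrame({"image_name": image_name, "object_id": ids, "m": values})
    if extra:
        for k, v in extra.items():
            df[k] = v
    return CellTable(df, ["m"])


def two_object_mask():
    labels = np.zeros((4, 4), dtype=np.int64)
    labels[0, 0] = 1
    labels[3, 3] = 2
    return SegmentationMask(labels)


class TestColorizeByFeature:
    def test_ramp_endpoints_hit_first_and_last_colors(self):
        mask = two_object_mask()
        img = colorize_mask_by_feature(mask, cells_for([0.0, 10.0]), "A", "m",
                                       ramp=[(0, 0, 0), (1, 0, 0)])
        np.testing.assert_array_equal(img.rgb[0, 0], [0, 0, 0])
        np.testing.assert_array_equal(img.rgb[3, 3], [1, 0, 0])

    def test_midpoint_interpolates_linearly_in_rgb(self):
        labels = np.zeros((1, 3), dtype=np.int64)
        labels[0] = [1, 2, 3]
        img = colorize_mask_by_feature(
            SegmentationMask(labels), cells_for([0.0, 5.0, 10.0], ids=[1, 2, 3]), "A", "m",
            ramp=[(0, 0, 0), (1, 0, 0)],
        )
        np.testing.assert_allclose(img.rgb[0, 1], [0.5, 0, 0])

    def test_single_cell_degenerate_range_uses_first_color(self):
        labels = np.zeros((2, 2), dtype=np.int64)
        labels[0, 0] = 1
        img = colorize_mask_by_feature(
            SegmentationMask(labels), cells_for([5.0]), "A", "m",
            ramp=[(0, 0, 1), (1, 0, 0)],
        )
        np.testing.assert_array_equal(img.rgb[0, 0], [0, 0, 1])

    def test_missing_object_gets_missing_color_and_background_black(self):
        mask = two_object_mask()
        img = colorize_mask_by_feature(mask, cells_for([1.0], ids=[1]), "A", "m")
        np.testing.assert_array_equal(img.rgb[3, 3], [1, 1, 1])
        np.testing.assert_array_equal(img.rgb[1, 1], [0, 0, 0])

    def test_orphan_table_ids_warn_not_fail(self):
        mask = two_object_mask()
        img = colorize_mask_by_feature(mask, cells_for([1.0, 2.0, 3.0], ids=[1, 2, 99]), "A", "m")
        warnings = [p for k, p in img.annotations if k == "warning"]
        assert warnings and warnings[0]["object_ids"] == [99]

    def test_legend_records_feature_and_range(self):
        mask = two_object_mask()
        img = colorize_mask_by_feature(mask, cells_for([2.0, 8.0]), "A", "m")
        legends = [p for k, p in img.annotations if k == "legend_entry"]
        assert legends[0]["feature"] == "m" and legends[0]["range"] == (2.0, 8.0)

    def test_monotone_ramp_preserves_feature_ordering(self):
        rng = np.random.default_rng(2)
        n = 12
        labels = np.zeros((3, n), dtype=np.int64)
        labels[1, :] = np.arange(1, n + 1)
        values = rng.random(n) * 7
        img = colorize_mask_by_feature(
            SegmentationMask(labels), cells_for(values, ids=list(range(1, n + 1))), "A", "m",
            ramp=[(0, 0, 0), (1, 0, 0)],
        )
        reds = img.rgb[1, :, 0]
        assert np.array_equal(np.argsort(values, kind="stable"), np.argsort(reds, kind="stable"))

    def test_all_nan_feature_is_error(self):
        # markers must be finite, but numeric metadata may carry NaN
        mask = two_object_mask()
        cells = cells_for([1.0, 2.0], extra={"score": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="NaN"):
            colorize_mask_by_feature(mask, cells, "A", "score")


class TestColorizeByMetadata:
    @pytest.fixture
    def typed_cells(self):
        return cells_for([0, 0, 0], ids=[1, 2, 3], extra={"cell_type": ["beta", "Tc", "Th"]})

    @pytest.fixture
    def three_object_mask(self):
        labels = np.zeros((2, 6), dtype=np.int64)
        labels[0, 0], labels[0, 3], labels[1, 5] = 1, 2, 3
        return SegmentationMask(labels)

    @pytest.fixture
    def palette(self):
        return CategoricalPalette(
            colors={"beta": (1, 0, 0), "Tc": (0, 1, 0), "Th": (0, 0, 1)}
        )

    def test_each_level_gets_its_palette_color(self, three_object_mask, typed_cells, palette):
        img = colorize_mask_by_metadata(three_object_mask, typed_cells, "A", "cell_type", palette)
        np.testing.assert_array_equal(img.rgb[0, 0], [1, 0, 0])
        np.testing.assert_array_equal(img.rgb[0, 3], [0, 1, 0])
        np.testing.assert_array_equal(img.rgb[1, 5], [0, 0, 1])

    def test_empty_subset_paints_everything_missing_color(self, three_object_mask, typed_cells, palette):
        img = colorize_mask_by_metadata(
            three_object_mask, typed_cells, "A", "cell_type", palette, subset=set()
        )
        for pos in [(0, 0), (0, 3), (1, 5)]:
            np.testing.assert_array_equal(img.rgb[pos], [1, 1, 1])

    def test_subset_leaves_other_cells_white(self, three_object_mask, typed_cells, palette):
        img = colorize_mask_by_metadata(
            three_object_mask, typed_cells, "A", "cell_type", palette, subset={"Tc", "Th"}
        )
        np.testing.assert_array_equal(img.rgb[0, 0], [1, 1, 1])  # beta not selected
        np.testing.assert_array_equal(img.rgb[0, 3], [0, 1, 0])

    def test_missing_palette_level_is_error_naming_level(self, three_object_mask, typed_cells):
        bad = CategoricalPalette(colors={"beta": (1, 0, 0)})
        with pytest.raises(KeyError, match="Tc"):
            colorize_mask_by_metadata(three_object_mask, typed_cells, "A", "cell_type", bad)

    def test_output_colors_subset_of_palette_and_defaults(self, three_object_mask, typed_cells, palette):
        img = colorize_mask_by_metadata(three_object_mask, typed_cells, "A", "cell_type", palette)
        seen = {tuple(px) for px in img.rgb.reshape(-1, 3)}
        allowed = set(map(tuple, palette.colors.values())) | {
            palette.missing_color, palette.background_color
        }
        assert seen <= allowed

    def test_mask_object_absent_from_table_warns(self, three_object_mask, palette):
        cells = cells_for([0], ids=[1], extra={"cell_type": ["beta"]})
        img = colorize_mask_by_metadata(three_object_mask, cells, "A", "cell_type", palette)
        warnings = [p for k, p in img.annotations if k == "warning"]
        assert any(p["object_ids"] == [2, 3] for p in warnings)


class TestComposite:
    def test_single_red_channel_scales_intensity(self):
        pix = np.full((2, 2, 1), 0.4)
        spec = ColorSpec({"a": ChannelDisplay(color=(1, 0, 0), range_=(0, 1))})
        img = composite_pixels(ImageStack(pix, ["a"]), spec)
        np.testing.assert_allclose(img.rgb[..., 0], 0.4)
        assert np.all(img.rgb[..., 1:] == 0)

    def test_additive_blend_clips_at_one(self):
        pix = np.stack([np.full((2, 2), 0.7), np.full((2, 2), 0.6)], axis=-1)
        spec = ColorSpec({
            "a": ChannelDisplay(color=(1, 0, 0), range_=(0, 1)),
            "b": ChannelDisplay(color=(1, 0, 0), range_=(0, 1)),
        })
        img = composite_pixels(ImageStack(pix, ["a", "b"]), spec)
        np.testing.assert_array_equal(img.rgb[0, 0], [1, 0, 0])

    def test_contrast_multiplies_before_range_mapping(self):
        pix = np.full((1, 1, 1), 0.03)
        spec = ColorSpec({"a": ChannelDisplay(color=(0, 0, 1), contrast=10, range_=(0, 1))})
        img = composite_pixels(ImageStack(pix, ["a"]), spec)
        assert img.rgb[0, 0, 2] == pytest.approx(0.3)

    def test_gamma_applied_after_contrast_and_background(self):
        pix = np.full((1, 1, 1), 0.2)
        spec = ColorSpec({"a": ChannelDisplay(color=(1, 0, 0), contrast=2, background=0.09,
                                              gamma=2.0, range_=(0, 1))})
        img = composite_pixels(ImageStack(pix, ["a"]), spec)
        assert img.rgb[0, 0, 0] == pytest.approx((0.2 * 2 + 0.09) ** 2)

    def test_permutation_invariance_and_unit_range(self):
        rng = np.random.default_rng(9)
        colors = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1)]
        for trial in range(6):
            k = rng.integers(1, 7)
            names = [f"ch{i}" for i in range(k)]
            stack = ImageStack(rng.random((8, 8, k)) * 5, names)
            displays = {n: ChannelDisplay(color=colors[i], contrast=float(rng.uniform(0.5, 3)))
                        for i, n in enumerate(names)}
            fwd = composite_pixels(stack, ColorSpec(displays))
            perm = list(displays.items())
            rng.shuffle(perm)
            rev = composite_pixels(stack, ColorSpec(dict(perm)))
            np.testing.assert_array_equal(fwd.rgb, rev.rgb)
            assert fwd.rgb.min() >= 0.0 and fwd.rgb.max() <= 1.0

    def test_seven_channels_is_hard_error(self):
        names = [f"ch{i}" for i in range(7)]
        stack = ImageStack(np.zeros((2, 2, 7)), names)
        with pytest.raises(ValueError, match="at most 6"):
            ColorSpec({n: ChannelDisplay(color=(1, 0, 0)) for n in names})
        # even a spec assembled around the constructor check is re-checked at render time
        spec = ColorSpec.__new__(ColorSpec)
        spec.channels = {n: ChannelDisplay(color=(1, 0, 0)) for n in names}
        with pytest.raises(ValueError, match="6"):
            composite_pixels(stack, spec)


from conftest import brute_force_boundary  # noqa: E402


class TestOutlines:
    def test_3x3_square_outline_spares_the_centre(self):
        labels = np.zeros((5, 5), dtype=np.int64)
        labels[1:4, 1:4] = 1
        base = RenderedImage(np.zeros((5, 5, 3)))
        out = outline_cells(base, SegmentationMask(labels), default_color=(1, 0, 0))
        red = out.rgb[..., 0] == 1.0
        expected = labels.astype(bool).copy()
        expected[2, 2] = False  # centre pixel is interior
        np.testing.assert_array_equal(red, expected)
        np.testing.assert_array_equal(out.rgb[2, 2], [0, 0, 0])

    def test_empty_mask_returns_base_unchanged(self):
        base = RenderedImage(np.full((4, 4, 3), 0.5))
        out = outline_cells(base, SegmentationMask(np.zeros((4, 4), dtype=int)))
        np.testing.assert_array_equal(out.rgb, base.rgb)

    def test_matches_brute_force_oracle_on_random_masks(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            labels = rng.integers(0, 6, size=(32, 32))
            got = boundary_pixels(labels)
            np.testing.assert_array_equal(got, brute_force_boundary(labels))

    def test_outline_pixels_stay_inside_their_object(self):
        rng = np.random.default_rng(22)
        labels = rng.integers(0, 4, size=(32, 32))
        base = RenderedImage(np.zeros((32, 32, 3)))
        for thickness in (1, 2):
            out = outline_cells(base, SegmentationMask(labels), thickness=thickness,
                                default_color=(1, 0, 0))
            touched = out.rgb[..., 0] == 1.0
            assert np.all(labels[touched] > 0)  # never background, never outside

    def test_metadata_coloured_outlines(self):
        labels = np.zeros((6, 6), dtype=np.int64)
        labels[1:3, 1:3] = 1
        labels[3:5, 3:5] = 2
        cells = cells_for([0, 0], extra={"cell_type": ["beta", "Tc"]})
        palette = CategoricalPalette(colors={"beta": (1, 0, 0), "Tc": (0, 1, 0)})
        base = RenderedImage(np.zeros((6, 6, 3)))
        out = outline_cells(base, SegmentationMask(labels), cells=cells, column="cell_type",
                            palette=palette)
        np.testing.assert_array_equal(out.rgb[1, 1], [1, 0, 0])
        np.testing.assert_array_equal(out.rgb[3, 3], [0, 1, 0])

    def test_thickness_below_one_is_error(self):
        base = RenderedImage(np.zeros((4, 4, 3)))
        with pytest.raises(ValueError, match="thickness"):
            outline_cells(base, SegmentationMask(np.zeros((4, 4), dtype=int)), thickness=0)


class TestScaleBar:
    @pytest.mark.parametrize("length_um,expected_px", [(20, 20), (100, 100)])
    def test_bar_length_in_pixels(self, length_um, expected_px):
        img = RenderedImage(np.zeros((120, 150, 3)), pixel_size_um=1.0)
        out = add_scale_bar(img, length_um)
        bars = [p for k, p in out.annotations if k == "scale_bar"]
        assert bars[0]["length_px"] == expected_px
        assert int((out.rgb[..., 0] == 1).sum(axis=1).max()) == expected_px

    def test_unknown_pixel_size_is_error(self):
        with pytest.raises(ValueError, match="pixel size"):
            add_scale_bar(RenderedImage(np.zeros((10, 10, 3))), 20)

    def test_bar_wider_than_image_is_error(self):
        img = RenderedImage(np.zeros((80, 80, 3)), pixel_size_um=1.0)
        with pytest.raises(ValueError, match="exceeds"):
            add_scale_bar(img, 100)


class TestRenderGrid:
    def test_100_panels_in_10_columns_make_10_rows(self):
        panels = [RenderedImage(np.zeros((4, 4, 3))) for _ in range(100)]
        grid = render_grid(panels, columns=10, margin_px=1)
        layout = [p for k, p in grid.annotations if k == "title"][0]["layout"]
        assert layout == (10, 10)
        assert grid.rgb.shape == (10 * 4 + 11, 10 * 4 + 11, 3)

    def test_single_panel_is_itself_plus_margin(self):
        panel = RenderedImage(np.full((3, 5, 3), 0.25))
        grid = render_grid([panel], columns=1, margin_px=2)
        assert grid.rgb.shape == (3 + 4, 5 + 4, 3)
        np.testing.assert_array_equal(grid.rgb[2:5, 2:7], panel.rgb)

    def test_short_last_row_padded_with_background(self):
        panels = [RenderedImage(np.ones((2, 2, 3))) for _ in range(5)]
        grid = render_grid(panels, columns=3, margin_px=0)
        assert grid.rgb.shape == (4, 6, 3)
        np.testing.assert_array_equal(grid.rgb[2:4, 4:6], np.zeros((2, 2, 3)))


def test_hex_colour_parsing():
    assert hex_to_rgb("#ff0000") == (1.0, 0.0, 0.0)
    assert hex_to_rgb("#000080") == (0.0, 0.0, 128 / 255)
    with pytest.raises(ValueError):
        hex_to_rgb("#ff00")
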