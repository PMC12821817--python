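from __future__ import annotations

import numpy as np
import pytest
import tifffile
from scipy import ndimage

from ttikit.imaging import (
    ImageStack,
    Transect,
    enhance_contrast,
    extract_profile,
    read_image,
    read_profile_csv,
    read_profiles_long,
    read_transects,
    smooth_image,
    transect_length,
    write_image,
    write_profile_csv,
    write_profiles_long,
    write_transects,
)


class TestImageStack:
    def test_rejects_out_of_range_intensities(self):
        with pytest.raises(ValueError, match="outside"):
            ImageStack(pixels=np.full((4, 4), 300), pixel_size_um=0.1, bit_depth=8)

    def test_rejects_tiny_planes(self):
        with pytest.raises(ValueError, match="2x2"):
            ImageStack(pixels=np.zeros((1, 5)), pixel_size_um=0.1)

    def test_plane_selection_3d(self):
        img = ImageStack(pixels=np.zeros((3, 4, 5), dtype=np.uint8), pixel_size_um=0.1)
        assert img.n_planes == 3
        assert img.plane(2).shape == (4, 5)
        with pytest.raises(IndexError):
            img.plane(3)


class TestSmoothImage:
    def test_constant_plane_is_fixed_point(self, flat_image):
        out = smooth_image(flat_image, rounds=5)
        np.testing.assert_array_equal(out.pixels, flat_image.pixels)

    def test_single_bright_pixel_spreads_to_mean(self):
        pixels = np.zeros((5, 5), dtype=np.uint8)
        pixels[2, 2] = 9
        img = ImageStack(pixels=pixels, pixel_size_um=0.1)
        out = smooth_image(img, rounds=1).pixels
        expected = np.zeros((5, 5), dtype=np.uint8)
        expected[1:4, 1:4] = 1
        np.testing.assert_array_equal(out, expected)

    def test_delta_matches_direct_convolution_and_conserves_mass(self):
        pixels = np.zeros((15, 15), dtype=np.uint8)
        pixels[7, 7] = 200
        img = ImageStack(pixels=pixels, pixel_size_um=0.1)
        out = smooth_image(img, rounds=3).pixels
        # independent oracle: repeated float convolution, rounded at the end
        ref = pixels.astype(float)
        for _ in range(3):
            ref = ndimage.uniform_filter(ref, size=3, mode="reflect")
        np.testing.assert_array_equal(out, np.floor(ref + 0.5).astype(np.uint8))
        support = np.argwhere(out > 0)
        span = support.max(axis=0) - support.min(axis=0)
        assert tuple(span) == (6, 6)  # 7x7 support after 3 rounds
        assert abs(int(out.sum()) - 200) <= out.size  # one count per pixel

    def test_zero_rounds_is_identity(self, flat_image):
        assert smooth_image(flat_image, rounds=0) is flat_image


class TestEnhanceContrast:
    def test_full_range_image_unchanged(self):
        pixels = np.linspace(0, 255, 100, dtype=np.uint8).reshape(10, 10)
        img = ImageStack(pixels=pixels, pixel_size_um=0.1)
        out = enhance_contrast(img, saturated_fraction=0.0)
        np.testing.assert_array_equal(out.pixels, pixels)

    def test_two_valued_image_maps_to_range_ends(self):
        pixels = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 10, 20).astype(np.uint8)
        img = ImageStack(pixels=pixels, pixel_size_um=0.1)
        out = enhance_contrast(img, saturated_fraction=0.0).pixels
        assert set(np.unique(out)) == {0, 255}

    def test_constant_image_unchanged(self, flat_image):
        out = enhance_contrast(flat_image, saturated_fraction=0.1)
        np.testing.assert_array_equal(out.pixels, flat_image.pixels)

    def test_preserves_rank_order_up_to_ties(self, rng):
        pixels = rng.integers(0, 256, size=(30, 30)).astype(np.uint8)
        img = ImageStack(pixels=pixels, pixel_size_um=0.1)
        out = enhance_contrast(img, saturated_fraction=0.02).pixels
        a, b = pixels.ravel().astype(int), out.ravel().astype(int)
        order = np.argsort(a, kind="stable")
        diffs_in = np.diff(a[order])
        diffs_out = np.diff(b[order])
        assert np.all(diffs_out[diffs_in > 0] >= 0)


class TestExtractProfile:
    def test_horizontal_constant_transect(self, flat_image):
        t = Transect("c1", "diagonal", x0=5, y0=10, x1=15, y1=10)
        p = extract_profile(flat_image, t)
        assert len(p) == 11
        np.testing.assert_allclose(p.intensity, 7.0)
        assert p.transect_length_um == pytest.approx(1.0)
        assert p.distance_um[-1] == pytest.approx(1.0)

    def test_diagonal_over_single_bright_line_has_one_maximum(self):
        pixels = np.zeros((40, 40), dtype=np.uint8)
        pixels[:, 20] = 200  # 1-px bright vertical line
        img = ImageStack(pixels=pixels, pixel_size_um=0.1)
        t = Transect("c1", "diagonal", x0=5, y0=5, x1=35, y1=30)
        p = extract_profile(img, t)
        from .oracles import brute_force_local_maxima

        assert len(brute_force_local_maxima(p.intensity)) == 1

    def test_reversed_transect_reverses_profile_exactly(self, rng):
        pixels = rng.integers(0, 256, size=(50, 60)).astype(np.uint8)
        img = ImageStack(pixels=pixels, pixel_size_um=0.2)
        t = Transect("c1", "diagonal", x0=3.2, y0=4.1, x1=55.4, y1=44.9)
        forward = extract_profile(img, t)
        backward = extract_profile(img, t.reversed())
        np.testing.assert_array_equal(forward.intensity, backward.intensity[::-1])
        assert forward.transect_length_um == backward.transect_length_um

    def test_out_of_bounds_transect_names_cell(self, flat_image):
        t = Transect("bad_cell", "diagonal", x0=0, y0=0, x1=100, y1=5)
        with pytest.raises(ValueError, match="bad_cell"):
            extract_profile(flat_image, t)


class TestEnhancementPipelineProperty:
    def test_crossing_counts_agree_between_raw_and_enhanced_images(self):
        """Contrast enhancement must not change what is counted.

        The ratio filters (med_ratio, min_ratio) are scale-free by design;
        the absolute-unit prominence filter is set on the matching intensity
        scale (scaled by the enhancement gain), after which counts agree on
        at least 95% of transects.
        """
        from ttikit import synth
        from ttikit.peakcall import PeakParams
        from ttikit.pipeline import analyze_transect

        pop = synth.benchmark_population(5, n_cells=40)
        cells = synth.sample_population(pop)
        agree = 0
        for cell in cells:
            _, raw = analyze_transect(cell.image, cell.diagonal, PeakParams())
            plane = cell.image.pixels.astype(float)
            lo, hi = np.quantile(plane, [0.0035, 1 - 0.0035])
            gain = 255.0 / (hi - lo)
            enhanced = enhance_contrast(cell.image, 0.0035)
            _, enh = analyze_transect(
                enhanced, cell.diagonal, PeakParams(prominence=10.0 * gain)
            )
            agree += raw.count == enh.count
        assert agree >= 0.95 * len(cells)


class TestTransectLength:
    @pytest.mark.parametrize(
        "x0,y0,x1,y1,px,expected",
        [(0, 0, 3, 4, 1.0, 5.0), (0, 0, 0, 10, 0.2, 2.0)],
    )
    def test_euclidean_times_pixel_size(self, x0, y0, x1, y1, px, expected):
        t = Transect("c", "diagonal", x0=x0, y0=y0, x1=x1, y1=y1)
        assert transect_length(t, px) == pytest.approx(expected)

    def test_agrees_with_extract_profile(self, rng, flat_image):
        for _ in range(10):
            x0, x1 = rng.uniform(0, 29, 2)
            y0, y1 = rng.uniform(0, 19, 2)
            t = Transect("c", "diagonal", x0=x0, y0=y0, x1=x1, y1=y1)
            if t.length_px < 2:
                continue
            p = extract_profile(flat_image, t)
            assert p.transect_length_um == pytest.approx(
                transect_length(t, flat_image.pixel_size_um)
            )


class TestFileIO:
    def test_tiff_round_trip(self, tmp_path, rng):
        pixels = rng.integers(0, 65535, size=(20, 25)).astype(np.uint16)
        img = ImageStack(pixels=pixels, pixel_size_um=0.13, bit_depth=16)
        path = tmp_path / "cell.tif"
        write_image(img, path)
        back = read_image(path, pixel_size_um=0.13)
        np.testing.assert_array_equal(back.pixels, pixels)
        assert back.bit_depth == 16

    def test_ome_pixel_size_from_metadata(self, tmp_path):
        path = tmp_path / "cell.ome.tif"
        tifffile.imwrite(
            path,
            np.zeros((10, 12), dtype=np.uint8),
            ome=True,
            metadata={"axes": "YX", "PhysicalSizeX": 0.21, "PhysicalSizeY": 0.21},
        )
        img = read_image(path)
        assert img.pixel_size_um == pytest.approx(0.21)

    def test_missing_calibration_instructs_user(self, tmp_path):
        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="pixel-size-um"):
            read_image(path)

    def test_transect_csv_round_trip(self, tmp_path):
        transects = [
            Transect("c1", "diagonal", 0, 0, 10, 8, z_index=2, direction_label="main"),
            Transect("c1", "longitudinal", 0, 4, 10, 4),
        ]
        path = tmp_path / "transects.csv"
        write_transects(transects, path)
        back = read_transects(path)
        assert back == transects

    def test_profile_csv_round_trip(self, tmp_path, profile_factory):
        p = profile_factory([5.0, 20.0, 7.0, 3.0, 11.0], cell_id="cellA")
        path = tmp_path / "cellA.csv"
        write_profile_csv(p, path)
        back = read_profile_csv(path)
        assert back.cell_id == "cellA"
        np.testing.assert_allclose(back.intensity, p.intensity, atol=1e-6)
        np.testing.assert_allclose(back.distance_um, p.distance_um, atol=1e-6)

    def test_long_format_round_trip(self, tmp_path, profile_factory):
        profiles = [
            profile_factory([1.0, 9.0, 2.0, 1.0], cell_id="a"),
            profile_factory([0.0, 3.0, 8.0, 3.0, 0.0], cell_id="b"),
        ]
        path = tmp_path / "profiles.csv"
        write_profiles_long(profiles, path)
        back = read_profiles_long(path)
        assert [p.cell_id for p in back] == ["a", "b"]
        np.testing.assert_allclose(back[1].intensity, profiles[1].intensity, atol=1e-6)
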