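"""Green-dominance filtering, ROI extraction and per-ROI statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

from icgquant.exceptions import (
    BoundsError,
    EmptyROIError,
    ImageFormatError,
    SamplingError,
)
from icgquant.image import (
    ROI,
    RGBImage,
    auto_sample_rois,
    export_pixels,
    extract_roi_values,
    green_dominance_mask,
    load_image,
    quantify_segment,
    read_roi_csv,
    roi_statistics,
    save_image,
    write_roi_csv,
)
from icgquant.synthetic import SyntheticImageSpec, generate_synthetic_image

from conftest import make_image


rgb_arrays = hnp.arrays(
    dtype=np.uint8,
    shape=hst.tuples(
        hst.integers(1, 12), hst.integers(1, 12), hst.just(3)
    ),
)


class TestLoadImage:
    def test_lossless_round_trip_of_synthetic_image(self, tmp_path):
        img, _ = generate_synthetic_image(
            SyntheticImageSpec(height=64, width=64, base_green=147, noise_sd=8,
                               reflection_fraction=0.1, n_vessels=2, seed=3)
        )
        path = tmp_path / "frame.png"
        save_image(img, path)
        back = load_image(path)
        np.testing.assert_array_equal(back.pixels, img.pixels)

    @pytest.mark.parametrize(
        "pixel, expected",
        [((0, 255, 0), (0, 255, 0)), ((255, 255, 255), (255, 255, 255))],
    )
    def test_single_color_decode(self, tmp_path, pixel, expected):
        img = make_image(*pixel)
        path = tmp_path / "px.png"
        save_image(img, path)
        back = load_image(path)
        assert tuple(back.pixels[0, 0]) == expected

    def test_alpha_channel_dropped(self, tmp_path):
        from PIL import Image as PILImage

        arr = np.zeros((2, 2, 4), dtype=np.uint8)
        arr[..., 1] = 200
        arr[..., 3] = 128
        PILImage.fromarray(arr, mode="RGBA").save(tmp_path / "a.png")
        back = load_image(tmp_path / "a.png")
        assert back.pixels.shape == (2, 2, 3)
        assert back.g[0, 0] == 200

    def test_missing_file_raises_ioerror_naming_path(self, tmp_path):
        with pytest.raises(IOError, match="nope.png"):
            load_image(tmp_path / "nope.png")

    def test_corrupt_file_raises_ioerror(self, tmp_path):
        bad = tmp_path / "bad.png"
        bad.write_bytes(b"not an image at all")
        with pytest.raises(IOError):
            load_image(bad)

    def test_mismatched_channels_rejected(self):
        with pytest.raises(ImageFormatError):
            RGBImage.from_channels(
                np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2))
            )


class TestGreenDominance:
    def test_exhaustive_three_level_oracle(self):
        """Strict dominance over every (R,G,B) combination of {0,100,255}."""
        triples = list(itertools.product([0, 100, 255], repeat=3))
        arr = np.array(triples, dtype=np.uint8).reshape(3, 9, 3)
        mask = green_dominance_mask(RGBImage(arr))
        for (r, g, b), got in zip(triples, mask.ravel()):
            assert got == (g > r and g > b)

    @pytest.mark.parametrize(
        "pixel, retained",
        [
            ((0, 255, 0), True),      # pure green
            ((255, 255, 255), False),  # white reflection
            ((100, 100, 50), False),   # green ties red
            ((99, 100, 99), True),
            ((0, 0, 0), False),        # black, R=G=B
        ],
    )
    def test_dominance_rule_examples(self, pixel, retained):
        img = make_image(*pixel)
        assert green_dominance_mask(img)[0, 0] == retained

    @settings(max_examples=60, derandomize=True)
    @given(rgb_arrays)
    def test_mask_matches_per_pixel_loop_and_never_retains_grays(self, arr):
        img = RGBImage(arr)
        mask = green_dominance_mask(img)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                r, g, b = (int(v) for v in arr[i, j])
                assert mask[i, j] == (g > r and g > b)
                if r == g == b:
                    assert not mask[i, j]

    def test_masking_is_idempotent(self, rng):
        arr = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        img = RGBImage(arr)
        m1 = green_dominance_mask(img)
        m2 = green_dominance_mask(img)
        np.testing.assert_array_equal(m1, m2)


class TestExtractROI:
    def test_uniform_field(self):
        img = make_image(0, np.full((12, 12), 134), 0)
        vals = extract_roi_values(img, ROI(1, 1, 10, 10))
        assert vals.size == 100
        assert (vals == 134).all()

    def test_mixed_white_and_green(self, rng):
        g = np.full((10, 10), 150, dtype=np.uint8)
        r = np.zeros((10, 10), dtype=np.uint8)
        b = np.zeros((10, 10), dtype=np.uint8)
        white = rng.choice(100, size=40, replace=False)
        for idx in white:
            r.flat[idx] = g.flat[idx] = b.flat[idx] = 255
        img = RGBImage.from_channels(r, g, b)
        vals = extract_roi_values(img, ROI(0, 0, 10, 10))
        assert vals.size == 60
        assert (vals == 150).all()

    def test_fully_masked_pixel_gives_empty(self):
        img = make_image(255, 255, 255)
        assert extract_roi_values(img, ROI(0, 0, 1, 1)).size == 0

    def test_out_of_bounds_reports_coordinates(self):
        img = make_image(0, np.zeros((5, 5)), 0)
        with pytest.raises(BoundsError, match="rows 2:8"):
            extract_roi_values(img, ROI(2, 0, 6, 3))


class TestROIStatistics:
    def test_constant_input(self):
        st = roi_statistics([134] * 100, 100)
        assert st.mean == 134 and st.sd == 0 and st.median == 134
        assert st.histogram[134] == 100 and st.histogram.sum() == st.n_retained

    def test_partial_retention_counts(self):
        st = roi_statistics([150] * 60, 100)
        assert st.n_retained == 60 and st.n_total == 100 and st.mean == 150
        assert st.low_retention is False

    def test_two_point_symmetry(self):
        st = roi_statistics([0, 255], 2)
        assert st.mean == 127.5 and st.min == 0 and st.max == 255

    def test_quartile_ordering_and_bounds(self, rng):
        vals = rng.integers(0, 256, size=200)
        st = roi_statistics(vals, 200)
        assert st.min <= st.q1 <= st.median <= st.q3 <= st.max
        assert 0 <= st.mean <= 255 and 0 <= st.median <= 255

    def test_empty_values_raise(self):
        with pytest.raises(EmptyROIError):
            roi_statistics([], 100)

    def test_low_retention_flag(self):
        assert roi_statistics([10] * 40, 100).low_retention is True


class TestQuantifySegment:
    def test_equal_size_average(self):
        g = np.zeros((10, 30), dtype=np.uint8)
        g[:, :10] = 140
        g[:, 20:] = 160
        img = make_image(0, g, 0)
        q = quantify_segment(img, [ROI(0, 0, 10, 10), ROI(0, 20, 10, 10)])
        assert q.pooled_mean == 150

    def test_pixel_weighted_pooling_not_mean_of_means(self, rng):
        g = np.full((10, 25), 100, dtype=np.uint8)
        r = np.zeros_like(g)
        b = np.zeros_like(g)
        g[:, 15:] = 200
        # whiten half of the second ROI so only 50 of its pixels survive
        white = rng.choice(100, size=50, replace=False)
        sub = np.s_[:, 15:]
        for idx in white:
            r[sub].flat[idx] = 255
            g[sub].flat[idx] = 255
            b[sub].flat[idx] = 255
        img = RGBImage.from_channels(r, g, b)
        q = quantify_segment(img, [ROI(0, 0, 10, 10), ROI(0, 15, 10, 10)])
        assert q.pooled_mean == pytest.approx((100 * 100 + 50 * 200) / 150)

    def test_uniform_field_many_rois(self, uniform_image):
        img, _ = uniform_image
        rois = [ROI(0, 10 * k, 10, 10, roi_id=str(k)) for k in range(6)]
        q = quantify_segment(img, rois)
        assert q.pooled_mean == 147
        assert q.n_retained == q.n_total == 600

    @settings(max_examples=40, derandomize=True)
    @given(
        hnp.arrays(dtype=np.uint8, shape=(8, 8, 3)),
    )
    def test_pooled_mean_matches_naive_loop_on_random_images(self, arr):
        """Whole-image quantification equals a per-pixel G>R and G>B loop."""
        img = RGBImage(arr)
        vals = [
            int(arr[i, j, 1])
            for i in range(8)
            for j in range(8)
            if arr[i, j, 1] > arr[i, j, 0] and arr[i, j, 1] > arr[i, j, 2]
        ]
        if not vals:
            with pytest.raises(Exception):
                quantify_segment(img, [ROI(0, 0, 8, 8)])
        else:
            q = quantify_segment(img, [ROI(0, 0, 8, 8)])
            assert q.pooled_mean == np.mean(vals)
            assert q.n_retained == len(vals)

    def test_reflection_immunity(self, rng):
        """Whitening pixels only removes them; survivors' pooled mean values
        are untouched."""
        spec = SyntheticImageSpec(height=40, width=40, base_green=150,
                                  noise_sd=10, seed=7)
        img, _ = generate_synthetic_image(spec)
        roi = ROI(5, 5, 20, 20)
        before = extract_roi_values(img, roi)
        arr = img.pixels.copy()
        rows = rng.integers(5, 25, size=60)
        cols = rng.integers(5, 25, size=60)
        arr[rows, cols] = 255
        after = extract_roi_values(RGBImage(arr), roi)
        whitened = set(zip(rows.tolist(), cols.tolist()))
        survivors = [
            int(img.g[i, j])
            for i in range(5, 25)
            for j in range(5, 25)
            if (i, j) not in whitened
            and img.g[i, j] > img.r[i, j]
            and img.g[i, j] > img.b[i, j]
        ]
        assert sorted(after.tolist()) == sorted(survivors)
        assert after.size <= before.size

    def test_ground_truth_recovery_within_standard_error(self):
        """Pooled mean over >=1000 retained pixels stays within 3*sd/sqrt(n)
        of the generator's base green level, despite 30% reflections."""
        spec = SyntheticImageSpec(height=80, width=80, base_green=147,
                                  noise_sd=8, reflection_fraction=0.3, seed=11)
        img, truth = generate_synthetic_image(spec)
        q = quantify_segment(img, [ROI(0, 0, 80, 80)])
        assert q.n_retained >= 1000
        tol = 3 * spec.noise_sd / np.sqrt(q.n_retained)
        assert abs(q.pooled_mean - spec.base_green) < tol


class TestAutoSampleROIs:
    def test_uniform_image_places_all(self, uniform_image):
        img, _ = uniform_image
        rois = auto_sample_rois(img, n=10, size=10, seed=5)
        assert len(rois) == 10
        for a, b in itertools.combinations(rois, 2):
            assert not a.overlaps(b)

    def test_avoids_saturated_vessel_stripe(self):
        img, truth = generate_synthetic_image(
            SyntheticImageSpec(height=60, width=60, base_green=120,
                               noise_sd=0, n_vessels=1, seed=2)
        )
        rois = auto_sample_rois(img, n=8, size=8, seed=3)
        stripe = set(truth.vessel_columns)
        for roi in rois:
            roi_cols = set(range(roi.col0, roi.col0 + roi.width))
            assert not (roi_cols & stripe)
            assert (img.g[roi.slices] < 250).all()

    def test_deterministic_given_seed(self, uniform_image):
        img, _ = uniform_image
        assert auto_sample_rois(img, seed=9) == auto_sample_rois(img, seed=9)

    def test_reports_partial_placement_on_failure(self):
        img = make_image(255, np.full((25, 25), 255), 255)  # nothing retained
        with pytest.raises(SamplingError, match="0 of 4"):
            auto_sample_rois(img, n=4, size=10, seed=1, max_attempts=200)


class TestExportPixels:
    def test_round_trip_and_coordinates(self, tmp_path):
        g = np.arange(16, dtype=np.uint8).reshape(4, 4) + 100
        img = make_image(0, g, 0)
        path = tmp_path / "pixels.csv"
        n = export_pixels(img, [ROI(1, 1, 2, 2)], path)
        assert n == 4
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        assert len(df) == 4
        for _, row in df.iterrows():
            assert row["green"] == img.g[row["row"], row["col"]]
        assert set(zip(df["row"], df["col"])) == {(1, 1), (1, 2), (2, 1), (2, 2)}

    def test_nothing_retained_raises(self, tmp_path):
        img = make_image(255, 255, 255)
        with pytest.raises(EmptyROIError):
            export_pixels(img, [ROI(0, 0, 1, 1)], tmp_path / "x.csv")


class TestROICsv:
    def test_round_trip(self, tmp_path):
        rois = [ROI(0, 0, 10, 10, roi_id="a"), ROI(20, 30, 5, 8, roi_id="b")]
        path = tmp_path / "rois.csv"
        write_roi_csv(rois, path)
        assert read_roi_csv(path) == rois

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="roi_id"):
            read_roi_csv(path)
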