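"""Image I/O, preprocessing, manifests, splitting and augmentation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from ocusiam.imaging import (
    AugmentSpec,
    CropSpec,
    DEFAULT_CROP,
    DatasetManifest,
    NormalizationSpec,
    RawImage,
    crop_fundus,
    load_image,
    normalize_channels,
    resize_to_input,
    stratified_split,
    traditional_augment,
)


class TestLoadImage:
    def test_uint8_range_maps_onto_unit_interval(self, tmp_path):
        arr = np.zeros((4, 4), dtype=np.uint8)
        arr[0, 0] = 255
        p = tmp_path / "img.png"
        Image.fromarray(arr, mode="L").save(p)
        img = load_image(p)
        assert img.pixels[0, 0, 0] == 1.0
        assert img.pixels[1, 1, 0] == 0.0

    def test_constant_midgray_roundtrip(self, tmp_path):
        p = tmp_path / "gray.png"
        Image.fromarray(np.full((10, 10), 128, dtype=np.uint8), mode="L").save(p)
        img = load_image(p)
        assert np.allclose(img.pixels, 128 / 255)
        assert img.pixels.shape == (10, 10, 1)

    def test_grayscale_expands_to_rgb_on_request(self, tmp_path):
        p = tmp_path / "g.png"
        Image.fromarray(np.full((5, 5), 64, dtype=np.uint8), mode="L").save(p)
        assert load_image(p, to_rgb=True).pixels.shape == (5, 5, 3)

    def test_corrupt_file_raises_io_error_naming_path(self, tmp_path):
        p = tmp_path / "broken.png"
        p.write_bytes(b"\x89PNG\r\n\x1a\nnot actually a png")
        with pytest.raises(OSError, match="broken.png"):
            load_image(p)


class TestCrop:
    def test_standard_fundus_window_is_300_by_250(self):
        img = RawImage(np.zeros((512, 512, 1)))
        out = crop_fundus(img, DEFAULT_CROP)
        assert (out.width, out.height) == (300, 250)

    def test_identity_crop_returns_input(self, rng):
        px = rng.random((8, 9, 1))
        out = crop_fundus(RawImage(px), CropSpec(0, 0, 9, 8))
        assert np.array_equal(out.pixels, px)

    def test_single_pixel_crop_indexes_correctly(self, rng):
        px = rng.random((2, 2, 1))
        out = crop_fundus(RawImage(px), CropSpec(1, 1, 2, 2))
        assert out.pixels.shape == (1, 1, 1)
        assert out.pixels[0, 0, 0] == px[1, 1, 0]

    def test_out_of_bounds_crop_reports_both_geometries(self):
        img = RawImage(np.zeros((100, 100, 1)))
        with pytest.raises(ValueError, match="100x100"):
            crop_fundus(img, CropSpec(50, 50, 150, 90))

    def test_nested_crops_compose(self, rng):
        px = rng.random((50, 60, 1))
        img = RawImage(px)
        two_step = crop_fundus(crop_fundus(img, CropSpec(5, 10, 45, 40)),
                               CropSpec(3, 2, 20, 25))
        one_step = crop_fundus(img, CropSpec(8, 12, 25, 35))
        assert np.array_equal(two_step.pixels, one_step.pixels)

    def test_degenerate_rectangle_rejected(self):
        with pytest.raises(ValueError):
            CropSpec(10, 0, 10, 5)


class TestResize:
    def test_constant_image_stays_constant(self):
        out = resize_to_input(RawImage(np.full((30, 17, 1), 0.37)), 224)
        assert out.pixels.shape == (224, 224, 1)
        assert np.allclose(out.pixels, 0.37)

    def test_identity_resize_is_exact(self, rng):
        px = rng.random((224, 224, 3))
        out = resize_to_input(RawImage(px), 224)
        assert np.array_equal(out.pixels, px)

    def test_bilinear_upsampling_preserves_monotonicity(self):
        px = np.array([[0.0, 1.0], [0.0, 1.0]])[:, :, None]
        out = resize_to_input(RawImage(px), 4)
        rows = out.pixels[:, :, 0]
        assert (np.diff(rows, axis=1) >= -1e-12).all()

    def test_invalid_side_rejected(self):
        with pytest.raises(ValueError):
            resize_to_input(RawImage(np.zeros((4, 4, 1))), 0)


class TestNormalize:
    def test_fixed_half_half_maps_unit_interval_onto_symmetric_range(self):
        px = np.array([[[0.0, 0.5, 1.0]]])  # one pixel, three channels
        out = normalize_channels(RawImage(px), NormalizationSpec())
        assert np.allclose(np.sort(out.pixels.reshape(-1)), [-1.0, 0.0, 1.0])

    def test_estimated_mode_standardizes(self, rng):
        px = rng.random((16, 16, 3))
        out = normalize_channels(RawImage(px), NormalizationSpec(mode="estimated"))
        flat = out.pixels.reshape(3, -1)
        assert np.allclose(flat.mean(axis=1), 0.0, atol=1e-6)
        assert np.allclose(flat.std(axis=1), 1.0, atol=1e-6)

    def test_inverse_transform_recovers_input(self, rng):
        px = rng.random((8, 8, 3))
        spec = NormalizationSpec(mean=(0.4, 0.5, 0.6), std=(0.2, 0.5, 0.9))
        out = normalize_channels(RawImage(px), spec)
        back = out.pixels * np.array(spec.std)[:, None, None] + np.array(spec.mean)[
            :, None, None
        ]
        assert np.allclose(np.moveaxis(back, 0, 2), px, atol=1e-6)

    def test_constant_channel_in_estimated_mode_rejected(self):
        with pytest.raises(ValueError, match="constant channel"):
            normalize_channels(RawImage(np.full((4, 4, 1), 0.5)),
                          NormalizationSpec(mode="estimated"))

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError):
            NormalizationSpec(std=(0.5, 0.0, 0.5))


def _manifest(n_a: int, n_b: int) -> DatasetManifest:
    rows = [{"path": f"a{i}.png", "label": "VO"} for i in range(n_a)]
    rows += [{"path": f"b{i}.png", "label": "PVD"} for i in range(n_b)]
    return DatasetManifest(pd.DataFrame(rows))


class TestSplit:
    def test_seven_three_split_of_balanced_440(self):
        train, test = stratified_split(_manifest(220, 220), 0.7, seed=3)
        assert train.class_counts() == {"VO": 154, "PVD": 154}
        assert test.class_counts() == {"VO": 66, "PVD": 66}
        merged = set(train.records["path"]) | set(test.records["path"])
        assert len(merged) == 440
        assert set(train.records["path"]).isdisjoint(test.records["path"])

    def test_same_seed_reproduces_split(self):
        m = _manifest(31, 29)
        a = stratified_split(m, 0.7, seed=9)
        b = stratified_split(m, 0.7, seed=9)
        assert a[0].records.equals(b[0].records)
        assert a[1].records.equals(b[1].records)

    def test_class_proportions_preserved_within_one_image(self):
        train, test = stratified_split(_manifest(33, 27), 0.7, seed=0)
        for mani, total in ((train, 0.7), (test, 0.3)):
            counts = mani.class_counts()
            assert abs(counts["VO"] - 33 * total) <= 1
            assert abs(counts["PVD"] - 27 * total) <= 1

    def test_full_train_fraction_requires_explicit_flag(self):
        m = _manifest(4, 4)
        with pytest.raises(ValueError, match="empty test"):
            stratified_split(m, 1.0, seed=0)
        train, test = stratified_split(m, 1.0, seed=0, allow_empty_test=True)
        assert len(train) == 8 and len(test) == 0

    def test_class_with_single_image_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(_manifest(1, 5), 0.7, seed=0)


class TestManifest:
    def test_csv_roundtrip(self, tmp_path):
        m = _manifest(3, 2)
        m.to_csv(tmp_path / "m.csv")
        back = DatasetManifest.from_csv(tmp_path / "m.csv")
        assert back.records.equals(m.records)

    def test_json_roundtrip(self, tmp_path):
        m = _manifest(2, 2)
        m.to_json(tmp_path / "m.json")
        back = DatasetManifest.from_json(tmp_path / "m.json")
        assert back.records.equals(m.records)

    def test_duplicate_paths_rejected(self):
        df = pd.DataFrame([{"path": "x.png", "label": "VO"}] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            DatasetManifest(df)


class TestAugment:
    def test_horizontal_flip_is_an_involution(self, rng):
        img = RawImage(rng.random((12, 10, 1)))
        spec = AugmentSpec(horizontal_flip=True)
        once = traditional_augment(img, spec, seed=5)
        twice = traditional_augment(once, spec, seed=5)
        assert np.array_equal(twice.pixels, img.pixels)

    def test_identity_configuration_returns_input(self, rng):
        img = RawImage(rng.random((8, 8, 1)))
        spec = AugmentSpec(rotation=True, max_degrees=0.0)
        out = traditional_augment(img, spec, seed=1)
        assert np.allclose(out.pixels, img.pixels)

    def test_same_seed_reproduces_bytes(self, rng):
        img = RawImage(rng.random((16, 16, 3)))
        spec = AugmentSpec(random_crop=True, rotation=True, color_jitter=True)
        a = traditional_augment(img, spec, seed=42)
        b = traditional_augment(img, spec, seed=42)
        assert np.array_equal(a.pixels, b.pixels)
        c = traditional_augment(img, spec, seed=43)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_spec_with_nothing_enabled_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            AugmentSpec()
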