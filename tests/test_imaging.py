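import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from actimage.imaging import (
    ActivityImage,
    DatasetIntegrityError,
    load_dataset,
    load_image,
    resize_to_square,
    save_dataset,
    save_image,
    window_to_activity_image,
    window_to_image,
    windows_to_images,
)
from actimage.preprocess import Window


def _window(values, label="walking"):
    return Window(values=np.asarray(values, dtype=float), label=label)


class TestWindowToImage:
    def test_zero_window_is_black(self):
        img = window_to_image(_window(np.zeros((6, 250))))
        assert img.dtype == np.uint8
        assert img.shape == (6, 250)
        assert img.max() == 0

    def test_unit_window_is_white(self):
        assert window_to_image(_window(np.ones((3, 50)))).min() == 255

    def test_half_rounds_up_to_128(self):
        img = window_to_image(_window(np.full((3, 4), 0.5)))
        assert img.max() == img.min() == 128

    def test_out_of_range_value_names_channel(self):
        vals = np.zeros((6, 10))
        vals[3, 2] = 1.2
        with pytest.raises(ValueError, match="channel index 3"):
            window_to_image(_window(vals))

    @given(
        a=hnp.arrays(float, (4, 20), elements=st.floats(0, 1)),
        b=hnp.arrays(float, (4, 20), elements=st.floats(0, 1)),
    )
    def test_monotone_in_every_sample(self, a, b):
        hi, lo = np.maximum(a, b), np.minimum(a, b)
        assert (window_to_image(_window(hi)) >= window_to_image(_window(lo))).all()

    def test_values_quarter_percent_apart_stay_distinct(self):
        # 1/255 separation in normalized units maps to distinct intensities
        vals = np.array([[0.0, 1 / 255, 2 / 255, 0.5, 0.5 + 1 / 255, 1.0]] * 3)
        img = window_to_image(_window(vals))
        assert len(set(img[0].tolist())) == 6


class TestResize:
    def test_constant_input_stays_constant(self):
        out = resize_to_square(np.full((6, 250), 200.0), side=224)
        assert out.shape == (224, 224)
        assert out.min() == out.max() == 200

    def test_channel_band_replication_factor(self):
        # 6 x 250 input: each channel row becomes a ~42-row band, so a
        # single bright channel lights roughly its sixth of the height
        raw = np.zeros((6, 250))
        raw[2, :] = 255.0
        out = resize_to_square(raw, side=224)
        band_rows = (out.max(axis=1) > 127).sum()
        assert abs(band_rows - 224 / 6) <= 2

    def test_identity_on_already_square_input(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (224, 224)).astype(float)
        np.testing.assert_array_equal(resize_to_square(img, 224), img.astype(np.uint8))

    def test_unknown_interpolation_rejected(self):
        with pytest.raises(ValueError, match="interpolation"):
            resize_to_square(np.zeros((6, 250)), interpolation="bicubic")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            resize_to_square(np.zeros((0, 10)))


class TestConversion:
    def test_cohort_conversion_preserves_class_counts(self):
        windows = [
            _window(np.random.default_rng(i).uniform(size=(6, 50)), label)
            for i, label in enumerate(["walking"] * 3 + ["standing"] * 2)
        ]
        images = windows_to_images(windows, side=64)
        assert len(images) == 5
        assert sum(im.label == "walking" for im in images) == 3
        assert all(im.pixels.shape == (64, 64) for im in images)
        assert all(im.provenance == "original" for im in images)


class TestPngRoundTrip:
    def test_save_load_is_lossless(self, tmp_path):
        rng = np.random.default_rng(2)
        img = ActivityImage(rng.integers(0, 256, (64, 64)).astype(np.uint8), "walking")
        save_image(img, tmp_path / "a.png")
        back = load_image(tmp_path / "a.png", label="walking")
        np.testing.assert_array_equal(back.pixels, img.pixels)

    def test_dataset_manifest_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        images = [
            ActivityImage(rng.integers(0, 256, (32, 32)).astype(np.uint8), lab)
            for lab in ("walking", "ascent", "descent")
        ]
        save_dataset(images, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert [im.label for im in back] == ["walking", "ascent", "descent"]
        for a, b in zip(images, back):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_png_without_manifest_entry_is_integrity_error(self, tmp_path):
        images = [ActivityImage(np.zeros((8, 8), dtype=np.uint8), "walking")]
        save_dataset(images, tmp_path / "ds")
        save_image(images[0], tmp_path / "ds" / "stray.png")
        with pytest.raises(DatasetIntegrityError, match="stray"):
            load_dataset(tmp_path / "ds")

    def test_manifest_entry_without_file_is_integrity_error(self, tmp_path):
        images = [ActivityImage(np.zeros((8, 8), dtype=np.uint8), "walking")]
        save_dataset(images, tmp_path / "ds")
        (tmp_path / "ds" / "img_000000.png").unlink()
        with pytest.raises(DatasetIntegrityError):
            load_dataset(tmp_path / "ds")


class TestActivityImageValidation:
    def test_intensities_outside_byte_range_rejected(self):
        with pytest.raises(ValueError):
            ActivityImage(np.full((4, 4), 300.0), "walking")

    def test_full_conversion_has_provenance_and_source(self):
        w = Window(np.full((6, 250), 0.25), "ascent", source_id="s01", start_index=125)
        img = window_to_activity_image(w)
        assert img.provenance == "original"
        assert img.source_id == "s01:125"
        assert img.is_square and img.side == 224
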