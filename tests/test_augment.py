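"""Normalization, stationary-wavelet decomposition, geometric augmentation,
and the stratified split rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungscreen import augment as aug
from lungscreen.containers import ImageSet
from lungscreen.errors import ConfigurationError, DegenerateImageError, ValidationError
from lungscreen.fixtures import FixtureSpec, make_image_dataset


def _rand_image(rng, h=32, w=32):
    return aug.NormalizedImage(rng.random((h, w, 3)), source_id="rand")


class TestNormalize:
    def test_uint8_range_divided_by_255(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[0, 0] = 255
        img[1, 1] = 51
        out = aug.normalize_minmax(img)
        assert out.pixels.max() == 1.0 and out.pixels.min() == 0.0
        assert np.isclose(out.pixels[1, 1, 0], 51 / 255)

    def test_binary_image_unchanged(self):
        img = np.zeros((4, 4, 3))
        img[2, 2] = 1.0
        out = aug.normalize_minmax(img)
        assert np.array_equal(out.pixels, img)

    def test_hand_arithmetic(self):
        img = np.array([[2.0, 4.0], [6.0, 10.0]])
        out = aug.normalize_minmax(img)
        expected = np.array([[0.0, 0.25], [0.5, 1.0]])
        assert np.allclose(out.pixels[:, :, 0], expected)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            aug.normalize_minmax(np.full((4, 4, 3), 7.0))


class TestSwt:
    def test_coefficient_layout_256(self):
        img = aug.NormalizedImage(np.random.default_rng(0).random((256, 256, 3)))
        st_ = aug.swt_decompose(img, levels=3)
        for arr in (st_.app, st_.ver, st_.hor, st_.dia):
            assert arr.shape == (256, 256, 3, 3)

    def test_constant_image_has_vanishing_details(self):
        # bypass normalization: decompose a constant plane directly
        img = aug.NormalizedImage(np.full((32, 32, 3), 0.5))
        st_ = aug.swt_decompose(img)
        for arr in (st_.ver, st_.hor, st_.dia):
            assert np.abs(arr).max() < 1e-8
        for li in range(3):
            plane = st_.app[:, :, 0, li]
            assert np.ptp(plane) < 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_perfect_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        img = _rand_image(rng)
        st_ = aug.swt_decompose(img)
        rec = aug.swt_reconstruct(st_)
        assert np.abs(rec - img.pixels).max() < 1e-6

    def test_shift_equivariance_under_periodic_boundaries(self):
        rng = np.random.default_rng(3)
        img = _rand_image(rng, 64, 64)
        st0 = aug.swt_decompose(img)
        for s1, s2 in [(1, 0), (5, 3), (16, 31)]:
            shifted = aug.NormalizedImage(np.roll(img.pixels, (s1, s2), axis=(0, 1)))
            st1 = aug.swt_decompose(shifted)
            for a0, a1 in [(st0.app, st1.app), (st0.ver, st1.ver),
                           (st0.hor, st1.hor), (st0.dia, st1.dia)]:
                assert np.abs(np.roll(a0, (s1, s2), axis=(0, 1)) - a1).max() < 1e-8

    def test_padding_recorded_for_awkward_sizes(self):
        img = aug.NormalizedImage(np.random.default_rng(1).random((30, 30, 3)))
        st_ = aug.swt_decompose(img, levels=3)
        assert st_.pad == ((0, 2), (0, 2))
        rec = aug.swt_reconstruct(st_)
        assert rec.shape == (30, 30, 3)
        assert np.abs(rec - img.pixels).max() < 1e-6

    def test_unknown_wavelet_rejected(self):
        img = aug.NormalizedImage(np.random.default_rng(0).random((16, 16, 3)))
        with pytest.raises(ConfigurationError):
            aug.swt_decompose(img, wavelet="nosuchwavelet")


class TestSwtAugment:
    def test_three_images_same_shape(self, rng):
        img = _rand_image(rng, 64, 64)
        out = aug.swt_augment_images(img)
        assert len(out) == 3
        for o in out:
            assert o.pixels.shape == (64, 64, 3)
            assert o.pixels.min() == 0.0 and o.pixels.max() == 1.0

    def test_constant_input_raises(self):
        img = aug.NormalizedImage(np.full((32, 32, 3), 0.3))
        with pytest.raises(DegenerateImageError):
            aug.swt_augment_images(img)

    def test_level1_of_step_edge_matches_lowpass_oracle(self):
        """The level-1 augmentation image of a step edge must equal the
        step directly low-pass filtered with the db2 scaling filter
        (periodic, separable), min-max rescaled — computed here without the
        wavelet machinery."""
        import pywt as _pywt
        img = np.zeros((64, 64, 3))
        img[:, 32:] = 1.0
        out = aug.swt_augment_images(aug.NormalizedImage(img))[0]
        w = np.asarray(_pywt.Wavelet("db2").dec_lo)[::-1]

        def circ_filter(a, axis):
            return sum(wt * np.roll(a, 1 - t, axis=axis)
                       for t, wt in enumerate(w))

        expected = circ_filter(circ_filter(img[:, :, 0], 0), 1)
        expected = (expected - expected.min()) / np.ptp(expected)
        assert np.abs(out.pixels[:, :, 0] - expected).max() < 1e-10
        # and it is a smoothed step away from the transition/wrap zones
        profile = out.pixels[32, :, 0]
        assert np.ptp(profile[10:28]) < 1e-9 and np.ptp(profile[36:54]) < 1e-9
        assert profile[20] < 0.2 and profile[44] > 0.8


class TestGeometric:
    def test_three_outputs_same_shape(self, rng):
        img = _rand_image(rng)
        out = aug.geometric_variants(img, aug.AugmentationParams(seed=0), rng)
        assert len(out) == 3
        for o in out:
            assert o.pixels.shape == img.pixels.shape

    def test_zero_ranges_are_identity(self, rng):
        img = _rand_image(rng)
        params = aug.AugmentationParams(translation_range=(0, 0),
                                        rotation_range=(0, 0),
                                        shear_range=(0, 0), seed=0)
        for o in aug.geometric_variants(img, params, rng):
            assert np.abs(o.pixels - img.pixels).max() < 1e-6

    def test_integer_translation_moves_pixel_exactly(self):
        img = np.zeros((32, 32, 3))
        img[10, 10] = 1.0
        out = aug.translate_image(aug.NormalizedImage(img), 5, 3)
        assert out.pixels[15, 13, 0] == 1.0
        assert out.pixels[10, 10, 0] == 0.0
        assert out.pixels.sum() == pytest.approx(3.0)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValidationError):
            aug.AugmentationParams(rotation_range=(10, -10))


class TestAugmentTrainingSet:
    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(n=st.integers(min_value=1, max_value=12))
    def test_ninefold_count(self, n):
        ds = make_image_dataset(FixtureSpec(n_per_class=max(1, n // 3 + 1),
                                            image_size=(16, 16, 3), seed=0))
        subset = ds.subset(range(n)) if n <= len(ds) else ds
        out = aug.augment_training_set(subset, aug.AugmentationParams(seed=1))
        assert len(out) == 9 * len(subset)

    def test_provenance_tags(self, small_images):
        subset = small_images.subset([0])
        out = aug.augment_training_set(subset, aug.AugmentationParams(seed=1))
        levels = {sid.split("|")[1] for sid in out.ids}
        transforms = {sid.split("|")[2] for sid in out.ids}
        assert levels == {"L1", "L2", "L3"}
        assert transforms == {"translate", "rotate", "shear"}
        assert all(sid.startswith(subset.ids[0]) for sid in out.ids)

    def test_empty_training_set_rejected(self):
        empty = ImageSet(images=[], labels=[], ids=[])
        with pytest.raises(ValidationError):
            aug.augment_training_set(empty, aug.AugmentationParams(seed=0))


class TestSplit:
    def test_table_counts(self):
        assert aug.split_sizes(4094) == (2456, 1024, 614)
        assert aug.split_sizes(100) == (60, 25, 15)
        assert aug.split_sizes(101) == (60, 26, 15)

    def test_floor_rule_exhaustive(self):
        for m in range(3, 501):
            tr, va, te = aug.split_sizes(m)
            assert tr == int(np.floor(0.60 * m))
            assert te == int(np.floor(0.15 * m))
            assert tr + va + te == m

    def test_disjoint_union(self, small_images):
        tr, va, te = aug.split_dataset(small_images, aug.SplitSpec(seed=4))
        ids = tr.ids + va.ids + te.ids
        assert len(set(ids)) == len(ids) == len(small_images)
        for label in small_images.classes:
            m = small_images.class_counts()[label]
            assert tr.class_counts()[label] == int(np.floor(0.6 * m))

    def test_seeded_shuffle_reproducible(self, small_images):
        a = aug.split_dataset(small_images, aug.SplitSpec(seed=4))
        b = aug.split_dataset(small_images, aug.SplitSpec(seed=4))
        assert a[0].ids == b[0].ids
        c = aug.split_dataset(small_images, aug.SplitSpec(seed=5))
        assert a[0].ids != c[0].ids

    def test_tiny_class_rejected(self):
        ds = ImageSet(images=[np.zeros((8, 8, 3))] * 2, labels=["a", "a"],
                      ids=["1", "2"])
        with pytest.raises(ValidationError):
            aug.split_dataset(ds, aug.SplitSpec(seed=0))

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValidationError):
            aug.SplitSpec(ratios=(0.5, 0.3, 0.3))
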