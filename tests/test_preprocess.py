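"""Background suppression and the six preprocessing arms."""

import numpy as np
import pytest
from skimage.restoration import denoise_tv_chambolle

from dbtmc.exceptions import ParameterError
from dbtmc.preprocess import (
    ARMS,
    PreprocessSpec,
    apply_preprocessing,
    binarize,
    clahe,
    fill_holes,
    largest_component,
    region_grow,
    resize_to,
    square_normalize,
    suppress_background,
    to_8bit_and_center,
    total_variation,
    tv_denoise,
    zero_center,
)


class TestBinarize:
    def test_bright_square_on_zeros(self):
        img = np.zeros((32, 32))
        img[8:16, 8:16] = 0.9
        mask, flag = binarize(img)
        assert not flag
        assert np.array_equal(mask, img > 0)

    def test_constant_image_degenerate(self):
        mask, flag = binarize(np.full((16, 16), 0.4))
        assert flag and not mask.any()

    def test_fixed_threshold_on_checkerboard(self):
        img = np.where(np.indices((8, 8)).sum(0) % 2 == 0, 0.7, 0.2)
        mask, _ = binarize(img, threshold_strategy=0.5)
        assert np.array_equal(mask, img == 0.7)


class TestMaskSteps:
    def test_fill_holes_ring(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:12, 4:12] = True
        mask[6:10, 6:10] = False
        filled = fill_holes(mask)
        assert filled[6:10, 6:10].all()

    def test_hole_touching_border_stays(self):
        mask = np.ones((10, 10), dtype=bool)
        mask[0:5, 4:6] = False  # notch open to the border
        assert np.array_equal(fill_holes(mask), mask)

    def test_fill_idempotent(self, fatty_mask):
        once = fill_holes(~fatty_mask)
        assert np.array_equal(fill_holes(once), once)

    def test_largest_component_selection(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:6, 1:11] = True  # area 50
        mask[12:14, 12:17] = True  # area 10
        out = largest_component(mask)
        assert out[1:6, 1:11].all() and not out[12:14, 12:17].any()

    def test_largest_component_single_blob_identity(self, fatty_mask):
        assert np.array_equal(largest_component(fatty_mask), fatty_mask)

    def test_equal_area_tie_scan_order(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0:3] = True  # first in scan order
        mask[5, 5:8] = True
        out = largest_component(mask)
        assert out[0, 0:3].all() and not out[5].any()

    def test_empty_mask(self):
        assert not largest_component(np.zeros((5, 5), dtype=bool)).any()


class TestRegionGrow:
    def test_monotone_growth_and_single_component(self, fatty_slice, fatty_mask):
        from scipy import ndimage

        raw, _ = binarize(fatty_slice)
        seed = largest_component(fill_holes(raw))
        grown = region_grow(seed, fatty_slice)
        assert (grown | seed).sum() == grown.sum()  # superset
        _, n = ndimage.label(grown, structure=np.ones((3, 3)))
        assert n == 1

    def test_infinite_admission_fraction_no_growth(self, fatty_slice, fatty_mask):
        out = region_grow(fatty_mask, fatty_slice, admit_fraction=np.inf)
        assert np.array_equal(out, fatty_mask)

    def test_growth_improves_jaccard_against_truth(self, fatty_slice, fatty_mask):
        raw, _ = binarize(fatty_slice)
        seed = largest_component(fill_holes(raw))
        grown = region_grow(seed, fatty_slice)

        def jaccard(a, b):
            return (a & b).sum() / (a | b).sum()

        assert jaccard(grown, fatty_mask) > jaccard(seed, fatty_mask)


class TestSuppressBackground:
    def test_outside_mask_exactly_zero(self, fatty_slice):
        suppressed, mask, flag = suppress_background(fatty_slice)
        assert not flag
        assert suppressed[~mask].sum() == 0.0

    def test_in_mask_pixels_unchanged(self, fatty_slice):
        suppressed, mask, _ = suppress_background(fatty_slice)
        assert np.array_equal(suppressed[mask], fatty_slice[mask])

    def test_idempotent_on_clean_input(self, fatty_slice):
        suppressed, mask, _ = suppress_background(fatty_slice)
        again, mask2, _ = suppress_background(suppressed)
        assert np.array_equal(again[mask & mask2], suppressed[mask & mask2])
        assert again[~mask2].sum() == 0.0

    def test_constant_image_propagates_flag(self):
        out, mask, flag = suppress_background(np.full((32, 32), 0.5))
        assert flag and out.sum() == 0


class TestTVDenoise:
    def test_constant_unchanged(self):
        img = np.full((16, 16), 0.3)
        assert np.allclose(tv_denoise(img, 14.0), img)

    def test_impulse_amplitude_reduced(self):
        img = np.full((17, 17), 0.2)
        img[8, 8] = 1.0
        out = tv_denoise(img, 14.0)
        assert out[8, 8] < 1.0
        assert out[8, 8] > 0.2  # not wiped out either

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tv_never_increases(self, seed):
        img = np.random.default_rng(seed).random((32, 32))
        assert total_variation(tv_denoise(img, 14.0)) <= total_variation(img) + 1e-9

    @pytest.mark.parametrize("seed", [0, 7])
    def test_agrees_with_reference_rof_solver(self, seed):
        """Independent check: converged solution matches skimage Chambolle."""
        img = np.random.default_rng(seed).random((32, 32))
        mine = tv_denoise(img, 14.0, tol=1e-7, max_iter=3000)
        ref = denoise_tv_chambolle(img, weight=1 / 14.0, eps=1e-9, max_num_iter=3000)
        assert np.abs(mine - ref).max() / np.abs(ref).max() < 1e-3

    def test_nonpositive_lambda_raises(self):
        with pytest.raises(ParameterError):
            tv_denoise(np.zeros((8, 8)), 0.0)


class TestClahe:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 0.5)
        assert np.array_equal(clahe(img), img)

    def test_output_in_unit_range(self, fatty_slice):
        out = clahe(fatty_slice)
        assert out.min() >= 0 and out.max() <= 1

    def test_low_contrast_ramp_gains_contrast(self):
        ramp = np.tile(np.linspace(0.45, 0.55, 64), (64, 1))
        rng = np.random.default_rng(0)
        ramp = np.clip(ramp + 0.005 * rng.standard_normal(ramp.shape), 0, 1)
        assert clahe(ramp).std() > ramp.std()

    def test_uniform_histogram_image_nearly_unchanged(self):
        """A full-range uniform ramp is its own equalization, up to tile blending."""
        img = np.tile(np.linspace(0, 1, 128), (128, 1))
        out = clahe(img)
        assert np.abs(out - img).mean() < 0.05

    def test_unsupported_distribution_raises(self):
        with pytest.raises(ParameterError):
            clahe(np.zeros((32, 32)), dist="rayleigh")

    def test_tiles_larger_than_image_raise(self):
        with pytest.raises(ParameterError):
            clahe(np.zeros((4, 4)), tiles=(8, 8))


class TestSquareNormalize:
    def test_endpoints_and_midpoint(self):
        img = np.array([[0.2, 0.6, 1.0]])
        out = square_normalize(img)
        assert out[0, 0] == 0.0
        assert out[0, 2] == 1.0
        assert np.isclose(out[0, 1], 0.25)  # midpoint of range -> 0.5^2

    def test_monotone(self):
        rng = np.random.default_rng(3)
        img = rng.random((16, 16))
        out = square_normalize(img)
        a, b = img.ravel(), out.ravel()
        order = np.argsort(a)
        assert (np.diff(b[order]) >= -1e-12).all()

    def test_constant_degenerates_to_zeros(self):
        assert not square_normalize(np.full((8, 8), 0.7)).any()


class TestApplyPreprocessing:
    @pytest.mark.parametrize("arm", ARMS)
    def test_every_arm_in_range_and_zero_background(self, arm, fatty_slice):
        spec = PreprocessSpec(method=arm, clahe_tiles=(4, 4))
        _, mask, _ = suppress_background(fatty_slice)
        out = apply_preprocessing(fatty_slice, spec, mask=mask)
        assert out.min() >= 0 and out.max() <= 1
        assert out[~mask].sum() == 0.0

    def test_original_arm_identity_on_clean_background(self, fatty_slice):
        suppressed, mask, _ = suppress_background(fatty_slice)
        out = apply_preprocessing(suppressed, PreprocessSpec(method="original"), mask=mask)
        assert np.array_equal(out, suppressed)

    def test_p3_differs_from_p4(self, fatty_slice):
        """TV->CLAHE and CLAHE->TV do not commute on textured slices."""
        p3 = apply_preprocessing(fatty_slice, PreprocessSpec(method="p3", clahe_tiles=(4, 4)))
        p4 = apply_preprocessing(fatty_slice, PreprocessSpec(method="p4", clahe_tiles=(4, 4)))
        assert not np.allclose(p3, p4)

    def test_unknown_arm_rejected(self):
        with pytest.raises(ParameterError):
            PreprocessSpec(method="p9")

    @pytest.mark.parametrize("arm", ["p5", "p6"])
    def test_contrast_arms_do_not_reduce_mc_salience(self, arm):
        """Squared normalization should highlight the calcifications."""
        from dbtmc.simulate import (DensityClass, MCClusterSpec,
                                    generate_anatomical_background,
                                    generate_breast_mask, insert_mc_cluster)

        d = DensityClass.standard("scattered")
        mask = generate_breast_mask(128, d, 2)
        bg = generate_anatomical_background(mask, d, 4)
        spec = MCClusterSpec(contrast=0.5)
        img, centers = insert_mc_cluster(bg, mask, spec, (64, 40), 8)

        def cbr(image):
            mc = max(image[r, c] for r, c in centers)
            in_mask = image[mask]
            return (mc - in_mask.mean()) / (in_mask.std() + 1e-12)

        out = apply_preprocessing(img, PreprocessSpec(method=arm), mask=mask)
        assert cbr(out) >= cbr(img) - 1e-9


class TestResizeAnd8Bit:
    def test_identity_at_target_size(self):
        img = np.random.default_rng(0).random((64, 64))
        assert np.array_equal(resize_to(img, 64), img)

    def test_constant_stays_constant(self):
        out = resize_to(np.full((40, 40), 0.3), 64)
        assert np.allclose(out, 0.3)

    def test_mask_resize_stays_binary(self, fatty_mask):
        out = resize_to(fatty_mask, 200, is_mask=True)
        assert out.dtype == bool

    def test_8bit_endpoints_and_roundtrip(self):
        img = np.random.default_rng(1).random((16, 16))
        img[0, 0], img[0, 1] = 0.0, 1.0
        (q,), (offset,) = to_8bit_and_center([img])
        assert q.dtype == np.uint8
        assert q[0, 0] == 0 and q[0, 1] == 255
        assert np.abs(q / 255.0 - img).max() <= 1 / 255 / 2 + 1e-12

    def test_zero_centered_mean(self):
        img = np.random.default_rng(2).random((16, 16))
        (q,), (offset,) = to_8bit_and_center([img])
        centered = zero_center(q, offset)
        assert abs(centered.mean()) < 1e-6
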