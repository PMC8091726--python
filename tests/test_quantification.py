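"""Raw-unit measurement, background estimation, detection calls and
calliper volume."""

import numpy as np
import pytest

from irfpquant.errors import DegenerateInputError, DomainError, ShapeError
from irfpquant.image_io import RawImage
from irfpquant.quantification import (
    calliper_volume,
    detect_signal,
    ellipse_region,
    estimate_background,
    measure_region,
)
from irfpquant.segmentation import (
    RegionMask,
    manual_plane,
    normalize,
    plane_segment,
)
from irfpquant.synthetic import SceneParams, gen_mouse_image


def full_mask(shape):
    return RegionMask.from_array(np.ones(shape, dtype=bool))


class TestMeasureRegion:
    def test_uniform_image_with_plane_at_value_nets_zero(self):
        img = RawImage(np.full((5, 5), 300, dtype=np.uint16))
        surf = normalize(img)
        plane = manual_plane(surf, 1.0)  # raw_level == 300
        m = measure_region(img, full_mask((5, 5)), plane)
        assert m.net_total == 0 and m.total_raw == 300 * 25

    def test_empty_mask_measures_zero(self):
        img = RawImage(np.full((4, 4), 10, dtype=np.uint16))
        plane = manual_plane(normalize(img), 0.5)
        m = measure_region(img, RegionMask.from_array(np.zeros((4, 4), bool)), plane)
        assert m.area_px == 0 and m.total_raw == 0 and m.net_total == 0

    def test_noiseless_blob_recovers_discrete_integral(self):
        params = SceneParams(
            body_ellipse=None, noise_sd=0.0,
            tumours=((48.0, 48.0, 5.0, 30000.0),),
        )
        img, truth = gen_mouse_image(params)
        surf = normalize(img)
        plane = manual_plane(surf, truth.body_level / surf.raw_max)
        mask = plane_segment(surf, plane)
        m = measure_region(img, mask, plane)
        # independent double-loop summation of (raw - plateau) over signal pixels
        oracle = 0.0
        for r in range(img.height):
            for c in range(img.width):
                v = float(img.pixels[r, c])
                if v > truth.body_level:
                    oracle += v - truth.body_level
        assert m.net_total == pytest.approx(oracle, rel=1e-12)
        # rounded discrete sum differs from the continuous blob integral
        # only by tail truncation at value < 1 count and rounding
        assert m.net_total == pytest.approx(truth.blob_integrals[0], rel=0.01)

    def test_offset_invariance_with_raised_plane(self):
        rng = np.random.default_rng(5)
        base = rng.integers(100, 2000, size=(16, 16)).astype(np.uint16)
        img = RawImage(base)
        shifted = RawImage(base + 500)
        surf, surf2 = normalize(img), normalize(shifted)
        raw_level = 800.0
        p1 = manual_plane(surf, raw_level / surf.raw_max)
        p2 = manual_plane(surf2, (raw_level + 500) / surf2.raw_max)
        mask = full_mask((16, 16))
        m1 = measure_region(img, mask, p1)
        m2 = measure_region(shifted, mask, p2)
        assert m2.net_total == pytest.approx(m1.net_total, abs=1e-6)

    def test_amplitude_monotonicity(self):
        nets = []
        for amp in (5000.0, 10000.0, 20000.0):
            params = SceneParams(body_ellipse=None, noise_sd=0.0,
                                 tumours=((48.0, 48.0, 5.0, amp),))
            img, truth = gen_mouse_image(params)
            surf = normalize(img)
            plane = manual_plane(surf, truth.body_level / surf.raw_max)
            nets.append(
                measure_region(img, plane_segment(surf, plane), plane).net_total
            )
        assert nets[0] < nets[1] < nets[2]

    def test_noisy_blob_mean_recovery_with_fixed_mask(self):
        # amplitude 20x the noise sd; the mask is the blob's true
        # support (independent of the noise), so the plane subtraction
        # leaves a mean-zero noise sum and the average over replicates
        # recovers the discrete blob integral well within 5%
        amp, sd = 5000.0, 250.0
        noiseless = SceneParams(body_ellipse=None, noise_sd=0.0,
                                tumours=((48.0, 48.0, 6.0, amp),))
        clean_img, truth = gen_mouse_image(noiseless)
        support = RegionMask.from_array(
            clean_img.pixels.astype(float) > truth.body_level
        )
        nets = []
        for seed in range(100):
            params = SceneParams(body_ellipse=None, noise_sd=sd, seed=seed,
                                 tumours=((48.0, 48.0, 6.0, amp),))
            img, _ = gen_mouse_image(params)
            surf = normalize(img)
            plane = manual_plane(surf, truth.body_level / surf.raw_max)
            nets.append(measure_region(img, support, plane).net_total)
        rel_err = abs(np.mean(nets) - truth.blob_integrals[0]) / truth.blob_integrals[0]
        assert rel_err < 0.05

    def test_saturated_pixels_counted_in_mask(self):
        arr = np.full((4, 4), 100, dtype=np.uint16)
        arr[0, 0] = 65535
        img = RawImage(arr)
        plane = manual_plane(normalize(img), 0.0)
        m = measure_region(img, full_mask((4, 4)), plane)
        assert m.saturated_in_mask == 1

    def test_shape_mismatch_rejected(self):
        img = RawImage(np.ones((4, 4), dtype=np.uint16))
        plane = manual_plane(normalize(img), 0.0)
        with pytest.raises(ShapeError):
            measure_region(img, full_mask((5, 5)), plane)


class TestEstimateBackground:
    def test_constant_region(self):
        img = RawImage(np.full((3, 3), 42, dtype=np.uint16))
        est = estimate_background(img, full_mask((3, 3)))
        assert est.mean == 42 and est.sd == 0

    def test_hand_computed_sample_sd(self):
        img = RawImage(np.array([[1, 2, 3]], dtype=np.uint16))
        est = estimate_background(img, full_mask((1, 3)))
        assert est.mean == pytest.approx(2.0)
        assert est.sd == pytest.approx(1.0)  # sample (n-1) sd of {1,2,3}

    def test_noisy_plateau_mean_within_sampling_bound(self):
        rng = np.random.default_rng(11)
        true_level, sd = 1000.0, 40.0
        pixels = np.rint(rng.normal(true_level, sd, size=(40, 40))).astype(np.uint16)
        img = RawImage(pixels)
        est = estimate_background(img, full_mask((40, 40)))
        n = 1600
        assert abs(est.mean - true_level) < 3 * sd / np.sqrt(n) + 0.5

    def test_empty_region_rejected(self):
        img = RawImage(np.ones((2, 2), dtype=np.uint16))
        with pytest.raises(DegenerateInputError):
            estimate_background(img, RegionMask.from_array(np.zeros((2, 2), bool)))


class TestDetectSignal:
    @staticmethod
    def _halves(pixels):
        h = pixels.shape[0] // 2
        bg = np.zeros(pixels.shape, bool)
        bg[:h] = True
        cand = ~bg
        return RegionMask.from_array(bg), RegionMask.from_array(cand)

    def test_null_false_positive_rate_is_small(self):
        # candidate drawn from the same distribution as background:
        # candidate mean has sem = sd/sqrt(n), so a 3 sd criterion on the
        # mean is passed essentially never
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pixels = np.rint(rng.normal(1000, 30, size=(20, 20))).astype(np.uint16)
            img = RawImage(pixels)
            bg_region, cand = self._halves(pixels)
            bg = estimate_background(img, bg_region)
            hits += detect_signal(img, cand, bg, k=3.0)
        assert hits <= 2

    def test_far_above_background_detected(self):
        arr = np.full((4, 4), 100, dtype=np.uint16)
        arr[2:] = 100 + 10 * 5  # mean + 10 sd for sd = 5
        img = RawImage(arr)
        bg_region, cand = self._halves(arr)
        bg = estimate_background(img, bg_region)
        # constant background: sd 0, candidate far above
        assert detect_signal(img, cand, bg, k=3.0)

    def test_k_zero_reduces_to_mean_comparison(self):
        arr = np.full((4, 4), 100, dtype=np.uint16)
        arr[2:, :] = 101
        img = RawImage(arr)
        bg_region, cand = self._halves(arr)
        bg = estimate_background(img, bg_region)
        assert detect_signal(img, cand, bg, k=0.0)

    def test_single_pixel_background_rejected(self):
        arr = np.array([[1, 2]], dtype=np.uint16)
        img = RawImage(arr)
        single = RegionMask.from_array(np.array([[True, False]]))
        cand = RegionMask.from_array(np.array([[False, True]]))
        bg = estimate_background(img, single)
        with pytest.raises(DegenerateInputError):
            detect_signal(img, cand, bg)


class TestCalliperVolume:
    def test_formula_evaluation(self):
        assert calliper_volume(10, 6) == pytest.approx(180.0)

    def test_zero_width_gives_zero(self):
        assert calliper_volume(12.5, 0) == 0

    def test_randomized_inputs_match_reevaluation(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            w = float(rng.uniform(0, 10))
            length = w + float(rng.uniform(0, 10))
            assert calliper_volume(length, w) == pytest.approx(length * w * w / 2)

    def test_negative_rejected_and_swap_warned(self):
        with pytest.raises(DomainError):
            calliper_volume(-1, 2)
        with pytest.warns(UserWarning):
            calliper_volume(3, 5)


def test_ellipse_region_is_centered_and_nonempty():
    region = ellipse_region((20, 20), 10, 10, 4, 6)
    assert region.mask[10, 10] and not region.mask[0, 0]
    assert region.n_pixels > 0
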