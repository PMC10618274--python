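"""Detector stages against hand arithmetic and brute-force oracles."""

import numpy as np
import pytest
from scipy.special import gammainc

from tomodensity import DetectionParams, GrayImage2D, detect_density, segment_breast
from tomodensity.detection import (
    chi2_threshold,
    highpass_wavelet,
    label_boxes,
    local_variances,
    multiply_noise,
    reference_variance,
)


class TestSegmentBreast:
    def test_recovers_phantom_mask(self, adipose_image):
        found = segment_breast(adipose_image.pixels)
        truth = adipose_image.mask
        jaccard = (found & truth).sum() / (found | truth).sum()
        assert jaccard >= 0.95

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="no breast"):
            segment_breast(np.zeros((64, 64)))

    def test_mirror_symmetry(self, adipose_image):
        direct = segment_breast(adipose_image.pixels)
        mirrored = segment_breast(adipose_image.pixels[:, ::-1])
        assert np.array_equal(mirrored, direct[:, ::-1])


class TestMultiplyNoise:
    def test_zero_image_stays_zero(self):
        out = multiply_noise(np.zeros((32, 32)), seed=1)
        assert np.all(out == 0)

    def test_mean_and_variance_on_constant_image(self):
        # v * Z with Z ~ N(0,1): mean 0, variance v^2
        v = 7.0
        out = multiply_noise(np.full((512, 400), v), seed=2)
        n = out.size
        assert abs(out.mean()) < 3 * v / np.sqrt(n)
        assert abs(out.var() - v * v) < 0.05 * v * v

    def test_seeded_determinism(self):
        img = np.ones((16, 16))
        assert np.array_equal(multiply_noise(img, seed=3), multiply_noise(img, seed=3))


class TestHighpassWavelet:
    def test_constant_image_maps_to_zero(self):
        out = highpass_wavelet(np.full((64, 64), 123.0))
        assert np.allclose(out, 0.0, atol=1e-8)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 64, 64))
        lhs = highpass_wavelet(2.0 * x + 3.0 * y)
        rhs = 2.0 * highpass_wavelet(x) + 3.0 * highpass_wavelet(y)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_white_noise_variance_matches_filter_gain(self):
        # interior impulse response: squared-tap sum predicts the output
        # variance for unit-variance white noise input
        impulse = np.zeros((64, 64))
        impulse[32, 32] = 1.0
        gain = (highpass_wavelet(impulse) ** 2).sum()
        rng = np.random.default_rng(5)
        noise = rng.standard_normal((512, 512))
        observed = highpass_wavelet(noise)[10:-10, 10:-10].var()
        assert abs(observed - gain) < 0.2 * gain

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="filter support"):
            highpass_wavelet(np.ones((2, 2)))


class TestLocalVariances:
    def test_constant_box_has_zero_variance(self):
        v, complete = local_variances(np.full((8, 8), 3.0), np.ones((8, 8), bool))
        assert complete.all()
        assert np.all(v == 0.0)

    def test_hand_value_for_binary_box(self):
        # 4x4 box of eight 0s and eight 1s: s^2 = 16*0.25/15 = 0.26667
        box = np.zeros((4, 4))
        box.ravel()[::2] = 1.0
        v, _ = local_variances(box, np.ones((4, 4), bool))
        assert v[0, 0] == pytest.approx(16 * 0.25 / 15)

    def test_box_count_bound_and_incomplete_exclusion(self, default_mask):
        rng = np.random.default_rng(6)
        detail = rng.normal(size=default_mask.shape)
        v, complete = local_variances(detail, default_mask)
        assert complete.sum() <= (128 // 4) * (100 // 4)
        # a box straddling the mask edge is not complete
        assert not complete.all()

    def test_no_complete_box_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[0, :] = True
        with pytest.raises(ValueError, match="no complete box"):
            local_variances(np.ones((8, 8)), mask)


def _chi2_upper_quantile_bisect(alpha: float, dof: int) -> float:
    """Independent quantile: bisection on the regularized incomplete gamma."""
    lo, hi = 0.0, 1000.0
    target = 1.0 - alpha
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if gammainc(dof / 2.0, mid / 2.0) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestChi2Threshold:
    def test_median_approximation_large_dof(self):
        dof = 1000
        assert chi2_threshold(0.5, dof) == pytest.approx(dof - 2.0 / 3.0, rel=0.01)

    def test_matches_bisection_oracle(self):
        assert chi2_threshold(0.1, 15) == pytest.approx(
            _chi2_upper_quantile_bisect(0.1, 15), abs=1e-6
        )

    def test_monotone_decreasing_in_alpha(self):
        cuts = [chi2_threshold(a, 15) for a in (0.01, 0.05, 0.1, 0.5)]
        assert all(a > b for a, b in zip(cuts, cuts[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            chi2_threshold(0.0, 15)
        with pytest.raises(ValueError):
            chi2_threshold(0.1, 0)


class TestReferenceVariance:
    def test_single_valued_grid_returns_bias_corrected_value(self):
        from scipy.stats import chi2 as chi2_dist

        v = np.full((5, 5), 2.0)
        ref = reference_variance(v, np.ones((5, 5), bool), dof=15)
        assert ref == pytest.approx(2.0 / (chi2_dist.ppf(0.5, 15) / 15))

    def test_consistent_for_gaussian_texture(self):
        # boxes of iid N(0, sigma^2): reference within 10% of sigma^2
        rng = np.random.default_rng(7)
        sigma2 = 3.0
        samples = rng.normal(0, np.sqrt(sigma2), size=(2000, 16))
        v = samples.var(axis=1, ddof=1).reshape(40, 50)
        ref = reference_variance(v, np.ones((40, 50), bool), dof=15)
        assert abs(ref - sigma2) < 0.1 * sigma2

    def test_removing_upper_tail_cannot_raise_reference(self):
        rng = np.random.default_rng(8)
        v = rng.chisquare(15, size=(20, 20)) / 15
        eligible = np.ones((20, 20), bool)
        ref_all = reference_variance(v, eligible, dof=15)
        dense = v > np.quantile(v, 0.9)
        ref_trim = reference_variance(v, eligible & ~dense, dof=15)
        assert ref_trim <= ref_all

    def test_insufficient_boxes_rejected(self):
        with pytest.raises(ValueError, match="insufficient adipose"):
            reference_variance(np.ones((3, 3)), np.ones((3, 3), bool), dof=15)


class TestLabelBoxes:
    def test_reference_level_variance_is_non_dense(self):
        ref = 2.0
        v = np.full((3, 3), ref)  # statistic = dof = 15 < cutoff 22.31
        labels = label_boxes(v, np.ones((3, 3), bool), ref, alpha=0.1, dof=15)
        assert not labels.any()

    def test_huge_variance_is_dense(self):
        v = np.array([[1e12]])
        assert label_boxes(v, np.ones((1, 1), bool), 1.0, 0.1, 15).all()

    def test_null_dense_fraction_approaches_alpha(self):
        # exact chi-square null: fraction above cutoff -> alpha
        rng = np.random.default_rng(9)
        sigma2 = 1.7
        v = sigma2 * rng.chisquare(15, size=(200, 200)) / 15
        frac = label_boxes(v, np.ones((200, 200), bool), sigma2, 0.1, 15).mean()
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / v.size)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            label_boxes(np.ones((2, 2)), np.ones((2, 2), bool), 0.0, 0.1, 15)


def _brute_force_two_stage(detail, box_n, alpha1, alpha2):
    """Naive-loop reimplementation of the box scan and two-stage labeling."""
    from scipy.stats import chi2 as chi2_dist

    dof = box_n * box_n - 1
    rows, cols = detail.shape
    variances = {}
    for bi in range(rows // box_n):
        for bj in range(cols // box_n):
            vals = []
            for i in range(box_n):
                for j in range(box_n):
                    vals.append(detail[bi * box_n + i, bj * box_n + j])
            mean = sum(vals) / len(vals)
            variances[(bi, bj)] = sum((x - mean) ** 2 for x in vals) / (len(vals) - 1)

    def median(xs):
        xs = sorted(xs)
        mid = len(xs) // 2
        return xs[mid] if len(xs) % 2 else 0.5 * (xs[mid - 1] + xs[mid])

    corr = chi2_dist.ppf(0.5, dof) / dof
    ref1 = median(list(variances.values())) / corr
    cut1 = chi2_dist.ppf(1 - alpha1, dof)
    stage1 = {k: dof * v / ref1 > cut1 for k, v in variances.items()}
    ref2 = median([v for k, v in variances.items() if not stage1[k]]) / corr
    cut2 = chi2_dist.ppf(1 - alpha2, dof)
    stage2 = {k: dof * v / ref2 > cut2 for k, v in variances.items()}
    labels = np.zeros_like(detail, dtype=bool)
    for (bi, bj), dense in stage2.items():
        if dense:
            labels[bi * box_n : (bi + 1) * box_n, bj * box_n : (bj + 1) * box_n] = True
    return labels


class TestDetectDensity:
    def test_matches_naive_loop_oracle_on_toy_image(self):
        rng = np.random.default_rng(10)
        pixels = rng.normal(100, 10, size=(32, 32))
        pixels[8:20, 8:20] += rng.normal(0, 30, size=(12, 12))
        image = GrayImage2D(pixels=pixels, mask=np.ones((32, 32), bool))
        params = DetectionParams(noise_multiplication=False)
        with pytest.warns(UserWarning, match="complete boxes"):
            result = detect_density(image, params)
        detail = highpass_wavelet(pixels, params.wavelet_name, params.wavelet_level)
        expected = _brute_force_two_stage(detail, 4, 0.1, 0.1)
        assert np.array_equal(result.labels, expected)

    def test_deterministic_given_seed(self, adipose_image):
        params = DetectionParams(seed=21)
        a = detect_density(adipose_image, params)
        b = detect_density(adipose_image, params)
        assert np.array_equal(a.labels, b.labels)
        assert a.meta["sigma2_ref_stage1"] == b.meta["sigma2_ref_stage1"]

    def test_pure_adipose_pd_monotone_in_alpha(self, adipose_image):
        pds = []
        for alpha in (0.01, 0.05, 0.1):
            params = DetectionParams(alpha_stage1=alpha, alpha_stage2=alpha, seed=22)
            pds.append(detect_density(adipose_image, params).pd_percent)
        assert pds[0] < pds[1] < pds[2]
        assert pds[0] < 15.0

    def test_dense_region_recall(self):
        # one ellipse with 4x detail-band variance over ~20% of the mask
        from tomodensity import PhantomSpec, make_slice

        spec = PhantomSpec(
            image_shape=(256, 200), n_slices=4, cbt_mm=4.0,
            dense_fraction_profile=(20.0, 0.0, 0.0), seed=30,
        )
        image, dense = make_slice(spec, 1, seed=30)
        result = detect_density(image, DetectionParams(seed=30))
        box = dense[:256, :200].reshape(64, 4, 50, 4).transpose(0, 2, 1, 3)
        fully_dense = box.reshape(64, 50, 16).all(axis=2)
        box_labels = result.labels[:256, :200].reshape(64, 4, 50, 4).transpose(0, 2, 1, 3)
        labeled = box_labels.reshape(64, 50, 16).all(axis=2)
        recall = labeled[fully_dense].mean()
        assert recall >= 0.8

    def test_detected_pd_exceeds_truth_by_null_rate(self):
        # at significance 0.1 the detector labels ~10-16% of adipose dense,
        # so measured PD sits above truth by roughly that fraction of the
        # non-dense area -- a documented positive bias
        from tomodensity import PhantomSpec, make_slice

        spec = PhantomSpec(
            image_shape=(256, 200), n_slices=4, cbt_mm=4.0,
            dense_fraction_profile=(20.0, 0.0, 0.0), seed=31,
        )
        image, dense = make_slice(spec, 1, seed=31)
        result = detect_density(image, DetectionParams(seed=31))
        truth_pd = 100.0 * dense[image.mask].sum() / image.mask.sum()
        assert result.pd_percent > truth_pd
        assert result.pd_percent - truth_pd < 20.0

    def test_labels_subset_of_mask_and_pd_bounds(self, adipose_image):
        result = detect_density(adipose_image, DetectionParams(seed=23))
        assert not np.any(result.labels & ~result.mask)
        assert 0.0 <= result.pd_percent <= 100.0
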