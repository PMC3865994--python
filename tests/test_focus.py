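import numpy as np
import pytest

import pombex as px
from pombex.exceptions import PlaneFitError
from pombex.focus import (FocusModel, complement_negative_region,
                          detect_focus_gradient, fit_focus_plane,
                          global_contrast_adjust)


def _plane_samples(a, b, c, n=100, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 512, n)
    y = rng.uniform(0, 512, n)
    z = a + b * x + c * y + rng.normal(0, noise, n)
    return np.column_stack([x, y, z])


class TestPlaneFit:
    def test_exact_recovery_from_noiseless_samples(self):
        samples = _plane_samples(2.0, 0.1, -0.05, n=20)
        model = fit_focus_plane(samples)
        np.testing.assert_allclose(model.coeffs, (2.0, 0.1, -0.05),
                                   atol=1e-10)
        assert model.r_squared == pytest.approx(1.0)

    def test_noisy_recovery_within_three_standard_errors(self):
        truth = np.array([2.0, 0.1, -0.05])
        sigma = 0.5
        samples = _plane_samples(*truth, n=100, noise=sigma, seed=42)
        model = fit_focus_plane(samples)
        # closed-form least-squares standard errors from the design matrix
        X = np.column_stack([np.ones(100), samples[:, 0], samples[:, 1]])
        se = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        np.testing.assert_array_less(np.abs(np.array(model.coeffs) - truth),
                                     3.0 * se)

    def test_collinear_centroids_rejected(self):
        samples = [(10.0, 20.0, 1.0), (20.0, 40.0, 2.0), (30.0, 60.0, 3.0)]
        with pytest.raises(PlaneFitError, match="collinear|rank"):
            fit_focus_plane(samples)

    def test_too_few_samples_rejected(self):
        with pytest.raises(PlaneFitError):
            fit_focus_plane([(0.0, 0.0, 1.0), (1.0, 1.0, 2.0)])


class TestComplement:
    def test_substitution(self):
        model = FocusModel(coeffs=(-1.0, 0.0, 0.0), mu_b=100.0)
        img = np.full((4, 4), 80.0)
        np.testing.assert_allclose(complement_negative_region(img, model),
                                   120.0)

    def test_background_mean_is_fixed_point(self):
        model = FocusModel(coeffs=(-1.0, 0.0, 0.0), mu_b=100.0)
        img = np.full((4, 4), 100.0)
        np.testing.assert_allclose(complement_negative_region(img, model),
                                   100.0)

    def test_involution(self):
        # bit-identical on exactly representable intensities ...
        rng = np.random.default_rng(1)
        img = np.round(rng.normal(100, 20, (64, 64)) * 4) / 4
        model = FocusModel(coeffs=(-30.0, 1.0, -0.4), mu_b=100.0)
        twice = complement_negative_region(
            complement_negative_region(img, model), model)
        np.testing.assert_array_equal(twice, img)
        # ... and to 1 ulp on arbitrary floats (double rounding)
        img = rng.normal(100, 20, (64, 64))
        twice = complement_negative_region(
            complement_negative_region(img, model), model)
        np.testing.assert_allclose(twice, img, rtol=1e-15, atol=1e-12)

    def test_positive_region_untouched(self):
        img = np.arange(16.0).reshape(4, 4)
        model = FocusModel(coeffs=(-2.5, 1.0, 0.0), mu_b=5.0)
        out = complement_negative_region(img, model)
        np.testing.assert_array_equal(out[:, 3:], img[:, 3:])
        assert not np.array_equal(out[:, :2], img[:, :2])


class TestGlobalContrastAdjust:
    def test_identity_when_contrast_already_matches(self):
        img = np.array([[0.0, 5.0, 10.0]])
        np.testing.assert_allclose(
            global_contrast_adjust(img, mu_n=10, mu_b=0, delta=10), img)

    def test_substitution(self):
        out = global_contrast_adjust(np.array([[5.0]]), mu_n=10.0, mu_b=0.0,
                                     delta=20.0)
        assert out[0, 0] == pytest.approx(10.0)

    def test_inverted_contrast_flips_sign(self):
        # mu_N below mu_B: the negative scale factor complements as it
        # rescales
        out = global_contrast_adjust(np.array([[80.0]]), mu_n=80.0,
                                     mu_b=100.0, delta=40.0)
        assert out[0, 0] == pytest.approx(140.0)

    def test_idempotent_composition(self):
        rng = np.random.default_rng(0)
        img = rng.normal(10, 5, (32, 32))
        once = global_contrast_adjust(img, mu_n=14.0, mu_b=10.0, delta=25.0)
        # after the first pass the nucleus-background difference is delta,
        # so applying again with the updated mu_N is the identity
        twice = global_contrast_adjust(once, mu_n=35.0, mu_b=10.0, delta=25.0)
        np.testing.assert_allclose(twice, once)

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError, match="mu_N == mu_B"):
            global_contrast_adjust(np.ones((2, 2)), 5.0, 5.0, 10.0)


class TestDetectFocusGradient:
    def test_all_positive_plane_is_not_a_gradient(self):
        samples = _plane_samples(50.0, 0.01, 0.0, n=30)
        detected, model = detect_focus_gradient(samples, (512, 512))
        assert not detected

    def test_flat_plane_is_not_a_gradient(self):
        samples = [(x, y, 5.0) for x, y in [(0, 0), (100, 30), (30, 200),
                                            (400, 400)]]
        detected, model = detect_focus_gradient(samples, (512, 512))
        assert not detected

    def test_sign_changing_plane_detected(self):
        samples = _plane_samples(-256.0, 1.0, 0.0, n=50, noise=5.0, seed=3)
        detected, model = detect_focus_gradient(samples, (512, 512))
        assert detected
        assert model.r_squared >= 0.3

    def test_noise_dominated_samples_rejected(self):
        rng = np.random.default_rng(0)
        samples = np.column_stack([rng.uniform(0, 512, 60),
                                   rng.uniform(0, 512, 60),
                                   rng.normal(0, 10, 60)])
        detected, _ = detect_focus_gradient(samples, (512, 512))
        assert not detected

    def test_fewer_than_three_samples_false(self):
        assert detect_focus_gradient([(0, 0, -1), (5, 5, 1)],
                                     (64, 64)) == (False, None)


def test_full_correction_restores_polarity_on_both_halves():
    """After adaptive correction of a scene with an inverted half, cell
    interiors are brighter than background and membranes darker on BOTH
    sides of the z=0 line."""
    spec = px.scene_preset("gradient", seed=4)
    scene = px.generate_scene(spec)
    records, mask, report = px.run(scene.images)
    assert report.focus_gradient_detected

    # reconstruct the corrected image the pipeline worked on
    from pombex import focus as F
    from pombex import preprocess as P
    trans = P.shading_correct(scene.images.trans, 40)
    bg = P.detect_background(trans)
    fl = [P.shading_correct(f, 40) for f in scene.images.fluor]
    nm, cent = P.detect_nuclei(fl)
    masks = P.build_region_masks(trans, bg, nm, cent)
    mu_n, mu_b = P.region_means(trans, masks)
    samples = [(x, y, m - mu_b) for (x, y), m in
               zip(masks.nucleus_centroids, masks.nucleus_trans_means)]
    detected, model = F.detect_focus_gradient(samples, trans.shape,
                                              mu_b=mu_b, mu_n=mu_n)
    assert detected
    corrected = F.complement_negative_region(trans, model)

    a, b, c = spec.focus_plane
    yy, xx = np.mgrid[0:trans.shape[0], 0:trans.shape[1]]
    halves = [(a + b * xx + c * yy) < 0, (a + b * xx + c * yy) >= 0]
    interior = scene.class_map.mask(px.INTERIOR)
    membrane = scene.class_map.mask(px.MEMBRANE)
    mu_b_corr = corrected[masks.background].mean()
    for half in halves:
        assert corrected[interior & half].mean() > mu_b_corr
        assert corrected[membrane & half].mean() < mu_b_corr
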