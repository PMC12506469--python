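import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.transform import rotate

from epsquant import (
    EigenField,
    HessianField,
    RidgeParams,
    compute_hessian,
    hessian_eigenvalues,
    multiscale_response,
    sato_response,
)
from epsquant.ridge import scale_grid

from _oracles import dense_hessian


class TestHessian:
    def test_constant_image_zero_everywhere(self):
        h = compute_hessian(np.full((32, 32), 0.7), sigma=2.0)
        for entry in (h.Ixx, h.Ixy, h.Iyy):
            np.testing.assert_allclose(entry, 0.0, atol=1e-12)

    @pytest.mark.parametrize("sigma", [1.0, 3.0, 10.0])
    def test_quadratic_ramp_second_derivative(self, sigma):
        """I = x^2 has Ixx = 2 in the interior at any smoothing scale."""
        n = 128
        x = np.arange(n, dtype=float)
        img = np.tile((x / 1.0) ** 2, (n, 1))
        h = compute_hessian(img, sigma=sigma)
        margin = int(4 * sigma) + 2
        interior = np.s_[margin:-margin, margin:-margin]
        np.testing.assert_allclose(h.Ixx[interior], 2.0, atol=1e-8)
        np.testing.assert_allclose(h.Ixy[interior], 0.0, atol=1e-8)
        np.testing.assert_allclose(h.Iyy[interior], 0.0, atol=1e-8)

    @pytest.mark.parametrize("sigma", [1.0, 2.5])
    def test_separable_equals_dense_convolution(self, rng, sigma):
        for _ in range(20):
            img = rng.random((64, 64))
            h = compute_hessian(img, sigma=sigma)
            ixx, ixy, iyy = dense_hessian(img, sigma)
            np.testing.assert_allclose(h.Ixx, ixx, atol=1e-8)
            np.testing.assert_allclose(h.Ixy, ixy, atol=1e-8)
            np.testing.assert_allclose(h.Iyy, iyy, atol=1e-8)

    def test_normalization_scales_by_sigma_squared(self, rng):
        img = rng.random((32, 32))
        plain = compute_hessian(img, 2.0, normalized=False)
        norm = compute_hessian(img, 2.0, normalized=True)
        np.testing.assert_allclose(norm.Ixx, 4.0 * plain.Ixx, rtol=1e-12)

    @pytest.mark.parametrize("sigma", [0.0, -1.0])
    def test_invalid_sigma(self, sigma):
        with pytest.raises(ValueError):
            compute_hessian(np.zeros((8, 8)), sigma)


class TestEigenvalues:
    def test_diagonal_matrix(self):
        h = HessianField(Ixx=np.array([[-1.0]]), Ixy=np.array([[0.0]]),
                         Iyy=np.array([[-4.0]]), sigma=1.0)
        e = hessian_eigenvalues(h)
        assert e.lambda1[0, 0] == pytest.approx(-1.0)
        assert e.lambda2[0, 0] == pytest.approx(-4.0)

    def test_tie_takes_more_positive_first(self):
        h = HessianField(Ixx=np.array([[0.0]]), Ixy=np.array([[3.0]]),
                         Iyy=np.array([[0.0]]), sigma=1.0)
        e = hessian_eigenvalues(h)
        assert e.lambda1[0, 0] == pytest.approx(3.0)
        assert e.lambda2[0, 0] == pytest.approx(-3.0)

    def test_closed_form_matches_generic_solver(self, rng):
        a, b, c = rng.normal(size=(3, 1000))
        h = HessianField(Ixx=a[None], Ixy=b[None], Iyy=c[None], sigma=1.0)
        e = hessian_eigenvalues(h)
        for i in range(1000):
            ref = np.linalg.eigvalsh([[a[i], b[i]], [b[i], c[i]]])
            got = sorted([e.lambda1[0, i], e.lambda2[0, i]])
            np.testing.assert_allclose(got, ref, atol=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.floats(-50, 50), b=st.floats(-50, 50), c=st.floats(-50, 50))
    def test_trace_determinant_and_ordering_property(self, a, b, c):
        h = HessianField(Ixx=np.array([[a]]), Ixy=np.array([[b]]),
                         Iyy=np.array([[c]]), sigma=1.0)
        e = hessian_eigenvalues(h)
        l1, l2 = e.lambda1[0, 0], e.lambda2[0, 0]
        assert l1 + l2 == pytest.approx(a + c, rel=1e-9, abs=1e-9)
        assert l1 * l2 == pytest.approx(a * c - b * b, rel=1e-9, abs=1e-9)
        assert abs(l1) <= abs(l2) + 1e-12

    def test_trace_and_determinant_conserved(self, rng):
        img = rng.random((48, 48))
        h = compute_hessian(img, 1.5)
        e = hessian_eigenvalues(h)
        np.testing.assert_allclose(e.lambda1 + e.lambda2, h.Ixx + h.Iyy, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(e.lambda1 * e.lambda2, h.Ixx * h.Iyy - h.Ixy**2,
                                   rtol=1e-9, atol=1e-12)
        assert np.all(np.abs(e.lambda1) <= np.abs(e.lambda2) + 1e-15)


class TestSatoResponse:
    def _eig(self, lam1, lam2):
        return EigenField(lambda1=np.array([[lam1]]), lambda2=np.array([[lam2]]), sigma=1.0)

    def test_ridge_pixel_reports_magnitude(self):
        r = sato_response(self._eig(0.0, -5.0), RidgeParams(alpha=0.25, tau=0.0))
        assert r.R[0, 0] == pytest.approx(5.0)

    def test_alpha_violation_is_zero(self):
        r = sato_response(self._eig(3.0, -5.0), RidgeParams(alpha=0.25))
        assert r.R[0, 0] == 0.0

    def test_positive_lambda2_is_zero_for_bright_ridges(self):
        r = sato_response(self._eig(0.0, 5.0), RidgeParams())
        assert r.R[0, 0] == 0.0

    def test_dark_polarity_flips_sign_test(self):
        r = sato_response(self._eig(0.0, 5.0), RidgeParams(polarity="dark"))
        assert r.R[0, 0] == pytest.approx(5.0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            RidgeParams(alpha=1.5)
        with pytest.raises(ValueError):
            RidgeParams(tau=-0.1)
        with pytest.raises(ValueError):
            RidgeParams(polarity="sideways")


def _gaussian_ridge(n=128, s=3.0, angle=0.0):
    """Bright ridge with Gaussian cross profile of scale s pixels."""
    yy, xx = np.mgrid[:n, :n]
    d = (xx - n / 2) * np.cos(np.radians(angle)) - (yy - n / 2) * np.sin(np.radians(angle))
    return np.exp(-0.5 * (d / s) ** 2)


class TestMultiscale:
    def test_single_scale_degenerate_case(self):
        img = _gaussian_ridge()
        multi = multiscale_response(img, 1.0, 1.0, 1)
        single = sato_response(hessian_eigenvalues(compute_hessian(img, 1.0, normalized=True)))
        np.testing.assert_allclose(multi.R, single.R, atol=1e-12)

    def test_max_dominates_every_single_scale(self):
        img = _gaussian_ridge()
        multi = multiscale_response(img, 1.0, 8.0, 5)
        for s in scale_grid(1.0, 8.0, 5):
            single = sato_response(
                hessian_eigenvalues(compute_hessian(img, float(s), normalized=True))
            )
            assert np.all(multi.R >= single.R - 1e-12)

    def test_argmax_sigma_matches_closed_form_grid_oracle(self):
        """At a Gaussian ridge centerline the winning scale is the grid
        argmax of sigma^2 * (s^2 + sigma^2)^(-3/2) (the normalized second
        derivative of the blurred profile)."""
        s = 3.0
        img = _gaussian_ridge(s=s)
        sigmas = scale_grid(1.0, 12.0, 8)
        oracle = sigmas[np.argmax(sigmas**2 * (s**2 + sigmas**2) ** -1.5)]
        multi = multiscale_response(img, 1.0, 12.0, 8)
        center = multi.argmax_sigma[64, 64]
        grid_step = sigmas[1] / sigmas[0]
        assert oracle / grid_step <= center <= oracle * grid_step

    def test_additive_intensity_invariance(self, rng):
        img = rng.random((64, 64))
        base = multiscale_response(img, 1.0, 4.0, 3)
        shifted = multiscale_response(img + 0.37, 1.0, 4.0, 3)
        np.testing.assert_allclose(base.R, shifted.R, atol=1e-10)

    def test_intensity_scaling_scales_response(self, rng):
        img = rng.random((64, 64))
        base = multiscale_response(img, 1.0, 4.0, 3)
        scaled = multiscale_response(3.0 * img, 1.0, 4.0, 3)
        np.testing.assert_allclose(scaled.R, 3.0 * base.R, rtol=1e-9, atol=1e-12)

    def test_rotation_robustness(self):
        """Response of a rotated ridge equals the rotated response within
        5% on well-interior, well-inside-support pixels."""
        img = _gaussian_ridge(n=160, s=3.0)
        resp = multiscale_response(img, 1.0, 8.0, 5).R
        img_rot = rotate(img, 30.0, order=3)
        resp_of_rot = multiscale_response(img_rot, 1.0, 8.0, 5).R
        rot_of_resp = rotate(resp, 30.0, order=3)
        yy, xx = np.mgrid[:160, :160]
        interior = (yy - 80) ** 2 + (xx - 80) ** 2 < 40**2
        strong = (resp_of_rot > 0.3 * resp.max()) & (rot_of_resp > 0.3 * resp.max())
        sel = interior & strong
        assert sel.sum() > 100
        rel = np.abs(resp_of_rot[sel] - rot_of_resp[sel]) / rot_of_resp[sel]
        assert rel.max() < 0.05

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            scale_grid(2.0, 1.0, 3)
        with pytest.raises(ValueError):
            scale_grid(1.0, 2.0, 0)
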