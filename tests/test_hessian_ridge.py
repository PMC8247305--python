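"""Hessian field, eigenvalue maps, ridge response and polyline extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrinklefind.hessian_ridge import (
    HessianField,
    RidgePolyline,
    binarize_response,
    eigenvalues,
    extract_lines,
    hessian_at_scale,
    ridge_response,
)


def _valley_image(width: float = 1.0, size: int = 81) -> np.ndarray:
    """Separable valley g(x, y) = -exp(-x^2 / (2 w^2)), constant along y."""
    x = np.arange(size) - size // 2
    return np.tile(-np.exp(-(x**2) / (2 * width**2)), (size, 1))


class TestHessianAtScale:
    def test_constant_image_gives_zero_field(self):
        fld = hessian_at_scale(np.full((32, 32), 0.7), sigma=2.0)
        assert np.allclose(fld.hxx, 0) and np.allclose(fld.hyy, 0)
        assert np.allclose(fld.hxy, 0)

    def test_analytic_valley_second_derivative(self):
        """For the unit-width valley, the smoothed second derivative at the
        centerline is (1 + sigma^2)^(-3/2); the gamma-normalized Hessian
        divided by sigma^2 must match it, and a finite-difference Hessian of
        the smoothed image must agree."""
        sigma = 1.0
        img = _valley_image()
        fld = hessian_at_scale(img, sigma)
        center = img.shape[1] // 2
        expected = (1 + sigma**2) ** -1.5
        got = fld.hxx[40, center] / sigma**2
        assert abs(got - expected) < 0.01
        assert abs(fld.hyy[40, center]) < 1e-6
        assert abs(fld.hxy[40, center]) < 1e-6
        # the underlying analytic value: f''(0) = +1 for f = -exp(-x^2/2),
        # confirmed by fine-step finite differences
        f = lambda v: -np.exp(-(v**2) / 2.0)
        h = 1e-4
        fd = (f(-h) - 2 * f(0.0) + f(h)) / h**2
        assert abs(fd - 1.0) < 1e-6

    def test_transpose_swaps_axes(self, rng):
        img = rng.random((40, 50))
        fld = hessian_at_scale(img, 1.5)
        fld_t = hessian_at_scale(img.T, 1.5)
        assert np.allclose(fld_t.hxx, fld.hyy.T)
        assert np.allclose(fld_t.hyy, fld.hxx.T)
        assert np.allclose(fld_t.hxy, fld.hxy.T)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            hessian_at_scale(np.zeros((4, 4)), 0.0)


class TestEigenvalues:
    def test_diagonal_field(self):
        fld = HessianField(
            hxx=np.full((3, 3), 2.0), hxy=np.zeros((3, 3)),
            hyy=np.full((3, 3), -1.0), scale_sigma=1.0,
        )
        lam1, lam2 = eigenvalues(fld)
        assert np.allclose(lam1, 2.0) and np.allclose(lam2, -1.0)

    def test_antidiagonal_field(self):
        c = 0.7
        fld = HessianField(
            hxx=np.zeros((3, 3)), hxy=np.full((3, 3), c),
            hyy=np.zeros((3, 3)), scale_sigma=1.0,
        )
        lam1, lam2 = eigenvalues(fld)
        assert np.allclose(lam1, c) and np.allclose(lam2, -c)

    def test_matches_dense_eigensolver(self, rng):
        h = rng.standard_normal((3, 50, 50))
        fld = HessianField(hxx=h[0], hxy=h[1], hyy=h[2], scale_sigma=1.0)
        lam1, lam2 = eigenvalues(fld)
        mats = np.stack(
            [np.stack([h[0], h[1]], -1), np.stack([h[1], h[2]], -1)], -2
        )
        dense = np.linalg.eigvalsh(mats)  # ascending
        assert np.abs(lam2 - dense[..., 0]).max() < 1e-10
        assert np.abs(lam1 - dense[..., 1]).max() < 1e-10

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_trace_and_determinant_conserved(self, seed):
        h = np.random.default_rng(seed).standard_normal((3, 20, 20))
        fld = HessianField(hxx=h[0], hxy=h[1], hyy=h[2], scale_sigma=1.0)
        lam1, lam2 = eigenvalues(fld)
        assert np.abs((lam1 + lam2) - (h[0] + h[2])).max() < 1e-9
        assert np.abs(lam1 * lam2 - (h[0] * h[2] - h[1] ** 2)).max() < 1e-9


class TestRidgeResponse:
    def test_constant_image_zero_response(self):
        fld = hessian_at_scale(np.full((16, 16), 0.3), 2.0)
        assert np.all(ridge_response(fld).value == 0)

    def test_intensity_inversion_swaps_polarities(self, rng):
        img = rng.random((32, 32))
        dark = ridge_response(hessian_at_scale(img, 2.0), "dark_ridge")
        bright = ridge_response(hessian_at_scale(1.0 - img, 2.0), "bright_ridge")
        assert np.allclose(dark.value, bright.value, atol=1e-12)

    def test_rotation_covariance(self, rng):
        img = rng.random((40, 40))
        resp = ridge_response(hessian_at_scale(img, 2.0)).value
        resp_rot = ridge_response(hessian_at_scale(np.rot90(img), 2.0)).value
        assert np.allclose(resp_rot, np.rot90(resp), atol=1e-10)

    def test_valley_argmax_on_centerline(self):
        img = _valley_image(width=2.0)
        resp = ridge_response(hessian_at_scale(img, 2.0)).value
        center = img.shape[1] // 2
        rows = resp[10:-10]
        assert np.all(np.abs(rows.argmax(axis=1) - center) <= 1)


class TestBinarize:
    def test_all_zero_response_stays_empty(self):
        resp = ridge_response(hessian_at_scale(np.zeros((16, 16)), 1.0))
        mask = np.ones((16, 16), bool)
        for method, param in (("otsu", None), ("quantile", 0.5), ("fixed", 0.0)):
            assert not binarize_response(resp, mask, method, param).any()

    def test_otsu_threshold_between_bimodal_populations(self):
        value = np.zeros((20, 20))
        value[:10] = 0.1
        value[10:] = 0.9
        from wrinklefind.hessian_ridge import RidgeResponse

        binary = binarize_response(
            RidgeResponse(value=value, polarity="dark_ridge"), np.ones_like(value, bool)
        )
        # exhaustive-search Otsu oracle: maximal between-class variance
        flat = value.ravel()
        candidates = np.unique(flat)
        best_t, best_v = None, -1
        for t in candidates[1:]:
            lo, hi = flat[flat < t], flat[flat >= t]
            v = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_t, best_v = t, v
        assert np.array_equal(binary, value >= best_t)

    def test_mask_contract(self):
        value = np.ones((10, 10))
        value[0, 0] = 0.0
        from wrinklefind.hessian_ridge import RidgeResponse

        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        binary = binarize_response(
            RidgeResponse(value=value, polarity="dark_ridge"), mask, "fixed", 0.5
        )
        assert not binary[5:].any()

    def test_empty_mask_rejected(self):
        from wrinklefind.hessian_ridge import RidgeResponse

        with pytest.raises(ValueError):
            binarize_response(
                RidgeResponse(value=np.ones((4, 4)), polarity="dark_ridge"),
                np.zeros((4, 4), bool),
            )


class TestExtractLines:
    def test_straight_line_single_polyline(self):
        binary = np.zeros((40, 140), bool)
        binary[20, 10:130] = True
        lines = extract_lines(binary)
        assert len(lines) == 1
        assert abs(lines[0].arc_length - 119) <= 2
        assert lines[0].total_turning < 0.05

    def test_empty_map_empty_list(self):
        assert extract_lines(np.zeros((10, 10), bool)) == []

    def test_plus_sign_splits_into_four_arms(self):
        binary = np.zeros((41, 41), bool)
        binary[20, 2:39] = True
        binary[2:39, 20] = True
        lines = extract_lines(binary)
        assert len(lines) == 4
        # arms terminate adjacent to the removed center branch point
        for ln in lines:
            d = np.linalg.norm(ln.points - [20, 20], axis=1)
            assert d.min() <= 2.0

    def test_mean_response_attached(self):
        binary = np.zeros((20, 60), bool)
        binary[10, 5:55] = True
        from wrinklefind.hessian_ridge import RidgeResponse

        resp = RidgeResponse(value=np.full((20, 60), 2.5), polarity="dark_ridge")
        lines = extract_lines(binary, response=resp)
        assert lines[0].mean_response == pytest.approx(2.5)


def test_polyline_arc_length_is_sum_of_segments():
    pts = np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 10.0]])
    poly = RidgePolyline(points=pts)
    assert poly.arc_length == pytest.approx(11.0)
    assert poly.total_turning >= 0
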