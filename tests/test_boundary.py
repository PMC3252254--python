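import numpy as np
import pytest

from caudatecut.boundary import (
    BoundaryPotentials,
    DerivativeField,
    EdgenessMap,
    boundary_potentials,
    edgeness_map,
    estimate_sigma_beta,
    gaussian_derivatives,
    intensity_boundary,
    orientation_angle,
    orientation_boundary,
    select_scales,
    window_entropy,
    BETA_FLOOR,
    SIGMA_FLOOR,
)

from conftest import make_slice

GRID = tuple(np.arange(1.0, 6.0 + 1e-9, 0.5))


class TestScaleSelection:
    def test_constant_image_falls_back_to_smallest_scale(self):
        sm = select_scales(make_slice(np.full((10, 10), 5.0)), GRID)
        assert np.all(sm.scales == GRID[0])

    def test_checkerboard_window_entropy_is_one_bit(self):
        board = (np.indices((8, 8)).sum(axis=0) % 2) * 255.0
        ent = window_entropy(make_slice(board), 2)
        # interior 2x2 windows hold two equiprobable graylevels -> H = 1 bit
        assert ent[3, 3] == pytest.approx(1.0, abs=1e-6)

    def test_entropy_bounded_by_log2_distinct(self, rng):
        img = make_slice(rng.integers(0, 4, (12, 12)))
        ent = window_entropy(img, 3)
        assert ent.max() <= np.log2(4) + 1e-9

    def test_selected_scales_are_grid_members(self, rng):
        img = make_slice(rng.uniform(0, 255, (16, 16)))
        sm = select_scales(img, GRID)
        assert np.all(np.isin(np.unique(sm.scales), GRID))


class TestGaussianDerivatives:
    def test_ramp_gradient_and_flat_hessian(self):
        a = 2.0
        ramp = a * np.arange(32)[None, :] * np.ones((32, 1))
        sm = select_scales(make_slice(np.zeros((32, 32))), (2.0,))
        f = gaussian_derivatives(make_slice(ramp), sm, ell=0.0)
        interior = (slice(12, 20), slice(12, 20))
        np.testing.assert_allclose(f.ix[interior], a, atol=1e-3)
        # discrete sampled-Gaussian kernels leave a small intensity-
        # proportional residual in the second derivative
        np.testing.assert_allclose(f.ixx[interior], 0.0, atol=5e-3)
        np.testing.assert_allclose(f.iy[interior], 0.0, atol=1e-6)

    def test_lindeberg_zero_means_no_renormalization(self, rng):
        img = make_slice(rng.uniform(0, 255, (16, 16)))
        sm = select_scales(img, (3.0,))
        f0 = gaussian_derivatives(img, sm, ell=0.0)
        f1 = gaussian_derivatives(img, sm, ell=1.0)
        np.testing.assert_allclose(f1.ix, 3.0 * f0.ix, rtol=1e-10)

    def test_gaussian_blob_tangential_orientation(self):
        # Bright isotropic blob: at a point on the +x axis from the center
        # the minimum-eigenvalue direction is tangential (+/- y).
        yy, xx = np.mgrid[-20:21, -20:21]
        blob = 200 * np.exp(-(yy**2 + xx**2) / (2 * 5.0**2))
        sm = select_scales(make_slice(np.zeros((41, 41))), (1.0,))
        f = gaussian_derivatives(make_slice(blob), sm, ell=0.0)
        oy, ox = f.orient_y[20, 32], f.orient_x[20, 32]
        assert abs(oy) == pytest.approx(1.0, abs=1e-2)
        assert abs(ox) == pytest.approx(0.0, abs=1e-2)

    def test_orientations_unit_norm_upper_half_plane(self, rng):
        img = make_slice(rng.uniform(0, 255, (12, 12)))
        sm = select_scales(img, (1.5,))
        f = gaussian_derivatives(img, sm)
        norm = np.hypot(f.orient_y, f.orient_x)
        np.testing.assert_allclose(norm, 1.0, rtol=1e-10)
        assert np.all((f.orient_y > 0) | ((f.orient_y == 0) & (f.orient_x > 0)))


class TestPairTerms:
    def test_intensity_boundary_plugins(self):
        assert intensity_boundary(100, 100, sigma=5.0) == pytest.approx(1.0)
        sigma = 7.0
        d = np.sqrt(2) * sigma  # (dI)^2 = 2 sigma^2
        assert intensity_boundary(0, d, sigma) == pytest.approx(np.exp(-1), rel=1e-12)
        assert intensity_boundary(50, 50, 5.0, dist=np.sqrt(2)) == pytest.approx(1 / np.sqrt(2))

    def test_orientation_boundary_plugins(self):
        assert orientation_boundary(0.0, beta=0.5) == pytest.approx(1.0)
        assert orientation_boundary(np.pi / 2, beta=np.pi / 4) == pytest.approx(
            np.exp(-2), rel=1e-12
        )

    def test_orientation_angle_sign_free_symmetric(self):
        v1, v2 = (0.0, 1.0), (1.0, 0.0)
        assert orientation_angle(v1, v2) == pytest.approx(np.pi / 2)
        assert orientation_angle(v2, v1) == pytest.approx(np.pi / 2)
        assert orientation_angle((0, 1), (0, -1)) == pytest.approx(0.0)  # orientation mod pi

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            intensity_boundary(0, 0, sigma=0.0)
        with pytest.raises(ValueError):
            orientation_boundary(0.1, beta=0.0)


class TestSigmaBeta:
    def _flat_field(self, shape):
        z = np.zeros(shape)
        return DerivativeField(
            ix=z, iy=z, ixx=z, ixy=z, iyy=z, orient_y=np.ones(shape), orient_x=z
        )

    def test_constant_image_floors(self):
        img = make_slice(np.full((6, 6), 3.0))
        sigma, beta = estimate_sigma_beta(img, self._flat_field((6, 6)))
        assert sigma == SIGMA_FLOOR
        assert beta == BETA_FLOOR

    def test_two_valued_rms(self):
        # Columns alternate 0/d: every horizontal pair differs by d, every
        # vertical pair by 0 -> sigma^2 = d^2 / 2 under the RMS estimator.
        d = 40.0
        img = make_slice(np.tile([0.0, d], (6, 3)))
        sigma, _ = estimate_sigma_beta(img, self._flat_field((6, 6)), sigma_estimator="rms")
        n_h, n_v = 6 * 5, 5 * 6  # equal pair counts
        assert sigma == pytest.approx(np.sqrt(d**2 / 2), rel=1e-12)

    def test_intensity_scaling_homogeneity(self, rng):
        base = rng.uniform(0, 50, (8, 8))
        s1, _ = estimate_sigma_beta(make_slice(base + 100), self._flat_field((8, 8)))
        s3, _ = estimate_sigma_beta(make_slice(3 * base + 100), self._flat_field((8, 8)))
        assert s3 == pytest.approx(3 * s1, rel=1e-9)

    def test_robust_ignores_rare_large_edges(self):
        img_arr = np.full((10, 10), 100.0)
        img_arr[:, 5:] = 200.0  # one strong edge column
        img = make_slice(img_arr)
        s_rms, _ = estimate_sigma_beta(img, self._flat_field((10, 10)), sigma_estimator="rms")
        s_rob, _ = estimate_sigma_beta(img, self._flat_field((10, 10)), sigma_estimator="robust")
        assert s_rob < s_rms


class TestEdgeness:
    GAMMAS = tuple(np.round(np.arange(0.02, 0.301, 0.01), 4))

    def test_constant_image_zero(self):
        em = edgeness_map(make_slice(np.full((16, 16), 9.0)), self.GAMMAS, (0.5, 1.0))
        np.testing.assert_allclose(em.values, 0.0)

    def test_step_edge_fires_at_all_thresholds(self):
        img_arr = np.zeros((20, 20))
        img_arr[:, 10:] = 255.0
        em = edgeness_map(make_slice(img_arr), self.GAMMAS, (0.5, 1.0), smooth_sd=0.0)
        # the step column carries edgeness 1 at interior rows before smoothing
        assert em.values[8:12, 9:11].max() == pytest.approx(1.0)

    def test_range_preserved_after_smoothing(self, rng):
        img = make_slice(rng.uniform(0, 255, (16, 16)))
        em = edgeness_map(img, self.GAMMAS, (0.5, 1.0, 1.5), smooth_sd=1.0)
        assert em.values.min() >= 0.0
        assert em.values.max() <= 1.0


class TestBoundaryPotentials:
    def _setup(self, rng, shape=(10, 10)):
        img = make_slice(rng.uniform(0, 255, shape))
        sm = select_scales(img, (1.0,))
        field = gaussian_derivatives(img, sm)
        return img, field

    def test_no_edges_identity(self, rng):
        img, field = self._setup(rng)
        zero_j = EdgenessMap(values=np.zeros(img.shape))
        b_damp = boundary_potentials(img, field, zero_j, 0.5, 10.0, 0.5, mode="damp-J")
        b_off = boundary_potentials(img, field, None, 0.5, 10.0, 0.5, mode="off")
        for off in b_damp.weights:
            np.testing.assert_allclose(b_damp.weights[off], b_off.weights[off])

    def test_full_edgeness_frees_the_cut(self, rng):
        img, field = self._setup(rng)
        ones_j = EdgenessMap(values=np.ones(img.shape))
        b = boundary_potentials(img, field, ones_j, 0.5, 10.0, 0.5, mode="damp-J")
        for w in b.weights.values():
            np.testing.assert_allclose(w, 0.0, atol=1e-12)

    def test_convex_combination_arithmetic(self):
        # alpha=0.5, N=1 (equal intensities), O=e^-2 (theta=pi/2, beta=pi/4),
        # J=0 -> B = 0.5*1 + 0.5*0.1353 = 0.5677
        img = make_slice(np.full((2, 2), 7.0))
        field = DerivativeField(
            ix=np.zeros((2, 2)),
            iy=np.zeros((2, 2)),
            ixx=np.zeros((2, 2)),
            ixy=np.zeros((2, 2)),
            iyy=np.zeros((2, 2)),
            orient_y=np.array([[1.0, 0.0], [1.0, 0.0]]),
            orient_x=np.array([[0.0, 1.0], [0.0, 1.0]]),
        )
        b = boundary_potentials(img, field, None, 0.5, 10.0, np.pi / 4, mode="off")
        assert b.weights[(0, 1)][0, 0] == pytest.approx(0.5677, abs=1e-4)

    def test_nonnegative_and_symmetric_roles(self, rng):
        img, field = self._setup(rng)
        em = EdgenessMap(values=rng.uniform(0, 1, img.shape))
        b = boundary_potentials(img, field, em, 0.3, 5.0, 0.4, neighborhood=8)
        assert set(b.weights) == {(0, 1), (1, 0), (1, 1), (1, -1)}
        for w in b.weights.values():
            assert np.all(w >= 0)

    def test_step_image_boundary_cheaper_than_flat(self):
        rng = np.random.default_rng(0)
        img_arr = np.full((20, 20), 60.0) + rng.normal(0, 2, (20, 20))
        img_arr[:, 10:] += 150.0
        img = make_slice(img_arr)
        sm = select_scales(img, (1.0,))
        field = gaussian_derivatives(img, sm)
        sigma, beta = estimate_sigma_beta(img, field, sigma_estimator="robust")
        em = edgeness_map(img, self_gammas(), (0.5, 1.0))
        b = boundary_potentials(img, field, em, 0.5, sigma, beta)
        w = b.weights[(0, 1)]
        across = w[5:15, 9:11].mean()
        flat = w[5:15, 2:5].mean()
        assert across < flat


def self_gammas():
    return tuple(np.round(np.arange(0.02, 0.301, 0.01), 4))
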