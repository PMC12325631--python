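"""Stress fields, summaries, ellipsoid mode, spectra, error propagation."""

import numpy as np
import pytest

from dropstress import (
    AxisFrame,
    FitError,
    HarmonicSurface,
    ParameterError,
    cell_stress,
    curvatures,
    decompose_stress,
    fit_ellipsoid,
    fit_harmonics,
    make_shape,
    mode_amplitudes,
    orientation_angles,
    stress_error,
    stress_summary,
    tissue_stress_pair,
    tissue_stress_scalar,
    total_stress,
    total_stress_along_axes,
)
from dropstress.ellipsoid import ellipsoid_mean_curvature
from dropstress.sh import basis_index, real_sh_basis


def _curv(shape, quad):
    return curvatures(
        HarmonicSurface(coeffs=shape.coeffs, center=shape.center,
                        L=shape.max_degree), quad
    )


def _param_cloud(shape, n=3000, seed=1):
    rng = np.random.default_rng(seed)
    pv = np.arccos(rng.uniform(-1, 1, n))
    pu = rng.uniform(0, 2 * np.pi, n)
    return shape.point(pv, pu)


class TestTotalStress:
    def test_sphere_stress_vanishes(self, quad41):
        field = total_stress(_curv(make_shape("sphere", radius=10.0), quad41), 3.3)
        assert np.abs(field.total).max() < 1e-10

    def test_magnitude_at_known_curvature_deviation(self):
        """γ = 3.3 mN/m and H − H0 = 0.01 μm⁻¹ give 0.066 kPa."""
        assert 2 * 3.3 * 0.01 == pytest.approx(0.066)

    def test_linearity_in_gamma(self, quad41):
        curv = _curv(make_shape("harmonic", radius=10.0, modes=[(3, 1, 0.5)]),
                     quad41)
        f1 = total_stress(curv, 1.5)
        f2 = total_stress(curv, 3.0)
        np.testing.assert_allclose(f2.total, 2 * f1.total, atol=1e-12)

    def test_area_weighted_mean_is_zero(self, quad41):
        curv = _curv(make_shape("harmonic", radius=10.0, modes=[(4, 2, 0.6)]),
                     quad41)
        field = total_stress(curv, 3.3)
        mean = (curv.area_weights * field.total).sum() / curv.area
        assert abs(mean) < 1e-8

    def test_nonpositive_gamma_rejected(self, quad41):
        curv = _curv(make_shape("sphere", radius=10.0), quad41)
        with pytest.raises(ParameterError):
            total_stress(curv, 0.0)


class TestSummary:
    def test_percentiles_match_brute_force(self):
        values = np.arange(1.0, 101.0)
        s = stress_summary(values, alpha=0.05)
        assert s.low == pytest.approx(np.percentile(values, 5))
        assert s.high == pytest.approx(np.percentile(values, 95))
        assert s.amplitude == pytest.approx(
            np.percentile(values, 95) - np.percentile(values, 5)
        )

    def test_alpha_zero_gives_min_max(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=400)
        s = stress_summary(values, alpha=0.0)
        assert s.low == values.min() and s.high == values.max()

    def test_constant_field_has_zero_amplitude(self):
        for alpha in (0.0, 0.05, 0.2):
            assert stress_summary(np.full(50, 3.3), alpha).amplitude == 0.0

    def test_weighted_quantile_equals_replication(self):
        """Area weighting ≡ replicating nodes proportionally to weight."""
        rng = np.random.default_rng(2)
        values = rng.normal(size=30)
        weights = rng.integers(1, 20, size=30).astype(float)
        rep = np.repeat(values, weights.astype(int))
        s = stress_summary(values, 0.1, weights)
        # midpoint vs linear replication conventions differ at O(1/n)
        assert s.low == pytest.approx(np.quantile(rep, 0.1), abs=0.15)
        assert s.high == pytest.approx(np.quantile(rep, 0.9), abs=0.15)

    def test_invalid_alpha_and_empty_field(self):
        with pytest.raises(ParameterError):
            stress_summary(np.ones(5), alpha=0.5)
        with pytest.raises(ParameterError):
            stress_summary(np.empty(0), alpha=0.05)


class TestEllipsoid:
    def test_exact_cloud_recovers_semiaxes_and_axes(self):
        shape = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0))
        e = fit_ellipsoid(_param_cloud(shape))
        np.testing.assert_allclose(e.semiaxes, [7.0, 5.0, 3.0], atol=1e-8)
        for fitted, true in zip(e.axes, shape.axes):
            assert abs(fitted @ true) == pytest.approx(1.0, abs=1e-8)

    def test_rotation_round_trip(self):
        shape = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0))
        pts = _param_cloud(shape)
        rng = np.random.default_rng(4)
        R, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        e = fit_ellipsoid(pts @ R.T)
        e1_expected = R @ shape.axes[0]
        assert np.arccos(min(abs(e.axes[0] @ e1_expected), 1.0)) < 1e-6

    def test_sphere_cloud_degenerate_but_orthonormal(self):
        shape = make_shape("sphere", radius=6.0)
        e = fit_ellipsoid(_param_cloud(shape))
        np.testing.assert_allclose(e.semiaxes, 6.0, rtol=1e-8)
        np.testing.assert_allclose(e.axes @ e.axes.T, np.eye(3), atol=1e-10)

    def test_planar_points_rejected(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.normal(size=(50, 2)), np.zeros(50)])
        with pytest.raises(FitError):
            fit_ellipsoid(pts)


class TestTissueStress:
    def test_closed_form_values(self):
        shape = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0))
        e = fit_ellipsoid(_param_cloud(shape))
        assert e.H_max == pytest.approx(0.52889, abs=1e-5)
        assert e.H_min == pytest.approx(0.09061, abs=1e-5)
        assert tissue_stress_scalar(e, 1.0) == pytest.approx(0.87655, abs=1e-5)
        assert tissue_stress_pair(e, 1.0, 1, 3) == pytest.approx(0.87655, abs=1e-5)

    def test_sphere_tissue_stress_zero(self):
        e = fit_ellipsoid(_param_cloud(make_shape("sphere", radius=6.0)))
        assert tissue_stress_scalar(e, 2.0) == pytest.approx(0.0, abs=1e-8)
        assert tissue_stress_pair(e, 2.0, 1, 2) == pytest.approx(0.0, abs=1e-8)

    def test_closed_form_extremes_match_dense_grid(self):
        """2000×1000 (u,v) grid of H_e vs the analytic extremes, 100 random
        ellipsoids with axis ratios in [1, 5]."""
        rng = np.random.default_rng(6)
        u = np.linspace(0, 2 * np.pi, 2000)
        v = np.linspace(0, np.pi, 1001)   # odd count puts π/2 on the grid
        uu, vv = np.meshgrid(u, v)
        for _ in range(100):
            c = rng.uniform(1.0, 3.0)
            b = c * rng.uniform(1.0, np.sqrt(5.0))
            a = b * rng.uniform(1.0, 5.0 / (b / c))
            He = ellipsoid_mean_curvature(a, b, c, uu, vv)
            H_max = a / (2 * c**2) + a / (2 * b**2)
            H_min = c / (2 * b**2) + c / (2 * a**2)
            assert He.max() == pytest.approx(H_max, rel=1e-6)
            assert He.min() == pytest.approx(H_min, rel=1e-6)

    def test_sigma_tt_equals_sigma_t_on_exact_ellipsoid(self, quad41):
        shape = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0))
        e = fit_ellipsoid(_param_cloud(shape))
        curv = _curv(shape, quad41)
        for i, j in ((1, 2), (1, 3), (2, 3)):
            assert total_stress_along_axes(curv, e, 1.0, i, j) == pytest.approx(
                tissue_stress_pair(e, 1.0, i, j), abs=1e-6
            )


class TestCellStress:
    def test_exact_ellipsoid_droplet_has_zero_cell_stress(self, quad41):
        shape = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0))
        e = fit_ellipsoid(_param_cloud(shape))
        sc = cell_stress(_curv(shape, quad41), e, 3.3)
        assert np.abs(sc).max() < 1e-8

    def test_decomposition_identity(self, quad41):
        """σ^A = σ^A_T + σ^A_C nodewise to ≤ 1e-8 kPa."""
        shape = make_shape("harmonic", radius=10.0,
                           modes=[(2, 1, 0.8), (3, 2, 0.4), (5, -1, 0.3)])
        pts = _param_cloud(shape)
        surf = fit_harmonics(pts, 8, center=np.zeros(3))
        curv = curvatures(surf, quad41)
        e = fit_ellipsoid(pts)
        field = decompose_stress(curv, e, 3.3)
        assert np.abs(field.total - field.tissue - field.cell).max() < 1e-8

    def test_perturbation_dominates_cell_spectrum(self, quad41):
        """Ellipsoid + degree-3 bump: σ^A_C power sits in degree 3."""
        shape = make_shape("harmonic", radius=10.0,
                           modes=[(2, 0, 0.5), (3, 2, 0.5)])
        pts = _param_cloud(shape)
        surf = fit_harmonics(pts, 8, center=np.zeros(3))
        curv = curvatures(surf, quad41)
        e = fit_ellipsoid(pts)
        sc = cell_stress(curv, e, 1.0, drop_small_offset=False)
        spec = mode_amplitudes(sc, quad41, Lmax=10)
        by_degree = {
            l: np.sqrt((spec.amplitudes[spec.degrees == l] ** 2).sum())
            for l in range(11)  # noqa: E741
        }
        assert max(by_degree, key=by_degree.get) == 3


class TestModeSpectrum:
    def test_single_mode_recovered(self, quad41):
        (B,) = real_sh_basis(3, quad41.polar, quad41.azimuth)
        f = 2.5 * B[:, basis_index(3, 2)]
        spec = mode_amplitudes(f, quad41, Lmax=5)
        nz = spec.amplitudes > 1e-10
        assert nz.sum() == 1
        assert spec.amplitudes[nz][0] == pytest.approx(2.5, rel=1e-10)

    def test_parseval_for_two_orthogonal_modes(self, quad41):
        (B,) = real_sh_basis(4, quad41.polar, quad41.azimuth)
        f = 3.0 * B[:, basis_index(3, 2)] + 4.0 * B[:, basis_index(4, -1)]
        spec = mode_amplitudes(f, quad41, Lmax=6)
        assert (spec.amplitudes ** 2).sum() == pytest.approx(25.0, rel=1e-8)
        assert spec.total_power == pytest.approx(25.0, rel=1e-8)
        assert spec.modes_for_fraction(0.999) == 2
        assert spec.cumulative_fraction[-1] == pytest.approx(1.0)

    def test_zero_residual_gives_zero_spectrum(self, quad41):
        spec = mode_amplitudes(np.zeros(len(quad41)), quad41, Lmax=5)
        assert np.all(spec.amplitudes == 0.0)

    def test_aliasing_guard(self, quad41):
        with pytest.raises(ParameterError):
            mode_amplitudes(np.zeros(len(quad41)), quad41, Lmax=30)


class TestOrientation:
    def test_aligned_and_oblique_axes(self):
        shape = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0),
                           axes=np.eye(3))
        e = fit_ellipsoid(_param_cloud(shape))
        angles = orientation_angles(e, AxisFrame.lab())
        assert angles["AP"] == pytest.approx(0.0, abs=1e-4)
        assert angles["ML"] == pytest.approx(90.0, abs=1e-4)
        assert angles["DV"] == pytest.approx(90.0, abs=1e-4)
        # ê1 at 45° in the AP–DV plane
        s = 1 / np.sqrt(2)
        axes45 = np.array([[s, 0, s], [0, 1, 0], [-s, 0, s]])
        shape45 = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0), axes=axes45)
        e45 = fit_ellipsoid(_param_cloud(shape45))
        a45 = orientation_angles(e45, AxisFrame.lab())
        assert a45["AP"] == pytest.approx(45.0, abs=1e-4)
        assert a45["DV"] == pytest.approx(45.0, abs=1e-4)
        assert a45["ML"] == pytest.approx(90.0, abs=1e-4)

    def test_axis_sign_is_irrelevant(self):
        shape = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0))
        e = fit_ellipsoid(_param_cloud(shape))
        flipped = type(e)(quadric=e.quadric, center=e.center,
                          axes=np.vstack([-e.axes[0], e.axes[1:]]),
                          semiaxes=e.semiaxes)
        assert orientation_angles(e, AxisFrame.lab()) == pytest.approx(
            orientation_angles(flipped, AxisFrame.lab())
        )

    def test_non_orthonormal_frame_rejected(self):
        with pytest.raises(ParameterError):
            AxisFrame(np.array([1.0, 0, 0]), np.array([1.0, 0, 0]),
                      np.array([0.0, 0, 1]))


class TestErrorPropagation:
    def test_printed_relative_bound(self):
        """δγ/γ = 5% with δH/(H−H0) = 10% → 11.18% ≈ the printed ~11%."""
        _, rel = stress_error(3.3, 0.05 * 3.3, np.array([0.11]), 0.10,
                              np.array([0.001]))
        assert rel[0] == pytest.approx(np.sqrt(0.05**2 + 0.10**2), rel=1e-12)
        assert rel[0] == pytest.approx(0.1118, abs=1e-4)

    def test_zero_uncertainties_give_zero_error(self):
        ab, _ = stress_error(3.3, 0.0, np.array([0.12, 0.08]), 0.10,
                             np.array([0.0, 0.0]))
        np.testing.assert_array_equal(ab, 0.0)

    def test_reduction_without_gamma_error(self):
        ab, _ = stress_error(2.0, 0.0, np.array([0.12]), 0.10, np.array([0.003]))
        assert ab[0] == pytest.approx(2 * 2.0 * 0.003)

    def test_relative_bound_undefined_at_h0(self):
        ab, rel = stress_error(2.0, 0.1, np.array([0.10]), 0.10, np.array([0.001]))
        assert np.isnan(rel[0]) and np.isfinite(ab[0])

    def test_negative_uncertainty_rejected(self):
        with pytest.raises(ParameterError):
            stress_error(2.0, -0.1, np.array([0.1]), 0.1, np.array([0.0]))
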