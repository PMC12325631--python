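"""Harmonic surface fitting, curvature, integrals, volume, Gauss-Bonnet."""

import numpy as np
import pytest

from dropstress import (
    GeometryError,
    HarmonicSurface,
    ParameterError,
    SphereQuadrature,
    curvatures,
    fit_harmonics,
    make_shape,
    surface_integral,
    volume_from_radius,
)
from dropstress.ellipsoid import ellipsoid_mean_curvature


def _surface_from_shape(shape, L=None):
    return HarmonicSurface(coeffs=shape.coeffs, center=shape.center,
                           L=shape.max_degree if L is None else L)


class TestCurvature:
    def test_sphere_curvatures_analytic(self, quad41):
        curv = curvatures(_surface_from_shape(make_shape("sphere", radius=10.0)),
                          quad41)
        assert np.abs(curv.H - 0.1).max() < 1e-8 * 0.1
        assert np.abs(curv.K - 0.01).max() < 1e-8 * 0.01
        assert curv.H0 == pytest.approx(0.1, rel=1e-10)

    def test_ellipsoid_curvature_extremes_match_closed_form(self, quad131):
        """(7,5,3): max H = 0.52889, min = 0.09061 μm⁻¹ (node resolution)."""
        shape = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0))
        curv = curvatures(_surface_from_shape(shape), quad131)
        assert curv.H.max() == pytest.approx(0.52889, abs=2e-3)
        assert curv.H.min() == pytest.approx(0.09061, abs=2e-3)

    def test_curvature_matches_dense_grid_oracle(self, quad41):
        """H at nodes equals the closed-form ellipsoid H at the same chart."""
        shape = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0))
        curv = curvatures(_surface_from_shape(shape), quad41)
        He = ellipsoid_mean_curvature(7.0, 5.0, 3.0, quad41.azimuth, quad41.polar)
        assert np.abs(curv.H - He).max() < 1e-10


class TestFit:
    def test_exact_ellipsoid_reproduced_in_parametric_chart(self):
        shape = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0))
        rng = np.random.default_rng(0)
        pv = np.arccos(rng.uniform(-1, 1, 400))
        pu = rng.uniform(0, 2 * np.pi, 400)
        pts = shape.point(pv, pu)
        fit = fit_harmonics(pts, 2, angles=(pv, pu))
        assert np.abs(fit.evaluate(pv, pu) - pts).max() < 1e-8

    def test_coefficient_budget_enforced(self):
        """100 points cannot support more than 50 coefficients/component."""
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(100, 3)) + 10.0
        with pytest.raises(ParameterError, match="maximum admissible degree"):
            fit_harmonics(pts, 7)   # 64 coefficients > 100/2
        fit_harmonics(pts, 6)       # 49 <= 50: allowed

    def test_fit_smooths_radial_noise(self, sphere_cloud_exact):
        pts, polar, azimuth = sphere_cloud_exact
        rng = np.random.default_rng(7)
        noisy = pts * (1.0 + rng.normal(0, 0.005, len(pts))[:, None])
        fit = fit_harmonics(noisy, 20)
        rec = fit.evaluate(polar, azimuth)
        rms_in = np.sqrt(np.mean((np.linalg.norm(noisy, axis=1) - 10.0) ** 2))
        rms_fit = np.sqrt(np.mean((np.linalg.norm(rec, axis=1) - 10.0) ** 2))
        assert rms_fit < rms_in

    def test_spectral_convergence_on_band_limited_shape(self, quad41):
        """Fit error decreases with L until machine precision."""
        shape = make_shape("harmonic", radius=10.0, modes=[(3, 2, 0.4)])
        rng = np.random.default_rng(3)
        pv = np.arccos(rng.uniform(-1, 1, 2000))
        pu = rng.uniform(0, 2 * np.pi, 2000)
        pts = shape.point(pv, pu)
        errs = []
        for L in (1, 2, 3, 4, 6):
            fit = fit_harmonics(pts, L, center=np.zeros(3))
            errs.append(np.sqrt(np.mean((fit.evaluate(pv, pu) - pts) ** 2)))
        # the least-squares residual is monotone in the nested basis,
        # down to the rounding floor
        assert all(a >= b * (1 - 1e-12) or b < 1e-12
                   for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-10


class TestIntegrals:
    def test_unit_sphere_area(self, quad41):
        curv = curvatures(_surface_from_shape(make_shape("sphere", radius=1.0)),
                          quad41)
        assert surface_integral(np.ones(len(quad41)), curv) == pytest.approx(
            4 * np.pi, abs=1e-10
        )

    def test_h0_from_integral_vs_node_mean_on_ellipsoid(self, quad41):
        """Plain node averaging of H is biased; the area integral is not."""
        shape = make_shape("ellipsoid", semiaxes=(7.0, 5.0, 3.0))
        curv = curvatures(_surface_from_shape(shape), quad41)
        assert abs(curv.H0 - curv.H_node_mean) > 1e-3

    def test_h0_from_volume_close_on_mild_shapes(self, quad41):
        shape = make_shape("harmonic", radius=12.0, modes=[(3, 1, 0.5)])
        curv = curvatures(_surface_from_shape(shape), quad41)
        assert curv.H0_from_volume == pytest.approx(curv.H0, rel=0.02)

    def test_shape_mismatch_rejected(self, quad41):
        curv = curvatures(_surface_from_shape(make_shape("sphere", radius=1.0)),
                          quad41)
        with pytest.raises(ParameterError):
            surface_integral(np.ones(5), curv)


class TestVolume:
    def test_eccentric_ellipsoid_radial_quadrature(self, quad41, quad131):
        """(3,5,7) ellipsoid: V = 140π, small rule ≤1e-7 rel, big ≤1e-9."""
        shape = make_shape("ellipsoid", semiaxes=(3.0, 5.0, 7.0))
        V41 = volume_from_radius(shape.radial_function(quad41.directions), quad41)
        V131 = volume_from_radius(shape.radial_function(quad131.directions), quad131)
        assert V41 == pytest.approx(140.0 * np.pi, rel=1e-7)
        assert V131 == pytest.approx(140.0 * np.pi, rel=1e-9)

    def test_sphere_volume(self, quad41):
        curv = curvatures(_surface_from_shape(make_shape("sphere", radius=10.0)),
                          quad41)
        assert curv.volume == pytest.approx(4000.0 * np.pi / 3.0, rel=1e-10)

    def test_divergence_and_radial_forms_agree(self, quad41):
        shape = make_shape("harmonic", radius=10.0, modes=[(4, -2, 0.5)])
        curv = curvatures(_surface_from_shape(shape), quad41)
        Vr = volume_from_radius(shape.radial_function(quad41.directions), quad41)
        assert curv.volume == pytest.approx(Vr, rel=1e-8)

    def test_nonpositive_radius_rejected(self, quad41):
        with pytest.raises(GeometryError):
            volume_from_radius(np.full(len(quad41), -1.0), quad41)


class TestGaussBonnet:
    def test_sphere_epsilon_machine_precision(self, quad41):
        curv = curvatures(_surface_from_shape(make_shape("sphere", radius=10.0)),
                          quad41)
        assert curv.epsilon < 1e-12

    def test_hole_punched_cloud_raises_epsilon(self, sphere_cloud_exact):
        """Deleting a cap of points degrades the Gauss-Bonnet error."""
        pts, polar, _ = sphere_cloud_exact
        rng = np.random.default_rng(5)
        noisy = pts + rng.normal(0, 0.05, pts.shape)
        q = SphereQuadrature.gauss_product(41)
        eps_intact = curvatures(fit_harmonics(noisy, 12), q).epsilon
        punched = noisy[polar > 0.7]           # delete a polar cap
        eps_punched = curvatures(fit_harmonics(punched, 12), q).epsilon
        assert eps_punched > eps_intact

    def test_rotation_invariance_of_scalars(self, quad41):
        """V, H0 and ε are invariant under rigid rotation (≤1e-8 rel)."""
        shape = make_shape("harmonic", radius=10.0, modes=[(3, 1, 0.5), (5, -2, 0.3)])
        rng = np.random.default_rng(11)
        pv = np.arccos(rng.uniform(-1, 1, 3000))
        pu = rng.uniform(0, 2 * np.pi, 3000)
        pts = shape.point(pv, pu)
        R, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        c0 = curvatures(fit_harmonics(pts, 8), quad41)
        c1 = curvatures(fit_harmonics(pts @ R.T, 8), quad41)
        assert c1.volume == pytest.approx(c0.volume, rel=1e-8)
        assert c1.H0 == pytest.approx(c0.H0, rel=1e-8)
        assert abs(c1.epsilon - c0.epsilon) < 1e-10
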