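"""Global spherical-harmonic surface representation and its geometry.

A closed genus-0 surface is represented by real spherical-harmonic series
for each Cartesian coordinate, ``r(v, u) = (x(v,u), y(v,u), z(v,u))`` with
polar angle ``v`` and azimuth ``u``.  Curvatures follow from the first and
second fundamental forms with analytically differentiated basis functions;
surface integrals use the exact sphere quadrature of
:class:`~dropstress.quadrature.SphereQuadrature` together with the true
area element of the fitted surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GeometryError, ParameterError
from .quadrature import SphereQuadrature
from .sh import n_basis, real_sh_basis


@dataclass(frozen=True)
class HarmonicSurface:
    """Spherical-harmonic coefficients of the Cartesian surface components.

    ``coeffs`` has shape (3, (L+1)**2) and describes positions relative to
    ``center`` (μm).  The chart is (polar, azimuth) assigned to input points
    by central projection from the cloud centroid.
    """

    coeffs: np.ndarray
    center: np.ndarray
    L: int
    fit_rms: float = 0.0

    def evaluate(self, polar: np.ndarray, azimuth: np.ndarray) -> np.ndarray:
        """Surface points at chart angles, shape (N, 3) μm."""
        (B,) = real_sh_basis(self.L, polar, azimuth)
        return B @ self.coeffs.T + self.center

    def frames(self, polar: np.ndarray, azimuth: np.ndarray):
        """Positions, derivatives and outward normals at chart angles.

        Returns (r, r_v, r_u, r_vv, r_vu, r_uu, normals) with r absolute.
        """
        # nudge off the chart poles where the azimuthal tangent degenerates
        polar = np.clip(polar, 1e-6, np.pi - 1e-6)
        Y, Yv, Yu, Yvv, Yvu, Yuu = real_sh_basis(
            self.L, polar, azimuth, diff_n=2
        )
        C = self.coeffs.T
        r = Y @ C
        rv, ru = Yv @ C, Yu @ C
        rvv, rvu, ruu = Yvv @ C, Yvu @ C, Yuu @ C
        n_raw = np.cross(rv, ru)
        norm = np.linalg.norm(n_raw, axis=1, keepdims=True)
        bad = np.nonzero(norm[:, 0] <= 1e-14 * np.abs(r).max())[0]
        if bad.size:
            raise GeometryError(
                f"degenerate metric (zero area element) at node(s) {bad[:5].tolist()}"
            )
        n_hat = n_raw / norm
        # orient outward (positive mean curvature for a sphere)
        sign = np.sign(np.mean(np.einsum("ij,ij->i", r, n_hat)))
        if sign < 0:
            n_hat = -n_hat
        return r + self.center, rv, ru, rvv, rvu, ruu, n_hat

    def normals(self, polar: np.ndarray, azimuth: np.ndarray) -> np.ndarray:
        return self.frames(polar, azimuth)[-1]


@dataclass(frozen=True)
class CurvatureField:
    """Geometry of a harmonic surface sampled at quadrature nodes.

    ``area_weights`` are per-node products of quadrature weight and area
    element, so ``sum(area_weights * f)`` is the surface integral of ``f``.
    """

    surface: HarmonicSurface
    quadrature: SphereQuadrature
    positions: np.ndarray     # (N, 3) μm
    normals: np.ndarray       # (N, 3) outward
    H: np.ndarray             # (N,) 1/μm
    K: np.ndarray             # (N,) 1/μm²
    area_weights: np.ndarray  # (N,) μm²
    H0: float                 # area-weighted mean curvature, 1/μm
    H_node_mean: float        # plain node average (biased; for comparison)
    epsilon: float            # Gauss-Bonnet error, dimensionless
    volume: float             # μm³
    area: float               # μm²

    @property
    def H0_from_volume(self) -> float:
        """Mean curvature of the sphere of equal volume, (4π/3V)^(1/3)."""
        return float((4.0 * np.pi / (3.0 * self.volume)) ** (1.0 / 3.0))


def max_admissible_degree(n_points: int) -> int:
    """Largest L whose per-component coefficient count stays <= N/2."""
    return int(np.floor(np.sqrt(n_points / 2.0))) - 1


def fit_harmonics(
    points: np.ndarray,
    L: int,
    center: Optional[np.ndarray] = None,
    angles: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> HarmonicSurface:
    """Least-squares harmonic fit to a surface point cloud.

    Chart angles are assigned to each point by central projection from the
    cloud centroid (or the given ``center``); a caller that knows a better
    parameterization (e.g. the parametric chart of an analytic shape) may
    pass ``angles=(polar, azimuth)`` instead.  The degree is capped so that
    there are at least two data points per fitted coefficient and component.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ParameterError("points must have shape (N, 3)")
    if not np.all(np.isfinite(points)):
        raise ParameterError("points contain non-finite coordinates")
    N = points.shape[0]
    if n_basis(L) > N / 2.0:
        raise ParameterError(
            f"degree {L} needs {n_basis(L)} coefficients per component but only "
            f"{N} points are available (budget N/2); maximum admissible degree "
            f"is {max_admissible_degree(N)}"
        )
    c = np.mean(points, axis=0) if center is None else np.asarray(center, float)
    rel = points - c
    if angles is None:
        rad = np.linalg.norm(rel, axis=1)
        if np.any(rad <= 0):
            raise GeometryError("a point coincides with the projection center")
        polar = np.arccos(np.clip(rel[:, 2] / rad, -1.0, 1.0))
        azimuth = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2.0 * np.pi)
    else:
        polar, azimuth = (np.asarray(a, dtype=float) for a in angles)
    (B,) = real_sh_basis(L, polar, azimuth)
    coef, *_ = np.linalg.lstsq(B, rel, rcond=None)
    rms = float(np.sqrt(np.mean(np.sum((B @ coef - rel) ** 2, axis=1))))
    return HarmonicSurface(coeffs=coef.T, center=c, L=L, fit_rms=rms)


def _fundamental(surface: HarmonicSurface, polar: np.ndarray, azimuth: np.ndarray):
    """H, K, metric determinant, positions and outward normals at angles."""
    r, rv, ru, rvv, rvu, ruu, n_hat = surface.frames(polar, azimuth)
    E = np.einsum("ij,ij->i", rv, rv)
    F = np.einsum("ij,ij->i", rv, ru)
    G = np.einsum("ij,ij->i", ru, ru)
    e2 = np.einsum("ij,ij->i", rvv, n_hat)
    f2 = np.einsum("ij,ij->i", rvu, n_hat)
    g2 = np.einsum("ij,ij->i", ruu, n_hat)
    det = E * G - F**2
    if np.any(det <= 0):
        bad = np.nonzero(det <= 0)[0]
        raise GeometryError(f"degenerate metric at node(s) {bad[:5].tolist()}")
    # sign convention: H > 0 for a convex surface with outward normals
    H = -(E * g2 - 2.0 * F * f2 + G * e2) / (2.0 * det)
    K = (e2 * g2 - f2**2) / det
    return H, K, np.sqrt(det), r, n_hat


def mean_curvature_at(
    surface: HarmonicSurface, polar: np.ndarray, azimuth: np.ndarray
) -> np.ndarray:
    """Mean curvature (1/μm) at arbitrary chart angles."""
    polar = np.atleast_1d(np.asarray(polar, dtype=float))
    azimuth = np.atleast_1d(np.asarray(azimuth, dtype=float))
    return _fundamental(surface, polar, azimuth)[0]


def chart_angles_for_directions(
    surface: HarmonicSurface,
    directions: np.ndarray,
    iters: int = 30,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Chart angles whose surface point lies along given rays from center.

    For the default central-projection chart this is the identity; for
    other charts a damped fixed-point iteration aligns the point direction
    with the target.  Raises :class:`GeometryError` if the surface is not
    star-shaped enough for the iteration to converge.
    """
    from scipy.optimize import minimize

    d = np.atleast_2d(np.asarray(directions, dtype=float))
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    # coarse scan of the chart for starting angles
    nv, nu = 65, 128
    gv = np.linspace(1e-3, np.pi - 1e-3, nv)
    gu = np.linspace(0.0, 2.0 * np.pi, nu, endpoint=False)
    vv, uu = (a.ravel() for a in np.meshgrid(gv, gu, indexing="ij"))
    p = surface.evaluate(vv, uu) - surface.center
    p_dir = p / np.linalg.norm(p, axis=1, keepdims=True)
    v_out, u_out = np.empty(len(d)), np.empty(len(d))
    for i, target in enumerate(d):
        start = np.argmax(p_dir @ target)

        def mismatch(ang, target=target):
            q = (surface.evaluate(ang[:1], ang[1:]) - surface.center)[0]
            return 1.0 - float(q @ target) / float(np.linalg.norm(q))

        res = minimize(
            mismatch, np.array([vv[start], uu[start]]), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 400},
        )
        if res.fun > 1e-8:
            raise GeometryError(
                "could not align chart angles with ray directions "
                "(surface not star-shaped about its center?)"
            )
        v_out[i] = np.clip(res.x[0], 0.0, np.pi)
        u_out[i] = np.mod(res.x[1], 2.0 * np.pi)
    return v_out, u_out


def curvatures(
    surface: HarmonicSurface, sampling: SphereQuadrature
) -> CurvatureField:
    """Mean/Gaussian curvature, area element, H0, ε and volume at nodes."""
    v, u = sampling.polar, sampling.azimuth
    H, K, sqrtg, r, n_hat = _fundamental(surface, v, u)
    area_w = sampling.weights * sqrtg / np.sin(v)
    area = float(area_w.sum())
    H0 = float((area_w * H).sum() / area)
    eps = abs(1.0 - float((area_w * K).sum()) / (4.0 * np.pi))
    vol = float(np.einsum("i,ij,ij->", area_w, r - surface.center, n_hat)) / 3.0
    return CurvatureField(
        surface=surface, quadrature=sampling, positions=r, normals=n_hat,
        H=H, K=K, area_weights=area_w, H0=H0,
        H_node_mean=float(H.mean()), epsilon=eps, volume=vol, area=area,
    )


def surface_integral(node_values: np.ndarray, curv: CurvatureField) -> float:
    """∫ f dA over the droplet surface from node samples."""
    node_values = np.asarray(node_values, dtype=float)
    if node_values.shape != curv.area_weights.shape:
        raise ParameterError(
            f"node values have shape {node_values.shape}, expected "
            f"{curv.area_weights.shape}"
        )
    return float((curv.area_weights * node_values).sum())


def average_mean_curvature(curv: CurvatureField) -> float:
    """Area-weighted mean curvature H0 = ∫H dA / ∫dA (1/μm)."""
    return curv.H0


def gauss_bonnet_error(curv: CurvatureField) -> float:
    """Relative deviation of ∫K dA from 4π (reconstruction QC metric)."""
    return curv.epsilon


def volume_from_radius(radii: np.ndarray, sampling: SphereQuadrature) -> float:
    """Volume of a star-shaped surface from its radial chart, ∫ R³/3 dΩ."""
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or not np.all(np.isfinite(radii)):
        raise GeometryError("radial chart undefined: non-positive or non-finite R")
    return sampling.integrate(radii**3) / 3.0


def volume(surface: HarmonicSurface, sampling: SphereQuadrature) -> float:
    """Enclosed volume (μm³) of the fitted surface."""
    return curvatures(surface, sampling).volume
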