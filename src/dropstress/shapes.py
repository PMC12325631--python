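"""Analytic ground-truth droplet shapes.

Shapes are star-shaped (radial) surfaces about a center: a sphere, an
ellipsoid, or a sphere carrying a radial spherical-harmonic perturbation.
They provide both a parametric evaluator (Cartesian components as finite
spherical-harmonic series, used for exact-representability tests) and the
radial function R(direction) used by the image renderer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError
from .quadrature import SphereQuadrature
from .sh import basis_index, n_basis, real_sh_basis


@dataclass(frozen=True)
class GroundTruthShape:
    """A known droplet shape with analytic descriptors.

    Attributes
    ----------
    kind : str
        ``sphere``, ``ellipsoid`` or ``harmonic``.
    center : (3,) array, μm.
    max_degree : int
        Band limit of the exact parametric representation.
    coeffs : (3, K) array
        Real-harmonic coefficients of the Cartesian components (relative to
        ``center``) on the (polar, azimuth) chart.
    radius : float or None
        Sphere radius (μm); mean radius for harmonic shapes.
    semiaxes : (3,) array or None
        Ellipsoid semiaxes a >= b >= c (μm).
    axes : (3, 3) array or None
        Ellipsoid principal directions as rows (ê1, ê2, ê3).
    radial_coeffs : (K,) array or None
        Harmonic coefficients of R(direction) for radial-harmonic shapes.
    """

    kind: str
    center: np.ndarray
    max_degree: int
    coeffs: np.ndarray
    radius: Optional[float] = None
    semiaxes: Optional[np.ndarray] = None
    axes: Optional[np.ndarray] = None
    radial_coeffs: Optional[np.ndarray] = None

    # -- evaluation -------------------------------------------------------
    def point(self, polar: np.ndarray, azimuth: np.ndarray) -> np.ndarray:
        """Parametric surface points at chart angles, shape (N, 3) μm."""
        (B,) = real_sh_basis(self.max_degree, polar, azimuth)
        return B @ self.coeffs.T + self.center

    def radial_function(self, directions: np.ndarray) -> np.ndarray:
        """Distance from center to the surface along unit ``directions``."""
        d = np.atleast_2d(np.asarray(directions, dtype=float))
        if self.kind == "sphere":
            return np.full(d.shape[0], float(self.radius))
        if self.kind == "ellipsoid":
            dp = d @ self.axes.T  # components along principal axes
            return 1.0 / np.sqrt(np.sum((dp / self.semiaxes) ** 2, axis=1))
        polar = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
        azimuth = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2.0 * np.pi)
        L_r = int(round(np.sqrt(self.radial_coeffs.size))) - 1
        (B,) = real_sh_basis(L_r, polar, azimuth)
        return B @ self.radial_coeffs

    def radial_at_angles(self, polar: np.ndarray, azimuth: np.ndarray) -> np.ndarray:
        sv = np.sin(polar)
        d = np.column_stack((sv * np.cos(azimuth), sv * np.sin(azimuth), np.cos(polar)))
        return self.radial_function(d)

    @property
    def max_radius(self) -> float:
        q = SphereQuadrature.gauss_product(max(31, 2 * self.max_degree + 1))
        return float(self.radial_function(q.directions).max())

    @property
    def volume_analytic(self) -> Optional[float]:
        """Closed-form volume (μm³) when available."""
        if self.kind == "sphere":
            return 4.0 / 3.0 * np.pi * self.radius**3
        if self.kind == "ellipsoid":
            return 4.0 / 3.0 * np.pi * float(np.prod(self.semiaxes))
        return None


def _harmonic_peak(l: int, m: int) -> float:  # noqa: E741
    """Global maximum of |Z_{l,m}| over the sphere.

    The azimuthal factor attains 1 at azimuth 0 (m >= 0) or pi/(2|m|)
    (m < 0); the polar profile is scanned on a dense grid.
    """
    polar = np.linspace(0.0, np.pi, 4097)
    azimuth = np.full_like(polar, 0.0 if m >= 0 else np.pi / (2 * abs(m)))
    (B,) = real_sh_basis(l, polar, azimuth)
    return float(np.abs(B[:, basis_index(l, m)]).max())


def _cartesian_coeffs_from_radial(
    radial_coeffs: np.ndarray, L: int
) -> np.ndarray:
    """Project x = R(Ω)·ê(Ω) onto harmonics (exact: band limit L+1)."""
    Lc = L + 1
    q = SphereQuadrature.gauss_product(2 * Lc + 2)
    (B_r,) = real_sh_basis(L, q.polar, q.azimuth)
    R = B_r @ radial_coeffs
    pts = R[:, None] * q.directions
    (B,) = real_sh_basis(Lc, q.polar, q.azimuth)
    # orthonormal basis: coefficients are quadrature inner products
    return ((B * q.weights[:, None]).T @ pts).T  # (3, (Lc+1)^2)


def make_shape(kind: str, **params) -> GroundTruthShape:
    """Construct a ground-truth shape.

    ``sphere``: radius (μm), optional center.
    ``ellipsoid``: semiaxes=(a, b, c) μm, optional axes (rows = principal
    directions; default lab axes), optional center.
    ``harmonic``: radius plus either ``modes=[(l, m, amplitude), ...]`` (μm)
    or ``radial_coeffs`` for R(Ω) = radius + perturbation.
    """
    center = np.asarray(params.get("center", (0.0, 0.0, 0.0)), dtype=float)
    if kind == "sphere":
        R = float(params["radius"])
        if not np.isfinite(R) or R <= 0:
            raise ParameterError(f"sphere radius must be positive, got {R}")
        radial = np.zeros(n_basis(0))
        radial[0] = R * np.sqrt(4.0 * np.pi)  # Z_00 = 1/sqrt(4π)
        coeffs = _cartesian_coeffs_from_radial(radial, 0)
        return GroundTruthShape(
            kind="sphere", center=center, max_degree=1, coeffs=coeffs,
            radius=R, radial_coeffs=radial,
        )
    if kind == "ellipsoid":
        semiaxes = np.asarray(params["semiaxes"], dtype=float)
        if semiaxes.shape != (3,) or np.any(~np.isfinite(semiaxes)) or np.any(semiaxes <= 0):
            raise ParameterError(f"ellipsoid semiaxes must be 3 positive numbers, got {semiaxes}")
        axes = np.asarray(params.get("axes", np.eye(3)), dtype=float)
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-10):
            raise ParameterError("ellipsoid axes must be orthonormal rows")
        order = np.argsort(semiaxes)[::-1]
        semiaxes, axes = semiaxes[order], axes[order]
        # parametric: r = a cos(u) sin(v) ê1 + b sin(u) sin(v) ê2 + c cos(v) ê3
        # sin(v)cos(u), sin(v)sin(u), cos(v) are degree-1 real harmonics:
        c1 = np.sqrt(4.0 * np.pi / 3.0)
        coeffs = np.zeros((3, n_basis(1)))
        for ax_len, ax_dir, (l, m) in zip(
            semiaxes, axes, [(1, 1), (1, -1), (1, 0)]
        ):
            coeffs[:, basis_index(l, m)] += ax_len * c1 * ax_dir
        return GroundTruthShape(
            kind="ellipsoid", center=center, max_degree=1, coeffs=coeffs,
            semiaxes=semiaxes, axes=axes,
        )
    if kind == "harmonic":
        R = float(params["radius"])
        if R <= 0:
            raise ParameterError(f"mean radius must be positive, got {R}")
        if "radial_coeffs" in params:
            radial = np.asarray(params["radial_coeffs"], dtype=float).copy()
            L = int(np.sqrt(radial.size)) - 1
            if n_basis(L) != radial.size:
                raise ParameterError("radial_coeffs length must be a perfect square")
        else:
            # mode amplitudes are peak radial deviations: each harmonic is
            # rescaled by its grid maximum so an "amplitude 0.5 μm" mode
            # deviates by exactly 0.5 μm at its antinode.
            modes = list(params.get("modes", []))
            L = max((l for l, _, _ in modes), default=0)
            radial = np.zeros(n_basis(L))
            for l, m, amp in modes:  # noqa: E741
                if not np.isfinite(amp):
                    raise ParameterError("mode amplitude must be finite")
                radial[basis_index(l, m)] += amp / _harmonic_peak(l, m)
        radial[0] += R * np.sqrt(4.0 * np.pi)
        coeffs = _cartesian_coeffs_from_radial(radial, L)
        return GroundTruthShape(
            kind="harmonic", center=center, max_degree=L + 1, coeffs=coeffs,
            radius=R, radial_coeffs=radial,
        )
    raise ParameterError(f"unknown shape kind {kind!r}")
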