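"""Least-squares ellipsoid (quadric) fit and closed-form mean curvature.

The ellipsoidal deformation mode of a droplet is obtained by fitting the
general quadric

    A x² + B xy + C y² + D xz + E yz + F z² + G x + H y + I z = 1

to the surface point cloud.  Its principal frame (ê1, ê2, ê3) with sorted
semiaxes a >= b >= c gives the directions and magnitude of tissue-scale
stress anisotropy; the mean curvature of the ellipsoid has a closed form
on the parametric chart x1 = a cos(u) sin(v), x2 = b sin(u) sin(v),
x3 = c cos(v).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, ParameterError
from .quadrature import SphereQuadrature
from .shapes import make_shape
from .surface import HarmonicSurface, curvatures


def ellipsoid_mean_curvature(
    a: float, b: float, c: float, u: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Closed-form H_e(u, v) of the ellipsoid with semiaxes a, b, c (1/μm)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    num = a * b * c * (
        3.0 * (a**2 + b**2) + 2.0 * c**2
        + (a**2 + b**2 - 2.0 * c**2) * np.cos(2.0 * v)
        - 2.0 * (a**2 - b**2) * np.cos(2.0 * u) * np.sin(v) ** 2
    )
    den = 8.0 * (
        a**2 * b**2 * np.cos(v) ** 2
        + c**2 * (b**2 * np.cos(u) ** 2 + a**2 * np.sin(u) ** 2) * np.sin(v) ** 2
    ) ** 1.5
    return num / den


@dataclass(frozen=True)
class EllipsoidMode:
    """Quadric fit of the droplet's ellipsoidal deformation mode."""

    quadric: np.ndarray        # (A, B, C, D, E, F, G, H, I)
    center: np.ndarray         # (3,) μm
    axes: np.ndarray           # rows ê1, ê2, ê3 (unit)
    semiaxes: np.ndarray       # (a, b, c) μm, a >= b >= c

    @property
    def a(self) -> float:
        return float(self.semiaxes[0])

    @property
    def b(self) -> float:
        return float(self.semiaxes[1])

    @property
    def c(self) -> float:
        return float(self.semiaxes[2])

    # -- closed-form curvature --------------------------------------------
    def mean_curvature(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return ellipsoid_mean_curvature(self.a, self.b, self.c, u, v)

    @property
    def H_max(self) -> float:
        """H_e at (u=0, v=π/2): a/(2c²) + a/(2b²)."""
        return self.a / (2.0 * self.c**2) + self.a / (2.0 * self.b**2)

    @property
    def H_min(self) -> float:
        """H_e at (u=0, v=0): c/(2b²) + c/(2a²)."""
        return self.c / (2.0 * self.b**2) + self.c / (2.0 * self.a**2)

    def H_at_axis(self, i: int) -> float:
        """H_e where principal axis ê_i (1-based) crosses the surface."""
        a, b, c = self.semiaxes
        if i == 1:
            return self.H_max
        if i == 2:
            return b / (2.0 * c**2) + b / (2.0 * a**2)
        if i == 3:
            return self.H_min
        raise ParameterError(f"principal axis index must be 1, 2 or 3, got {i}")

    def average_mean_curvature(self, sampling: SphereQuadrature) -> float:
        """Area-weighted H_e0 = ∫H_e dA / ∫dA over the ellipsoid."""
        return self.as_harmonic_surface_curvatures(sampling).H0

    def as_harmonic_surface(self) -> HarmonicSurface:
        """Exact degree-1 harmonic representation (parametric chart)."""
        shape = make_shape(
            "ellipsoid", semiaxes=self.semiaxes, axes=self.axes, center=self.center
        )
        return HarmonicSurface(coeffs=shape.coeffs, center=self.center, L=1)

    def as_harmonic_surface_curvatures(self, sampling: SphereQuadrature):
        return curvatures(self.as_harmonic_surface(), sampling)

    # -- geometry ----------------------------------------------------------
    def radial_function(self, directions: np.ndarray) -> np.ndarray:
        """Center-to-surface distance along unit ``directions`` (lab frame)."""
        dp = np.atleast_2d(directions) @ self.axes.T
        return 1.0 / np.sqrt(np.sum((dp / self.semiaxes) ** 2, axis=1))

    def parametric_coords(self, directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) of the surface point radially aligned with each direction.

        This is the droplet↔ellipsoid correspondence: a droplet surface
        point in direction d (about the common center) maps to the
        ellipsoid point along the same ray, whose parametric coordinates
        follow from its principal-frame components.
        """
        d = np.atleast_2d(directions)
        dp = d @ self.axes.T
        R = 1.0 / np.sqrt(np.sum((dp / self.semiaxes) ** 2, axis=1))
        p = R[:, None] * dp
        u = np.arctan2(p[:, 1] / self.b, p[:, 0] / self.a)
        v = np.arccos(np.clip(p[:, 2] / self.c, -1.0, 1.0))
        return u, v


def fit_ellipsoid(points: np.ndarray) -> EllipsoidMode:
    """Least-squares quadric fit, reduced to principal axes and semiaxes.

    Raises :class:`FitError` when the best-fit quadric is not an ellipsoid
    (non-positive-definite quadratic form).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 9:
        raise ParameterError("ellipsoid fit needs at least 9 points of shape (N, 3)")
    x, y, z = pts.T
    M = np.column_stack([x * x, x * y, y * y, x * z, y * z, z * z, x, y, z])
    coef, *_ = np.linalg.lstsq(M, np.ones(len(pts)), rcond=None)
    A, B, C, D, E, F, G, H, I = coef  # noqa: E741
    Q = np.array([
        [A, B / 2.0, D / 2.0],
        [B / 2.0, C, E / 2.0],
        [D / 2.0, E / 2.0, F],
    ])
    g = np.array([G, H, I])
    try:
        center = np.linalg.solve(2.0 * Q, -g)
    except np.linalg.LinAlgError as exc:
        raise FitError("quadric fit is degenerate (singular quadratic form)") from exc
    s = 1.0 - g @ center - center @ Q @ center
    lam, vec = np.linalg.eigh(Q / s)
    if np.any(lam <= 0) or s == 0:
        raise FitError("best-fit quadric is not an ellipsoid (non-positive-definite)")
    semi = 1.0 / np.sqrt(lam)            # eigh: ascending λ → descending axes
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    axes = vec[:, order].T
    # deterministic sign: first component of largest magnitude positive
    for i in range(3):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    return EllipsoidMode(quadric=coef, center=center, axes=axes, semiaxes=semi)
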