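"""Anisotropic stress fields and summaries from droplet geometry.

With interfacial tension γ (mN/m) and mean curvature H (1/μm) the Laplace
law gives the total anisotropic stress at a surface point,

    σ^A = 2 γ (H − H0)          [kPa],

where H0 is the area-weighted average mean curvature.  The ellipsoidal
deformation mode carries the tissue-scale part σ^A_T; what remains,
σ^A_C = σ^A − σ^A_T, is the cell-scale stress field.  Units are chosen so
no conversion factors appear: mN/m × 1/μm = kPa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ellipsoid import EllipsoidMode
from .errors import ParameterError
from .sh import degrees_orders, real_sh_basis
from .surface import CurvatureField, chart_angles_for_directions, mean_curvature_at


# -- weighted quantiles ----------------------------------------------------

def weighted_quantile(
    values: np.ndarray, q: float, weights: Optional[np.ndarray] = None
) -> float:
    """Linear-interpolation quantile of weight-replicated samples.

    With ``weights=None`` this matches :func:`numpy.quantile`.  Quadrature
    nodes are not area-uniform, so stress percentiles default to
    area-weighted quantiles; the unweighted variant is kept for strict
    parity with per-node statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("cannot take quantiles of an empty field")
    if weights is None:
        return float(np.quantile(values, q))
    w = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v, w = values[order], w[order]
    cw = np.cumsum(w) - 0.5 * w           # midpoint plotting positions
    p = cw / w.sum()
    return float(np.interp(q, p, v))


@dataclass(frozen=True)
class StressField:
    """Nodal stress fields (kPa) on the quadrature sampling of a frame."""

    total: np.ndarray                  # σ^A per node
    gamma: float                       # mN/m
    delta_gamma: float                 # mN/m
    curv: CurvatureField
    tissue: Optional[np.ndarray] = None   # σ^A_T map
    cell: Optional[np.ndarray] = None     # σ^A_C map

    @property
    def area_weights(self) -> np.ndarray:
        return self.curv.area_weights


@dataclass(frozen=True)
class StressSummary:
    """α-percentile amplitude summary of a nodal stress field."""

    alpha: float
    low: float        # σ^A_N, kPa
    high: float       # σ^A_M, kPa

    @property
    def amplitude(self) -> float:
        """Δσ^A = σ^A_M − σ^A_N (kPa)."""
        return self.high - self.low


def total_stress(
    curv: CurvatureField, gamma: float, delta_gamma: float = 0.0
) -> StressField:
    """Total anisotropic stress σ^A = 2γ(H − H0) at every node (kPa)."""
    if gamma <= 0:
        raise ParameterError(f"interfacial tension must be positive, got {gamma}")
    sigma = 2.0 * gamma * (curv.H - curv.H0)
    return StressField(total=sigma, gamma=gamma, delta_gamma=delta_gamma, curv=curv)


def stress_summary(
    values: np.ndarray,
    alpha: float = 0.05,
    weights: Optional[np.ndarray] = None,
) -> StressSummary:
    """α / (1−α) quantile range of a nodal field.

    ``alpha=0`` returns the exact minimum and maximum.  Pass the field's
    ``area_weights`` for area-weighted percentiles (the default choice in
    the pipeline), or ``None`` for plain per-node percentiles.
    """
    if not 0.0 <= alpha < 0.5:
        raise ParameterError(f"alpha must lie in [0, 0.5), got {alpha}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("empty stress field")
    if alpha == 0.0:
        return StressSummary(alpha=0.0, low=float(values.min()),
                             high=float(values.max()))
    return StressSummary(
        alpha=alpha,
        low=weighted_quantile(values, alpha, weights),
        high=weighted_quantile(values, 1.0 - alpha, weights),
    )


# -- tissue-scale ----------------------------------------------------------

def tissue_stress_scalar(e: EllipsoidMode, gamma: float) -> float:
    """Closed-form σ^A_T = 2γ(H_{e,M} − H_{e,N}) = γ(a/c² + (a−c)/b² − c/a²)."""
    a, b, c = e.semiaxes
    return gamma * (a / c**2 + (a - c) / b**2 - c / a**2)


def tissue_stress_map(
    e: EllipsoidMode, gamma: float, curv: CurvatureField
) -> np.ndarray:
    """Nodal σ^A_T = 2γ(H_e − H_{e0}) at the corresponding ellipsoid points.

    Node directions (the droplet's radial chart about the ellipsoid
    center) are mapped to the ellipsoid surface along the same ray; H_e is
    evaluated there in closed form and H_{e0} is the area-weighted average
    mean curvature of the ellipsoid.
    """
    u, v = e.parametric_coords(_node_directions(curv, e))
    He = e.mean_curvature(u, v)
    He0 = e.average_mean_curvature(curv.quadrature)
    return 2.0 * gamma * (He - He0)


def _node_directions(curv: CurvatureField, e: EllipsoidMode) -> np.ndarray:
    """Radial directions of the node positions about the common center."""
    rel = curv.positions - e.center
    return rel / np.linalg.norm(rel, axis=1, keepdims=True)


def tissue_stress_pair(e: EllipsoidMode, gamma: float, i: int, j: int) -> float:
    """σ^A_T(ê_i, ê_j) = 2γ(H_e(x_i) − H_e(x_j)) between principal axes."""
    if i == j:
        raise ParameterError("tissue stress pair needs two distinct axes")
    return 2.0 * gamma * (e.H_at_axis(i) - e.H_at_axis(j))


def total_stress_along_axes(
    curv: CurvatureField, e: EllipsoidMode, gamma: float, i: int, j: int
) -> float:
    """σ^A_TT(ê_i, ê_j): like σ^A_T between axes but with the droplet's
    actual mean curvature at the axis-intersection points.

    The droplet curvature is evaluated directly on the fitted surface at
    the two directions ±ê of each axis and averaged (an axis crosses the
    surface twice; for a pure ellipsoid both crossings agree).
    """
    if i == j:
        raise ParameterError("stress anisotropy needs two distinct axes")

    def h_at(axis_idx: int) -> float:
        d = e.axes[axis_idx - 1]
        v, u = chart_angles_for_directions(curv.surface, np.vstack((d, -d)))
        return float(np.mean(mean_curvature_at(curv.surface, v, u)))

    return 2.0 * gamma * (h_at(i) - h_at(j))


# -- cell-scale ------------------------------------------------------------

def cell_stress(
    curv: CurvatureField,
    e: EllipsoidMode,
    gamma: float,
    drop_small_offset: bool = True,
) -> np.ndarray:
    """Cell-scale stress σ^A_C = 2γ[(H − H_e) − (H0 − H_{e0})] per node.

    When the mean-curvature offset H0 − H_{e0} is relatively tiny
    (<1e-3 of H0) it is dropped (``drop_small_offset=True``), matching
    the approximation used in practice; keeping it makes the decomposition
    σ^A = σ^A_T + σ^A_C exact.
    """
    u, v = e.parametric_coords(_node_directions(curv, e))
    He = e.mean_curvature(u, v)
    He0 = e.average_mean_curvature(curv.quadrature)
    offset = curv.H0 - He0
    if drop_small_offset and abs(offset) / abs(curv.H0) < 1e-3:
        offset = 0.0
    return 2.0 * gamma * ((curv.H - He) - offset)


def decompose_stress(
    curv: CurvatureField,
    e: EllipsoidMode,
    gamma: float,
    delta_gamma: float = 0.0,
) -> StressField:
    """Total, tissue-scale and cell-scale nodal fields in one container.

    Built with the exact offset so total = tissue + cell holds nodewise.
    """
    field = total_stress(curv, gamma, delta_gamma)
    tissue = tissue_stress_map(e, gamma, curv)
    cell = field.total - tissue
    return StressField(
        total=field.total, gamma=gamma, delta_gamma=delta_gamma,
        curv=curv, tissue=tissue, cell=cell,
    )


# -- mode spectrum ---------------------------------------------------------

@dataclass(frozen=True)
class ModeSpectrum:
    """Combined spherical-harmonic amplitudes of a nodal residual field.

    Opposite orders ±m of a degree are combined in quadrature, matching
    the symmetric structure of real-field coefficients.
    """

    degrees: np.ndarray          # per combined mode
    orders: np.ndarray           # |m| per combined mode
    amplitudes: np.ndarray       # >= 0
    total_power: float           # quadrature integral of the squared field

    @property
    def cumulative_fraction(self) -> np.ndarray:
        """Fraction of power explained by the strongest k modes (sorted)."""
        p = np.sort(self.amplitudes**2)[::-1]
        tot = p.sum()
        if tot == 0:
            return np.zeros_like(p)
        return np.cumsum(p) / tot

    def modes_for_fraction(self, fraction: float) -> int:
        """Number of strongest modes needed to reach a power fraction."""
        cf = self.cumulative_fraction
        return int(np.searchsorted(cf, fraction) + 1)


def mode_amplitudes(residual_field, sampling, Lmax: int = 20) -> ModeSpectrum:
    """Spherical-harmonic decomposition of a node field up to ``Lmax``.

    Coefficients are quadrature projections onto the orthonormal real
    basis; Parseval's identity (Σ coef² = ∫ f² dΩ) holds to rounding for
    fields band-limited within the rule's exactness.
    """
    if Lmax > sampling.degree // 2:
        raise ParameterError(
            f"Lmax={Lmax} exceeds half the quadrature exactness degree "
            f"({sampling.degree}); projections would alias"
        )
    f = np.asarray(residual_field, dtype=float)
    (B,) = real_sh_basis(Lmax, sampling.polar, sampling.azimuth)
    coef = (B * sampling.weights[:, None]).T @ f
    ls, ms = degrees_orders(Lmax)
    degs, ords, amps = [], [], []
    for l in range(Lmax + 1):  # noqa: E741
        for m in range(0, l + 1):
            c2 = coef[l * (l + 1) + m] ** 2
            if m > 0:
                c2 = c2 + coef[l * (l + 1) - m] ** 2
            degs.append(l)
            ords.append(m)
            amps.append(np.sqrt(c2))
    return ModeSpectrum(
        degrees=np.asarray(degs), orders=np.asarray(ords),
        amplitudes=np.asarray(amps),
        total_power=float(sampling.integrate(f**2)),
    )


# -- orientation -----------------------------------------------------------

@dataclass(frozen=True)
class AxisFrame:
    """Anatomical reference frame (e.g. AP/ML/DV embryo axes)."""

    e_ap: np.ndarray
    e_ml: np.ndarray
    e_dv: np.ndarray

    def __post_init__(self) -> None:
        M = np.vstack((self.e_ap, self.e_ml, self.e_dv)).astype(float)
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-8):
            raise ParameterError("axis frame must be orthonormal")
        object.__setattr__(self, "e_ap", M[0])
        object.__setattr__(self, "e_ml", M[1])
        object.__setattr__(self, "e_dv", M[2])

    @classmethod
    def lab(cls) -> "AxisFrame":
        return cls(np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])


def orientation_angles(e: EllipsoidMode, frame: AxisFrame) -> dict:
    """Angles (deg) between the elongation axis ê1 and each frame axis.

    An axis has no sign, so angles are folded into [0°, 90°].
    """
    out = {}
    for name, ax in (("AP", frame.e_ap), ("ML", frame.e_ml), ("DV", frame.e_dv)):
        cosang = abs(float(np.dot(e.axes[0], ax)))
        out[name] = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return out


# -- error propagation -----------------------------------------------------

def stress_error(
    gamma: float,
    delta_gamma: float,
    H: np.ndarray,
    H0: float,
    delta_H: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagated stress uncertainty per node.

    Returns (δσ^A, relative bound): the absolute error
    sqrt((2(H−H0)δγ)² + (2γδH)²) in kPa and the relative bound
    sqrt((δγ/γ)² + (δH/(H−H0))²), which is NaN where H = H0 (the relative
    error is undefined there; use the absolute value).
    """
    if np.any(np.asarray(delta_gamma) < 0) or np.any(np.asarray(delta_H) < 0):
        raise ParameterError("uncertainties must be non-negative")
    H = np.asarray(H, dtype=float)
    dH = np.broadcast_to(np.asarray(delta_H, dtype=float), H.shape)
    dev = H - H0
    absolute = np.sqrt((2.0 * dev * delta_gamma) ** 2 + (2.0 * gamma * dH) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.sqrt((delta_gamma / gamma) ** 2 + (dH / dev) ** 2)
    relative = np.where(dev == 0.0, np.nan, relative)
    return absolute, relative
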