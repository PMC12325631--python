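"""Real spherical-harmonic basis with analytic angular derivatives.

The real orthonormal basis ``Z_{l,m}`` is assembled from the complex
harmonics ``Y_l^m`` (Condon-Shortley convention, as in :mod:`scipy.special`):

* ``m = 0``:  ``Z = Y_l^0`` (real already),
* ``m > 0``:  ``Z = sqrt(2) * (-1)^m * Re(Y_l^m)``,
* ``m < 0``:  ``Z = sqrt(2) * (-1)^m * Im(Y_l^{|m|})``.

Basis functions are indexed ``k = l*(l+1) + m`` for ``l = 0..L``,
``m = -l..l``.  First and second derivatives with respect to the polar and
azimuthal angles come from :func:`scipy.special.sph_harm_y_all`, which
evaluates them analytically (no finite differences) -- second derivatives
feed the curvature calculation and must be low-noise.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y_all

from .errors import ParameterError


def n_basis(L: int) -> int:
    """Number of real basis functions up to degree ``L``."""
    return (L + 1) ** 2


def basis_index(l: int, m: int) -> int:  # noqa: E741
    """Flat index of the (degree, order) real basis function."""
    if abs(m) > l:
        raise ParameterError(f"|m| = {abs(m)} exceeds degree l = {l}")
    return l * (l + 1) + m


def degrees_orders(L: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (degree, order) labels for the flat basis indexing."""
    ls = np.concatenate([np.full(2 * l + 1, l) for l in range(L + 1)])
    ms = np.concatenate([np.arange(-l, l + 1) for l in range(L + 1)])
    return ls, ms


def real_sh_basis(
    L: int,
    polar: np.ndarray,
    azimuth: np.ndarray,
    diff_n: int = 0,
    chunk: int = 2048,
) -> tuple[np.ndarray, ...]:
    """Evaluate the real basis (and optionally derivatives) at angles.

    Parameters
    ----------
    L : int
        Maximum degree.
    polar, azimuth : (N,) arrays
        Polar angle in [0, pi], azimuth in [0, 2*pi).
    diff_n : {0, 1, 2}
        Highest derivative order to return.
    chunk : int
        Number of points evaluated per pass (bounds peak memory; the complex
        intermediate scales as ``(L+1) * (2L+1) * chunk``).

    Returns
    -------
    tuple of arrays, each of shape (N, (L+1)**2)
        ``(Y,)`` for ``diff_n=0``; ``(Y, Yv, Yu)`` adds polar and azimuthal
        first derivatives; ``(Y, Yv, Yu, Yvv, Yvu, Yuu)`` adds seconds.
    """
    if L < 0:
        raise ParameterError(f"degree L must be >= 0, got {L}")
    if diff_n not in (0, 1, 2):
        raise ParameterError(f"diff_n must be 0, 1 or 2, got {diff_n}")
    polar = np.atleast_1d(np.asarray(polar, dtype=float))
    azimuth = np.atleast_1d(np.asarray(azimuth, dtype=float))
    if polar.shape != azimuth.shape or polar.ndim != 1:
        raise ParameterError("polar and azimuth must be 1-D arrays of equal length")

    N, K = polar.size, n_basis(L)
    n_out = (1, 3, 6)[diff_n]
    out = tuple(np.empty((N, K)) for _ in range(n_out))

    # sqrt(2) * (-1)^m prefactors for positive orders
    m_pos = np.arange(1, L + 1)
    pref = np.sqrt(2.0) * (-1.0) ** m_pos

    for start in range(0, N, chunk):
        sl = slice(start, min(start + chunk, N))
        res = sph_harm_y_all(L, L, polar[sl], azimuth[sl], diff_n=diff_n)
        if diff_n == 0:
            res = (res,)
        # gather: (value, d/dv, d/du, d2/dv2, d2/dvdu, d2/du2)
        parts = [res[0]]
        if diff_n >= 1:
            g = res[1]
            parts += [g[..., 0], g[..., 1]]
        if diff_n == 2:
            h = res[2]
            parts += [h[..., 0, 0], h[..., 0, 1], h[..., 1, 1]]
        for arr, part in zip(out, parts):
            _fill_real(arr[sl], part, L, pref)
    return out


def _fill_real(dst: np.ndarray, cplx: np.ndarray, L: int, pref: np.ndarray) -> None:
    """Map complex harmonics ``cplx[l, m, pt]`` into real-basis columns."""
    for l in range(L + 1):  # noqa: E741
        base = l * (l + 1)
        dst[:, base] = cplx[l, 0].real
        if l:
            m = np.arange(1, l + 1)
            block = cplx[l, 1 : l + 1]  # (l, npts), orders 1..l
            dst[:, base + m] = (pref[: l][None, :] * block.T.real)
            dst[:, base - m] = (pref[: l][None, :] * block.T.imag)


def fit_coefficients(
    L: int, polar: np.ndarray, azimuth: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares fit of real harmonics to samples; returns (coeffs, rms)."""
    (B,) = real_sh_basis(L, polar, azimuth)
    coef, *_ = np.linalg.lstsq(B, values, rcond=None)
    rms = float(np.sqrt(np.mean((B @ coef - values) ** 2)))
    return coef, rms
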