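"""Spatial and temporal autocorrelation of surface stress fields.

Spatial: pairs of node values are binned over geodesic separation with a
compactly supported bump kernel w(s) = exp(1 − 1/(ℓ² − s²)) for s < ℓ,
with ℓ a fraction (default 5%) of the geodesic diameter.  The estimator is
the kernel-weighted average of pair products normalized by the weighted
average of squared values, and the curve is normalized to C(0) = 1.

Temporal: fields are compared at the same radial parameterization (same
node directions) across frames; C(τ) averages products over nodes and
over all start times and is normalized by the zero-lag term.  No mean is
subtracted — stress fields are zero-mean by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError
from .meshgeo import NodeMesh, geodesic_distances


@dataclass(frozen=True)
class CorrelationCurve:
    """An autocorrelation curve over distance (μm) or lag (min)."""

    abscissa: np.ndarray
    values: np.ndarray
    kind: str                      # "spatial" | "temporal"
    field_kind: str = "total"      # total | tissue | cell
    kernel_width: Optional[float] = None   # ℓ (μm), spatial only

    def __post_init__(self) -> None:
        if np.any(np.diff(self.abscissa) <= 0):
            raise ParameterError("correlation abscissa must be strictly increasing")


def bump_kernel(s: np.ndarray, ell: float) -> np.ndarray:
    """w(s) = exp(1 − 1/(ℓ² − s²)) for |s| < ℓ, else 0."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    inside = np.abs(s) < ell
    d = ell**2 - s[inside] ** 2
    out[inside] = np.exp(1.0 - 1.0 / d)
    return out


def spatial_autocorrelation(
    field_values: np.ndarray,
    mesh: NodeMesh,
    ell_fraction: float = 0.05,
    n_bins: int = 50,
    field_kind: str = "total",
    distances: Optional[np.ndarray] = None,
) -> CorrelationCurve:
    """Kernel-binned spatial autocorrelation over geodesic separation.

    ``distances`` may supply a precomputed all-pairs geodesic matrix
    (reused across the three stress kinds of a frame).  The kernel width
    ℓ is ``ell_fraction`` of the geodesic diameter; values well below the
    node spacing make the estimate noisy (a warning, not an error).
    """
    f = np.asarray(field_values, dtype=float)
    if f.shape != (mesh.n_vertices,):
        raise ParameterError("field must have one value per mesh vertex")
    if distances is None:
        distances = geodesic_distances(mesh)
    diameter = float(distances.max())
    ell = ell_fraction * diameter
    # smallest nonzero neighbor separation
    G = mesh.geodesic_graph()
    min_spacing = float(G.data.min())
    if ell < min_spacing:
        warnings.warn(
            f"kernel width ℓ={ell:.3g} μm below the node spacing "
            f"{min_spacing:.3g} μm; the estimate will be noisy", stacklevel=2,
        )
    s_grid = np.linspace(0.0, diameter, n_bins)
    iu = np.triu_indices(mesh.n_vertices, k=0)   # include self-pairs at s=0
    d_pairs = distances[iu]
    prod = np.outer(f, f)[iu]
    sq = np.outer(f**2, np.ones_like(f))[iu]
    num = np.empty(n_bins)
    den = np.empty(n_bins)
    for k, s in enumerate(s_grid):
        w = bump_kernel(d_pairs - s, ell)
        num[k] = float(w @ prod)
        den[k] = float(w @ sq)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = num / den
    C = C / C[0]                                 # normalization: C(0) = 1
    return CorrelationCurve(abscissa=s_grid, values=C, kind="spatial",
                            field_kind=field_kind, kernel_width=ell)


def temporal_autocorrelation(
    field_series: Sequence[np.ndarray],
    times: Sequence[float],
    field_kind: str = "total",
) -> CorrelationCurve:
    """Node-matched temporal autocorrelation over all start times.

    Frames must share the node sampling.  Times must lie on a uniform
    grid (missing frames may be encoded as None in ``field_series``); the
    result is invariant to a constant time offset.
    """
    times = np.asarray(times, dtype=float)
    fields = list(field_series)
    if len(fields) != times.size or len(fields) < 2:
        raise ParameterError("need >= 2 frames with matching time stamps")
    n_nodes = {len(f) for f in fields if f is not None}
    if len(n_nodes) != 1:
        raise ParameterError("frames have mismatched node sets")
    steps = np.diff(times)
    dt = float(np.min(steps))
    idx = np.round((times - times[0]) / dt).astype(int)
    if not np.allclose(idx * dt + times[0], times, atol=1e-6 * dt):
        raise ParameterError("frame times must lie on a uniform grid")
    n_slots = idx.max() + 1
    slots: list[Optional[np.ndarray]] = [None] * n_slots
    for i, f in zip(idx, fields):
        slots[i] = None if f is None else np.asarray(f, dtype=float)
    denom = np.mean([np.mean(f**2) for f in slots if f is not None])
    lags, vals = [], []
    for lag in range(n_slots):
        prods = [
            np.mean(slots[t] * slots[t + lag])
            for t in range(n_slots - lag)
            if slots[t] is not None and slots[t + lag] is not None
        ]
        if prods:
            lags.append(lag * dt)
            vals.append(float(np.mean(prods) / denom))
    return CorrelationCurve(
        abscissa=np.asarray(lags), values=np.asarray(vals),
        kind="temporal", field_kind=field_kind,
    )


def correlation_scale(
    curve: CorrelationCurve, threshold: float = np.exp(-1)
) -> float:
    """First abscissa where the curve falls below the threshold.

    Linear interpolation between the bracketing grid points; ``inf`` when
    the curve never crosses (a beyond-range sentinel).
    """
    C, s = curve.values, curve.abscissa
    below = np.nonzero(C < threshold)[0]
    if below.size == 0:
        return float("inf")
    i = int(below[0])
    if i == 0:
        return float(s[0])
    c0, c1 = C[i - 1], C[i]
    return float(s[i - 1] + (c0 - threshold) / (c0 - c1) * (s[i] - s[i - 1]))
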