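"""Per-frame and time-lapse orchestration with QC gating.

``analyze_frame`` runs image → point cloud → harmonic surface → curvature
→ stress decomposition → extrema for one stack and applies the
Gauss-Bonnet quality gate (frames with ε above the threshold are flagged
rejected and excluded from time series).  ``analyze_timelapse`` assembles
per-frame scalars into a table and computes temporal autocorrelations of
the three stress kinds on the shared node sampling, preserving gaps where
frames were rejected.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .correlations import CorrelationCurve, spatial_autocorrelation, temporal_autocorrelation
from .ellipsoid import EllipsoidMode, fit_ellipsoid
from .errors import DropstressError, ReconstructionError
from .image import VolumetricImage
from .meshgeo import ExtremaSet, NodeMesh, find_extrema, pair_statistics, triangulate_nodes
from .quadrature import SphereQuadrature
from .reconstruction import SurfacePointCloud, reconstruct_pointcloud
from .stress import (
    AxisFrame,
    StressField,
    StressSummary,
    decompose_stress,
    orientation_angles,
    stress_summary,
    tissue_stress_scalar,
    total_stress_along_axes,
)
from .surface import CurvatureField, HarmonicSurface, curvatures, fit_harmonics, max_admissible_degree

log = logging.getLogger(__name__)


@dataclass
class FrameResult:
    """Everything computed for one timepoint."""

    index: int
    time: Optional[float]              # min
    cloud: SurfacePointCloud
    surface: HarmonicSurface
    curv: CurvatureField
    stress: StressField
    ellipsoid: EllipsoidMode
    summary_total: StressSummary
    summary_cell: StressSummary
    sigma_tissue: float                # closed-form σ^A_T (kPa)
    sigma_tt: dict                     # σ^A_TT per principal-axis pair
    angles: dict                       # θ_AP, θ_ML, θ_DV (deg)
    epsilon: float
    accepted: bool
    mesh: Optional[NodeMesh] = None
    extrema: Optional[ExtremaSet] = None
    pair_stats: Optional[object] = None
    spatial_curves: dict = field(default_factory=dict)

    def scalar_row(self) -> dict:
        return {
            "frame": self.index,
            "time_min": self.time,
            "n_points": len(self.cloud),
            "H0": self.curv.H0,
            "volume": self.curv.volume,
            "epsilon": self.epsilon,
            "accepted": self.accepted,
            "sigma_A_low": self.summary_total.low,
            "sigma_A_high": self.summary_total.high,
            "delta_sigma_A": self.summary_total.amplitude,
            "sigma_T": self.sigma_tissue,
            "delta_sigma_C": self.summary_cell.amplitude,
            "a": self.ellipsoid.a,
            "b": self.ellipsoid.b,
            "c": self.ellipsoid.c,
            "theta_AP": self.angles["AP"],
            "theta_ML": self.angles["ML"],
            "theta_DV": self.angles["DV"],
            **{f"sigma_TT_{i}{j}": v for (i, j), v in self.sigma_tt.items()},
        }


@dataclass
class TimeSeriesResult:
    """Assembled per-frame scalars and temporal correlation curves."""

    frames: list[FrameResult]
    table: pd.DataFrame                # all frames, accepted column included
    temporal_curves: dict              # field kind → CorrelationCurve

    @property
    def accepted_table(self) -> pd.DataFrame:
        return self.table[self.table["accepted"]].reset_index(drop=True)


def analyze_frame(
    image: VolumetricImage,
    config: Optional[AnalysisConfig] = None,
    index: int = 0,
    quadrature: Optional[SphereQuadrature] = None,
) -> FrameResult:
    """Run the full single-frame analysis.

    A prebuilt ``quadrature`` may be shared across frames to avoid
    rebuilding node tables.
    """
    cfg = config if config is not None else AnalysisConfig()
    t0 = _time.perf_counter()
    try:
        if cfg.rescale_isotropic is not None:
            image = _rescale(image, cfg.rescale_isotropic)
        cloud = reconstruct_pointcloud(
            image,
            label_mode=cfg.label_mode,
            n_rays=cfg.n_rays,
            refine_iterations=cfg.refine_iterations,
            mls=cfg.mls,
            mls_radius=cfg.mls_radius,
            residual_threshold=cfg.residual_threshold,
            provisional_degree=cfg.provisional_degree,
            half_window=cfg.refine_half_window,
        )
        L = min(cfg.harmonic_degree, max_admissible_degree(len(cloud)))
        if L < cfg.harmonic_degree:
            log.warning("frame %d: degree reduced to %d for %d points",
                        index, L, len(cloud))
        surface = fit_harmonics(cloud.points, L)
        quad = quadrature if quadrature is not None else SphereQuadrature.gauss_product(
            cfg.quadrature_degree
        )
        curv = curvatures(surface, quad)
        ell = fit_ellipsoid(cloud.points)
        stress = decompose_stress(curv, ell, cfg.gamma, cfg.delta_gamma)
        weights = curv.area_weights if cfg.area_weighted_percentiles else None
        sum_tot = stress_summary(stress.total, cfg.alpha, weights)
        sum_cell = stress_summary(stress.cell, cfg.alpha, weights)
        sigma_t = tissue_stress_scalar(ell, cfg.gamma)
        sigma_tt = {
            (i, j): total_stress_along_axes(curv, ell, cfg.gamma, i, j)
            for i, j in ((1, 2), (1, 3), (2, 3))
        }
        frame_axes = AxisFrame(*cfg.axis_frame)
        angles = orientation_angles(ell, frame_axes)
        accepted = curv.epsilon <= cfg.epsilon_threshold
        mesh = extrema = stats = None
        spatial = {}
        if cfg.compute_extrema:
            mesh = triangulate_nodes(quad, positions=curv.positions,
                                     normals=curv.normals,
                                     neighbor_ring=cfg.neighbor_ring)
            extrema = find_extrema(stress.cell, mesh)
            stats = pair_statistics(extrema, mesh, stress.cell)
        if cfg.compute_spatial_correlation:
            if mesh is None:
                mesh = triangulate_nodes(quad, positions=curv.positions,
                                         normals=curv.normals,
                                         neighbor_ring=cfg.neighbor_ring)
            from .meshgeo import geodesic_distances
            D = geodesic_distances(mesh)
            for kind, f in (("total", stress.total), ("tissue", stress.tissue),
                            ("cell", stress.cell)):
                spatial[kind] = spatial_autocorrelation(
                    f, mesh, cfg.spatial_ell_fraction, cfg.spatial_bins,
                    field_kind=kind, distances=D,
                )
        result = FrameResult(
            index=index, time=image.timestamp, cloud=cloud, surface=surface,
            curv=curv, stress=stress, ellipsoid=ell,
            summary_total=sum_tot, summary_cell=sum_cell,
            sigma_tissue=sigma_t, sigma_tt=sigma_tt, angles=angles,
            epsilon=curv.epsilon, accepted=accepted,
            mesh=mesh, extrema=extrema, pair_stats=stats,
            spatial_curves=spatial,
        )
    except DropstressError as exc:
        raise type(exc)(f"frame {index}: {exc}") from exc
    log.info(
        "frame %d: N=%d ε=%.2e rms=%.3g %s (%.1f s)",
        index, len(cloud), curv.epsilon, surface.fit_rms,
        "accepted" if accepted else "REJECTED", _time.perf_counter() - t0,
    )
    return result


def analyze_timelapse(
    images: Sequence[VolumetricImage],
    config: Optional[AnalysisConfig] = None,
) -> TimeSeriesResult:
    """Analyze every frame, assemble time series and temporal correlations.

    Frames failing the ε gate stay in the table (flagged) but are excluded
    from the accepted series; their slots enter the temporal correlation
    as gaps.  Frames may be given in any order; results are ordered by
    time.
    """
    if len(images) == 0:
        raise ReconstructionError("no frames to analyze")
    cfg = config if config is not None else AnalysisConfig()
    quad = SphereQuadrature.gauss_product(cfg.quadrature_degree)
    frames = [
        analyze_frame(img, cfg, index=i, quadrature=quad)
        for i, img in enumerate(images)
    ]
    frames.sort(key=lambda fr: (fr.time if fr.time is not None else fr.index))
    table = pd.DataFrame([fr.scalar_row() for fr in frames])
    if not table["accepted"].any():
        eps = table[["frame", "epsilon"]].to_string(index=False)
        raise ReconstructionError(
            f"all frames rejected by the ε gate:\n{eps}"
        )
    temporal = {}
    times = [fr.time if fr.time is not None else float(fr.index)
             for fr in frames]
    if len(frames) >= 2:
        for kind in ("total", "tissue", "cell"):
            series = [
                getattr(fr.stress, kind) if fr.accepted else None
                for fr in frames
            ]
            temporal[kind] = temporal_autocorrelation(series, times, kind)
    return TimeSeriesResult(frames=frames, table=table, temporal_curves=temporal)


def _rescale(image: VolumetricImage, target: float) -> VolumetricImage:
    """Resample to isotropic voxels of the given size (explicit, logged)."""
    from scipy.ndimage import zoom

    factors = image.spacing / target
    log.info("rescaling image by factors %s to %.3g μm voxels",
             np.round(factors, 3), target)
    data = zoom(image.data, factors, order=3)
    return VolumetricImage(
        data=data, spacing=np.full(3, target), timestamp=image.timestamp,
        metadata=image.metadata,
    )
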