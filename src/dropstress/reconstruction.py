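"""Droplet surface reconstruction from 3-D fluorescence stacks.

The reconstruction follows the segmentation-seeded raytracing scheme:

1. Otsu threshold → largest connected component → marching-cubes mesh
   (lightly smoothed) and region centroid.
2. Rays from the centroid through near-uniform sphere directions sample the
   intensity; each profile is fit with an edge model (Gaussian ridge for
   surface labels, attenuated sigmoid for interior labels) by
   Levenberg-Marquardt, giving a sub-voxel surface point per accepted ray.
3. The procedure is repeated with rays retraced along local surface
   normals obtained from a provisional spherical-harmonic fit.
4. A 2-D moving-least-squares pass projects each point onto a local
   polynomial patch fitted in its tangent frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes

from .errors import ParameterError, ReconstructionError, SegmentationError
from .image import VolumetricImage
from .surface import fit_harmonics, max_admissible_degree

log = logging.getLogger(__name__)

_ICOSPHERE_SUBDIV = {12: 0, 42: 1, 162: 2, 642: 3, 2562: 4, 10242: 5}


@dataclass
class EdgeFit:
    """Result of fitting an edge model to one sampled ray profile."""

    kind: str                 # "gaussian" | "attenuated-sigmoid"
    params: np.ndarray        # (a, b, c, d, e)
    residual: float           # RMS residual / intensity range
    success: bool

    @property
    def b(self) -> float:
        """Edge location along the ray (μm from the ray origin)."""
        return float(self.params[1])


@dataclass
class Ray:
    """A sampling ray with its intensity profile."""

    origin: np.ndarray        # (3,) μm
    direction: np.ndarray     # (3,) unit
    step: float               # μm
    x: np.ndarray             # (n,) sample offsets along the ray, μm
    profile: np.ndarray       # (n,) sampled intensities


@dataclass
class SurfacePointCloud:
    """Sub-voxel droplet surface points with outward normals."""

    points: np.ndarray                    # (N, 3) μm
    normals: Optional[np.ndarray]         # (N, 3) unit, outward
    center: np.ndarray                    # (3,) μm
    provenance: np.ndarray = field(default=None)  # pass label per point
    residuals: np.ndarray = field(default=None)   # edge-fit residual per point

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("point cloud contains non-finite coordinates")
        if self.provenance is None:
            self.provenance = np.zeros(len(self.points), dtype=int)
        if self.residuals is None:
            self.residuals = np.full(len(self.points), np.nan)

    def __len__(self) -> int:
        return len(self.points)


# -- 1. segmentation ------------------------------------------------------

def initial_surface(
    image: VolumetricImage,
    threshold_method: str = "otsu",
    smooth_iterations: int = 10,
) -> tuple[trimesh.Trimesh, np.ndarray]:
    """Coarse droplet mesh and center from thresholding + marching cubes.

    The binary mask is hole-filled (surface labels produce hollow shells),
    and the marching-cubes mesh is Laplacian-smoothed for
    ``smooth_iterations`` passes to remove voxel staircase artifacts.
    """
    if threshold_method != "otsu":
        raise ParameterError(f"unknown threshold method {threshold_method!r}")
    data = image.data
    if data.max() <= data.min():
        raise SegmentationError("blank image: no intensity variation to threshold")
    mask = data > threshold_otsu(data)
    if not mask.any():
        raise SegmentationError("segmentation found 0 foreground components")
    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    big = np.nonzero(sizes >= max(64.0, 0.05 * sizes.max()))[0]
    if big.size != 1:
        raise SegmentationError(
            f"expected a single droplet but found {big.size} large components"
        )
    mask = ndimage.binary_fill_holes(labels == big[0] + 1)
    center = np.asarray(ndimage.center_of_mass(mask)) * image.spacing
    verts, faces, _, _ = marching_cubes(
        mask.astype(float), level=0.5, spacing=tuple(image.spacing)
    )
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if smooth_iterations > 0:
        trimesh.smoothing.filter_laplacian(mesh, iterations=smooth_iterations)
    log.info(
        "initial surface: %d voxels, center %s, mesh %d verts",
        int(mask.sum()), np.round(center, 2), len(mesh.vertices),
    )
    return mesh, center


# -- 2. edge models -------------------------------------------------------

def _sigmoid_model(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, b, c, d, e = p
    return (d + c * (x - b)) / (1.0 + np.exp(np.clip(a * (x - b), -60.0, 60.0))) + e


def _gaussian_model(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, b, c, d, e = p
    return d * np.exp(-np.clip(a, 0.0, None) * (x - b) ** 2) + c * (x - b) + e


_MODELS = {"attenuated-sigmoid": _sigmoid_model, "gaussian": _gaussian_model}


def _initial_guess(kind: str, x: np.ndarray, y: np.ndarray, step: float) -> np.ndarray:
    n4 = max(len(y) // 4, 1)
    if kind == "attenuated-sigmoid":
        b0 = x[np.argmin(np.gradient(y, x))]
        d0 = np.median(y[:n4]) - np.median(y[-n4:])
        return np.array([2.0 / step, b0, 0.0, d0, np.median(y[-n4:])])
    b0 = x[np.argmax(y)]
    e0 = np.min(y)
    sigma0 = max(2.0 * step, 1e-3)
    return np.array([1.0 / (2.0 * sigma0**2), b0, 0.0, np.max(y) - e0, e0])


def fit_edge_profile(
    x: np.ndarray,
    y: np.ndarray,
    model_kind: str,
    residual_threshold: float = 0.5,
) -> EdgeFit:
    """Fit one intensity profile; flat or off-window fits are flagged."""
    if model_kind not in _MODELS:
        raise ParameterError(f"unknown edge model {model_kind!r}")
    model = _MODELS[model_kind]
    rng_y = float(y.max() - y.min())
    if rng_y <= 1e-12 * max(abs(float(y.max())), 1.0) or len(x) < 8:
        return EdgeFit(model_kind, np.full(5, np.nan), np.inf, False)
    p0 = _initial_guess(model_kind, x, y, float(x[1] - x[0]))
    try:
        res = least_squares(lambda p: model(p, x) - y, p0, method="lm", xtol=1e-12)
    except Exception:
        return EdgeFit(model_kind, p0, np.inf, False)
    rel = float(np.sqrt(np.mean(res.fun**2)) / rng_y)
    b = res.x[1]
    ok = bool(res.success) and (x[0] <= b <= x[-1]) and rel < residual_threshold
    return EdgeFit(model_kind, res.x, rel, ok)


def trace_rays(
    image: VolumetricImage,
    origins: np.ndarray,
    directions: np.ndarray,
    lengths: np.ndarray,
    step: Optional[float] = None,
    interpolation_order: int = 3,
) -> list[Ray]:
    """Sample intensity profiles along rays.

    Intensities come from spline interpolation of the stack (cubic by
    default; order 1 gives plain trilinear).  The sampling step defaults
    to half the smallest voxel spacing, giving sub-voxel localization
    without inventing data.
    """
    origins = np.atleast_2d(origins)
    directions = np.atleast_2d(directions)
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    if step is None:
        step = float(image.spacing.min()) / 2.0
    rays = []
    for o, d, length in zip(origins, directions, np.broadcast_to(lengths, (len(origins),))):
        x = np.arange(0.0, float(length) + step / 2, step)
        pts = o + np.outer(x, d)
        inside = image.contains(pts)
        x = x[inside]
        rays.append(Ray(origin=o, direction=d, step=step, x=x,
                        profile=image.sample(pts[inside], order=interpolation_order)))
    return rays


def trace_and_fit(
    image: VolumetricImage,
    rays: list[Ray],
    model_kind: str,
    residual_threshold: float = 0.5,
) -> list[EdgeFit]:
    """One edge fit per ray; failures are flagged, never dropped silently."""
    return [
        fit_edge_profile(r.x, r.profile, model_kind, residual_threshold)
        for r in rays
    ]


def _points_from_fits(rays: list[Ray], fits: list[EdgeFit]):
    pts, resid, ok = [], [], []
    for r, f in zip(rays, fits):
        ok.append(f.success)
        if f.success:
            pts.append(r.origin + f.b * r.direction)
            resid.append(f.residual)
    return np.asarray(pts), np.asarray(resid), np.asarray(ok)


# -- 3. passes ------------------------------------------------------------

def sphere_directions(n_rays: int = 2562) -> np.ndarray:
    """Near-uniform unit directions from a subdivided icosahedron."""
    if n_rays not in _ICOSPHERE_SUBDIV:
        raise ParameterError(
            f"n_rays must be one of {sorted(_ICOSPHERE_SUBDIV)} (icosphere sizes)"
        )
    v = trimesh.creation.icosphere(subdivisions=_ICOSPHERE_SUBDIV[n_rays]).vertices
    return np.asarray(v / np.linalg.norm(v, axis=1, keepdims=True))


def first_pass(
    image: VolumetricImage,
    center: np.ndarray,
    model_kind: str,
    n_rays: int = 2562,
    r_max: Optional[float] = None,
    residual_threshold: float = 0.5,
    interpolation_order: int = 3,
) -> SurfacePointCloud:
    """Radial raytracing pass from the segmentation centroid."""
    dirs = sphere_directions(n_rays)
    if r_max is None:
        r_max = float(np.min(np.minimum(center, image.extent - center)))
    rays = trace_rays(image, np.tile(center, (len(dirs), 1)), dirs, r_max,
                      interpolation_order=interpolation_order)
    fits = trace_and_fit(image, rays, model_kind, residual_threshold)
    pts, resid, ok = _points_from_fits(rays, fits)
    n_fail = int((~ok).sum())
    if len(pts) < max(16, len(dirs) // 2):
        raise ReconstructionError(
            f"first pass: {n_fail}/{len(dirs)} edge fits failed "
            "(wrong label mode or empty image?)"
        )
    log.info("first pass: %d/%d rays accepted", len(pts), len(dirs))
    normals = (pts - center) / np.linalg.norm(pts - center, axis=1, keepdims=True)
    return SurfacePointCloud(points=pts, normals=normals, center=center,
                             provenance=np.zeros(len(pts), int), residuals=resid)


def refine_along_normals(
    image: VolumetricImage,
    cloud: SurfacePointCloud,
    model_kind: str,
    half_window: float = 5.0,
    provisional_degree: int = 10,
    residual_threshold: float = 0.5,
    interpolation_order: int = 3,
) -> SurfacePointCloud:
    """Re-trace each point along its local surface normal and refit.

    Normals come from a provisional harmonic fit of the input cloud (the
    cloud's own normals are used as a fallback for tiny clouds).  Points
    whose refit fails are removed; the removal count is logged.  More than
    50% failures aborts with an error (usually a wrong edge model).
    """
    L = min(provisional_degree, max_admissible_degree(len(cloud)))
    if L >= 1:
        surf = fit_harmonics(cloud.points, L, center=cloud.center)
        rel = cloud.points - surf.center
        rad = np.linalg.norm(rel, axis=1)
        polar = np.arccos(np.clip(rel[:, 2] / rad, -1, 1))
        azim = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
        normals = surf.normals(polar, azim)
    else:
        normals = cloud.normals
    # orient along the outward radial direction so the edge model sees
    # interior first, background last
    radial = cloud.points - cloud.center
    flip = np.sign(np.einsum("ij,ij->i", normals, radial))
    normals = normals * flip[:, None]
    origins = cloud.points - half_window * normals
    rays = trace_rays(image, origins, normals, 2.0 * half_window,
                      interpolation_order=interpolation_order)
    fits = trace_and_fit(image, rays, model_kind, residual_threshold)
    pts, resid, ok = _points_from_fits(rays, fits)
    n_fail = int((~ok).sum())
    if n_fail > 0.5 * len(cloud):
        raise ReconstructionError(
            f"normal refinement: {n_fail}/{len(cloud)} refits failed "
            "(likely wrong edge model kind)"
        )
    if n_fail:
        log.info("normal refinement: removed %d/%d points", n_fail, len(cloud))
    return SurfacePointCloud(
        points=pts, normals=normals[ok], center=cloud.center,
        provenance=np.ones(len(pts), int), residuals=resid,
    )


# -- 4. moving least squares ----------------------------------------------

def smooth_mls(
    cloud: SurfacePointCloud,
    search_radius: Optional[float] = None,
    poly_degree: int = 2,
) -> tuple[SurfacePointCloud, np.ndarray]:
    """Project each point onto a local polynomial patch (Monge form).

    Each point's neighborhood is rotated so the local normal is the patch
    z-axis, a 2-D polynomial of ``poly_degree`` is fit by least squares,
    and the point moves onto the patch.  Returns the smoothed cloud and a
    per-point local mean-curvature diagnostic (1/μm, sphere-positive).
    """
    pts, normals = cloud.points, cloud.normals
    if normals is None:
        raise ParameterError("MLS smoothing needs per-point normals")
    if search_radius is None:
        # 10% of the mean radius, but never below ~2.5 mean point spacings
        # so sparse clouds still fill their patches
        r_mean = float(np.mean(np.linalg.norm(pts - cloud.center, axis=1)))
        spacing = np.sqrt(4.0 * np.pi) * r_mean / np.sqrt(len(pts))
        search_radius = max(0.1 * r_mean, 2.5 * spacing)
    n_coef = (poly_degree + 1) * (poly_degree + 2) // 2
    tree = cKDTree(pts)
    neighborhoods = tree.query_ball_point(pts, search_radius)
    starved = [i for i, nb in enumerate(neighborhoods) if len(nb) < n_coef]
    if starved:
        raise ParameterError(
            f"MLS neighborhoods of fewer than {n_coef} points at indices "
            f"{starved[:10]}{'...' if len(starved) > 10 else ''}; "
            "increase the search radius"
        )
    powers = [(i, j) for t in range(poly_degree + 1) for i, j in
              [(t - jj, jj) for jj in range(t + 1)]]
    new_pts = np.empty_like(pts)
    H_local = np.empty(len(pts))
    for i, nb in enumerate(neighborhoods):
        n_hat = normals[i]
        # orthonormal tangent frame
        t1 = np.cross(n_hat, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-8:
            t1 = np.cross(n_hat, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n_hat, t1)
        local = (pts[nb] - pts[i]) @ np.column_stack((t1, t2, n_hat))
        A = np.column_stack([
            local[:, 0] ** p * local[:, 1] ** q for p, q in powers
        ])
        coef, *_ = np.linalg.lstsq(A, local[:, 2], rcond=None)
        c = dict(zip(powers, coef))
        new_pts[i] = pts[i] + c[(0, 0)] * n_hat
        if poly_degree >= 2:
            hx, hy = c[(1, 0)], c[(0, 1)]
            hxx, hxy, hyy = 2 * c[(2, 0)], c[(1, 1)], 2 * c[(0, 2)]
            denom = 2.0 * (1 + hx**2 + hy**2) ** 1.5
            H_local[i] = -((1 + hy**2) * hxx - 2 * hx * hy * hxy
                           + (1 + hx**2) * hyy) / denom
        else:
            H_local[i] = np.nan
    out = SurfacePointCloud(
        points=new_pts, normals=normals, center=cloud.center,
        provenance=np.full(len(pts), 2, int), residuals=cloud.residuals,
    )
    return out, H_local


# -- top-level convenience -------------------------------------------------

def reconstruct_pointcloud(
    image: VolumetricImage,
    label_mode: str = "interior",
    n_rays: int = 2562,
    refine_iterations: int = 1,
    mls: bool = True,
    mls_radius: Optional[float] = None,
    mls_degree: int = 2,
    residual_threshold: float = 0.5,
    provisional_degree: int = 10,
    half_window: float = 5.0,
    interpolation_order: int = 3,
) -> SurfacePointCloud:
    """Full image → refined surface point cloud."""
    model = {"interior": "attenuated-sigmoid", "surface": "gaussian"}.get(label_mode)
    if model is None:
        raise ParameterError(f"unknown label mode {label_mode!r}")
    _, center = initial_surface(image)
    cloud = first_pass(image, center, model, n_rays,
                       residual_threshold=residual_threshold,
                       interpolation_order=interpolation_order)
    for _ in range(refine_iterations):
        cloud = refine_along_normals(
            image, cloud, model, half_window=half_window,
            provisional_degree=provisional_degree,
            residual_threshold=residual_threshold,
            interpolation_order=interpolation_order,
        )
    if mls:
        cloud, _ = smooth_mls(cloud, search_radius=mls_radius,
                              poly_degree=mls_degree)
    return cloud
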