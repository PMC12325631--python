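"""Synthetic droplet images, time-lapses and node-field fixtures.

The renderer emulates the two labeling geometries of droplet experiments:
a *surface* label (fluorophore adsorbed at the interface, imaged as a thin
bright shell) and an *interior* label (fluorescent oil, bright plateau
inside with a sharp intensity drop at the interface and a mild linear
attenuation within the droplet).  The interior profile is the generative
inverse of the attenuated-sigmoid edge model fitted during reconstruction,
so a noiseless render admits a zero-residual fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import eval_legendre

from .errors import ParameterError
from .image import VolumetricImage
from .quadrature import SphereQuadrature
from .sh import basis_index, n_basis, real_sh_basis
from .shapes import GroundTruthShape, make_shape

__all__ = [
    "RenderConfig",
    "render_image",
    "make_timelapse",
    "make_stress_fixture",
    "rotating_ellipsoid_schedule",
    "breathing_mode_schedule",
]


@dataclass(frozen=True)
class RenderConfig:
    """Synthetic image formation parameters.

    Defaults follow the acquisition geometry of typical droplet stacks
    (in-plane 0.346 μm, axial 4 μm); reconstruction-accuracy tests use the
    recommended near-isotropic regime (voxel < R/10) instead.
    """

    label_mode: str = "interior"            # "surface" | "interior"
    spacing: tuple = (4.0, 0.346, 0.346)    # μm per axis (axis 0 = stack)
    extent_voxels: Optional[tuple] = None   # auto-sized when None
    margin: float = 2.0                     # μm clearance around the shape
    shell_width: Optional[float] = None     # μm; default 2x in-plane spacing
    edge_steepness: float = 4.0             # 1/μm, sigmoid sharpness a
    attenuation_slope: float = 0.01         # intensity/μm inside the droplet
    plateau: float = 1.0                    # interior / ridge amplitude
    baseline: float = 0.05                  # background level
    noise: str = "none"                     # "none" | "gaussian" | "poisson"
    noise_magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label_mode not in ("surface", "interior"):
            raise ParameterError(f"unknown label mode {self.label_mode!r}")
        if np.any(np.asarray(self.spacing) <= 0):
            raise ParameterError("voxel spacings must be positive")
        if self.shell_width is not None and self.shell_width <= 0:
            raise ParameterError("shell width must be positive")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise ParameterError(f"unknown noise model {self.noise!r}")

    @property
    def effective_shell_width(self) -> float:
        return self.shell_width if self.shell_width is not None else 2.0 * min(
            self.spacing[1], self.spacing[2]
        )


def render_image(shape: GroundTruthShape, cfg: RenderConfig) -> VolumetricImage:
    """Render a droplet shape into a noisy or noiseless 3-D stack.

    The signed radial distance ρ(x) = |x − c| − R(direction) drives the
    intensity: a Gaussian ridge exp(−ρ²/2w²) for surface labels, the
    attenuated sigmoid (plateau + slope·ρ)/(1 + exp(aρ)) + baseline for
    interior labels.  Along any ray through the center the intensity is
    therefore exactly the corresponding 1-D edge model with the edge at the
    true surface.
    """
    spacing = np.asarray(cfg.spacing, dtype=float)
    r_max = shape.max_radius
    pad = cfg.margin + 3.0 * cfg.effective_shell_width
    if cfg.extent_voxels is None:
        n_vox = np.ceil(2.0 * (r_max + pad) / spacing).astype(int) + 1
    else:
        n_vox = np.asarray(cfg.extent_voxels, dtype=int)
        if np.any(n_vox * spacing < 2.0 * (r_max + cfg.margin)):
            raise ParameterError(
                f"image extent {(n_vox * spacing)} μm cannot contain the shape "
                f"(needs {2 * (r_max + cfg.margin):.1f} μm per axis)"
            )
    center = (n_vox - 1) * spacing / 2.0

    data = np.empty(tuple(n_vox))
    j = np.arange(n_vox[1]) * spacing[1] - center[1]
    k = np.arange(n_vox[2]) * spacing[2] - center[2]
    jj, kk = np.meshgrid(j, k, indexing="ij")
    for i in range(n_vox[0]):
        z = i * spacing[0] - center[0]
        rel = np.column_stack(
            (np.full(jj.size, z), jj.ravel(), kk.ravel())
        )
        r = np.linalg.norm(rel, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dirs = np.where(r[:, None] > 0, rel / np.maximum(r, 1e-300)[:, None], [[1.0, 0, 0]])
        rho = r - shape.radial_function(dirs)
        data[i] = _profile(rho, cfg).reshape(jj.shape)

    if cfg.noise == "gaussian":
        rng = np.random.default_rng(cfg.seed)
        data = data + rng.normal(0.0, cfg.noise_magnitude * cfg.plateau, data.shape)
    elif cfg.noise == "poisson":
        rng = np.random.default_rng(cfg.seed)
        counts = np.clip(data, 0.0, None) * cfg.noise_magnitude
        data = rng.poisson(counts) / max(cfg.noise_magnitude, 1e-12)

    meta = {
        "label_mode": cfg.label_mode,
        "seed": cfg.seed,
        "center_um": center,
        "shape_kind": shape.kind,
        "ground_truth": _shape_meta(shape, center),
    }
    return VolumetricImage(data=data, spacing=spacing, metadata=meta)


def _profile(rho: np.ndarray, cfg: RenderConfig) -> np.ndarray:
    if cfg.label_mode == "surface":
        w = cfg.effective_shell_width / 2.0
        return cfg.plateau * np.exp(-(rho**2) / (2.0 * w**2)) + cfg.baseline
    arg = np.clip(cfg.edge_steepness * rho, -60.0, 60.0)
    return (cfg.plateau + cfg.attenuation_slope * rho) / (1.0 + np.exp(arg)) + cfg.baseline


def _shape_meta(shape: GroundTruthShape, center: np.ndarray) -> dict:
    meta = {
        "kind": shape.kind,
        "center_um": center + shape.center,
        "max_degree": shape.max_degree,
        "cartesian_coeffs": shape.coeffs,
    }
    if shape.radius is not None:
        meta["radius_um"] = shape.radius
    if shape.semiaxes is not None:
        meta["semiaxes_um"] = shape.semiaxes
        meta["axes"] = shape.axes
    if shape.radial_coeffs is not None:
        meta["radial_coeffs"] = shape.radial_coeffs
    return meta


# -- time-lapses ----------------------------------------------------------

def rotating_ellipsoid_schedule(
    semiaxes: Sequence[float],
    increment_deg: float,
    rotation_axis: Sequence[float] = (1.0, 0.0, 0.0),
) -> Callable[[int], GroundTruthShape]:
    """Ellipsoid whose principal frame rotates by a fixed step per frame."""
    axis = np.asarray(rotation_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    def schedule(i: int) -> GroundTruthShape:
        ang = np.deg2rad(increment_deg * i)
        K = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        Rm = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        axes = (Rm @ np.eye(3)).T  # rows: rotated lab axes
        return make_shape("ellipsoid", semiaxes=semiaxes, axes=axes)

    return schedule


def breathing_mode_schedule(
    radius: float, l: int, m: int, amplitude: float, period_frames: int  # noqa: E741
) -> Callable[[int], GroundTruthShape]:
    """Volume-preserving single-mode oscillation (amplitude in μm, peak)."""

    def schedule(i: int) -> GroundTruthShape:
        a = amplitude * np.sin(2.0 * np.pi * i / period_frames)
        return make_shape("harmonic", radius=radius, modes=[(l, m, a)])

    return schedule


def make_timelapse(
    shape0: GroundTruthShape,
    n_frames: int,
    perturbation_schedule: Optional[Callable[[int], GroundTruthShape]] = None,
    seed: int = 0,
    cfg: Optional[RenderConfig] = None,
    frame_interval: float = 3.0,
) -> tuple[list[VolumetricImage], list[GroundTruthShape], np.ndarray]:
    """Render a droplet time-lapse with per-frame ground truth.

    A ``None`` schedule repeats ``shape0``; otherwise the schedule maps the
    frame index to a shape.  Returns (images, shapes, times) with times in
    minutes at the given frame interval (default 3 min, the cadence of the
    60-min acquisitions this emulates).
    """
    if n_frames < 1:
        raise ParameterError(f"n_frames must be >= 1, got {n_frames}")
    cfg = cfg if cfg is not None else RenderConfig()
    images, shapes = [], []
    times = frame_interval * np.arange(n_frames)
    for i in range(n_frames):
        shape = shape0 if perturbation_schedule is None else perturbation_schedule(i)
        frame_cfg = replace(cfg, seed=cfg.seed + i if cfg.noise != "none" else cfg.seed)
        img = render_image(shape, frame_cfg)
        img.timestamp = float(times[i])
        images.append(img)
        shapes.append(shape)
    return images, shapes, times


# -- node-valued stress fixtures ------------------------------------------

def make_stress_fixture(
    node_sampling: SphereQuadrature,
    pattern: str,
    params: Optional[dict] = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Scalar field on quadrature nodes with known structure.

    Patterns
    --------
    ``dipole``
        f ∝ cos(polar): exactly one maximum (north) and one minimum (south).
    ``single-harmonic``
        One real harmonic Z_{l,m} of given amplitude.
    ``band-limited-random``
        Independent N(0,1) coefficients for degrees in [l_min, l_max]; the
        expected normalized autocorrelation over angular separation ψ is
        Σ_l (2l+1) P_l(cos ψ) / Σ_l (2l+1), whose 1/e crossing is returned
        as ``correlation_scale_rad``.

    The area-weighted mean is removed in all cases.  Returns (field, info).
    """
    params = dict(params or {})
    v, u = node_sampling.polar, node_sampling.azimuth
    info: dict = {"pattern": pattern, "seed": seed}
    if pattern == "dipole":
        amp = float(params.get("amplitude", 1.0))
        axis = np.asarray(params.get("axis", (1.0, 1.0, 1.0)), dtype=float)
        axis = axis / np.linalg.norm(axis)
        # cosine of the angle to the dipole axis; the default axis is tilted
        # off the sampling grid so no node ring is exactly iso-valued
        f = amp * (node_sampling.directions @ axis)
        info.update(axis=axis.tolist())
    elif pattern == "single-harmonic":
        l = int(params.get("l", 3))  # noqa: E741
        m = int(params.get("m", 2))
        amp = float(params.get("amplitude", 1.0))
        (B,) = real_sh_basis(l, v, u)
        f = amp * B[:, basis_index(l, m)]
        info.update(l=l, m=m, amplitude=amp)
    elif pattern == "band-limited-random":
        l_min = int(params.get("l_min", 4))
        l_max = int(params.get("l_max", 8))
        if l_min < 1 or l_max < l_min:
            raise ParameterError("need 1 <= l_min <= l_max")
        rng = np.random.default_rng(seed)
        coeffs = np.zeros(n_basis(l_max))
        for l in range(l_min, l_max + 1):  # noqa: E741
            for m in range(-l, l + 1):
                coeffs[basis_index(l, m)] = rng.normal()
        (B,) = real_sh_basis(l_max, v, u)
        f = B @ coeffs
        info.update(
            l_min=l_min, l_max=l_max,
            correlation_scale_rad=_band_limited_corr_scale(l_min, l_max),
        )
    else:
        raise ParameterError(f"unknown fixture pattern {pattern!r}")
    f = f - node_sampling.integrate(f) / (4.0 * np.pi)
    return f, info


def _band_limited_corr_scale(l_min: int, l_max: int, threshold: float = np.exp(-1)) -> float:
    """1/e crossing of the expected autocorrelation of the random fixture."""
    psi = np.linspace(0.0, np.pi, 4096)
    ls = np.arange(l_min, l_max + 1)
    num = sum((2 * l + 1) * eval_legendre(l, np.cos(psi)) for l in ls)
    corr = num / num[0]
    below = np.nonzero(corr < threshold)[0]
    i = below[0]
    # linear interpolation between bracketing samples
    c0, c1 = corr[i - 1], corr[i]
    return float(psi[i - 1] + (c0 - threshold) / (c0 - c1) * (psi[i] - psi[i - 1]))
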