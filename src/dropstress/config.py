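"""Analysis configuration: every tunable decision with its default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ParameterError


@dataclass
class AnalysisConfig:
    """Parameters of the per-frame droplet stress analysis.

    Units: lengths μm, interfacial tension mN/m, stresses kPa, times min.
    """

    # physics
    gamma: float = 3.3                 # interfacial tension γ (mN/m)
    delta_gamma: float = 0.165         # uncertainty δγ (mN/m); 5% of γ
    alpha: float = 0.05                # percentile cut for Δσ amplitudes
    # surface representation
    harmonic_degree: int = 20          # L of the global fit
    quadrature_degree: int = 131       # sphere-rule exactness degree
    # reconstruction
    label_mode: str = "interior"       # "interior" | "surface"
    n_rays: int = 2562                 # first-pass ray directions
    refine_iterations: int = 1         # normal-refinement passes
    residual_threshold: float = 0.5    # edge-fit relative residual gate
    provisional_degree: int = 10       # degree of the normals fit
    refine_half_window: float = 5.0    # μm each side of a point
    mls: bool = True
    mls_radius: Optional[float] = None # μm; None → 10% of mean radius
    mls_degree: int = 2
    interpolation_order: int = 3       # image spline order for ray sampling
    rescale_isotropic: Optional[float] = None  # μm; resample voxels if set
    # QC
    epsilon_threshold: float = 0.01    # Gauss-Bonnet gate on ε
    # stress details
    area_weighted_percentiles: bool = True
    drop_small_offset: bool = True     # drop H0 − H_e0 when relatively tiny
    # spatial structure
    compute_extrema: bool = True
    neighbor_ring: int = 6             # geodesic graph k-ring
    compute_spatial_correlation: bool = False
    spatial_ell_fraction: float = 0.05
    spatial_bins: int = 50
    # anatomy
    axis_frame: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )                                   # rows ê_AP, ê_ML, ê_DV

    def __post_init__(self) -> None:
        self.axis_frame = np.asarray(self.axis_frame, dtype=float)
        if self.gamma <= 0:
            raise ParameterError("gamma must be positive")
        if not 0 <= self.alpha < 0.5:
            raise ParameterError("alpha must lie in [0, 0.5)")
        if self.label_mode not in ("interior", "surface"):
            raise ParameterError(f"unknown label mode {self.label_mode!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["axis_frame"] = self.axis_frame.tolist()
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
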