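"""Volumetric image container and TIFF/JSON I/O.

Images are 3-D intensity grids with per-axis voxel spacing in μm.  World
coordinates use the same axis order as the array (axis 0 = stack/z), so a
voxel at index ``(i, j, k)`` sits at ``(i*s0, j*s1, k*s2)`` μm.  Multi-page
TIFF carries the pixels; voxel spacing, units and any ground-truth metadata
travel in a JSON sidecar because TIFF resolution tags are unreliable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from scipy.ndimage import map_coordinates, spline_filter

from .errors import ParameterError


@dataclass
class VolumetricImage:
    """A 3-D fluorescence stack of a single droplet."""

    data: np.ndarray            # (n0, n1, n2) intensities
    spacing: np.ndarray         # (3,) μm per axis
    timestamp: Optional[float] = None   # minutes
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ParameterError("image data must be a non-empty 3-D array")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ParameterError("spacing must be 3 positive values (μm)")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("image intensities must be finite")

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid per axis (μm)."""
        return self.spacing * np.asarray(self.data.shape)

    def sample(self, points: np.ndarray, order: int = 3) -> np.ndarray:
        """Interpolated intensities at world points (N, 3) μm.

        Cubic-spline interpolation by default (the spline coefficients are
        prefiltered once and cached); ``order=1`` gives plain trilinear.
        Points outside the grid return 0 (used to pad ray windows).
        """
        pts = np.atleast_2d(points) / self.spacing
        if order <= 1:
            return map_coordinates(self.data, pts.T, order=1,
                                   mode="constant", cval=0.0)
        key = f"_spline_coeffs_{order}"
        coeffs = getattr(self, key, None)
        if coeffs is None:
            coeffs = spline_filter(self.data, order=order)
            object.__setattr__(self, key, coeffs)
        return map_coordinates(coeffs, pts.T, order=order, prefilter=False,
                               mode="constant", cval=0.0)

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(points)
        lo = pts >= margin
        hi = pts <= (self.extent - self.spacing - margin)
        return np.all(lo & hi, axis=1)

    # -- I/O --------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF plus a ``.json`` sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.float32))
        sidecar = {
            "spacing_um": self.spacing.tolist(),
            "timestamp_min": self.timestamp,
            "units": "um",
            **_jsonable(self.metadata),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(
        cls, path: str | Path, spacing: Optional[np.ndarray] = None
    ) -> "VolumetricImage":
        """Read a TIFF; spacing comes from the sidecar unless overridden."""
        path = Path(path)
        data = tifffile.imread(path)
        sidecar_path = path.with_suffix(".json")
        meta: dict = {}
        ts = None
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            ts = meta.get("timestamp_min")
            if spacing is None:
                spacing = meta.get("spacing_um")
        if spacing is None:
            raise ParameterError(
                f"no voxel spacing: {sidecar_path.name} missing and no override given"
            )
        return cls(data=data, spacing=np.asarray(spacing, float), timestamp=ts,
                   metadata=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
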