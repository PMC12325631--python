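"""Export helpers: point clouds, node meshes with fields, result tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .meshgeo import NodeMesh
from .reconstruction import SurfacePointCloud
from .surface import HarmonicSurface


def pointcloud_to_csv(cloud: SurfacePointCloud, path: str | Path) -> None:
    """x, y, z, nx, ny, nz, pass, residual table (μm)."""
    n = cloud.normals if cloud.normals is not None else np.full_like(cloud.points, np.nan)
    df = pd.DataFrame({
        "x": cloud.points[:, 0], "y": cloud.points[:, 1], "z": cloud.points[:, 2],
        "nx": n[:, 0], "ny": n[:, 1], "nz": n[:, 2],
        "pass": cloud.provenance, "residual": cloud.residuals,
    })
    df.to_csv(path, index=False)


def pointcloud_to_ply(cloud: SurfacePointCloud, path: str | Path) -> None:
    """ASCII PLY with per-vertex normals."""
    n = cloud.normals if cloud.normals is not None else np.zeros_like(cloud.points)
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(cloud)}",
        "property float x", "property float y", "property float z",
        "property float nx", "property float ny", "property float nz",
        "end_header",
    ]
    for p, nv in zip(cloud.points, n):
        lines.append(" ".join(f"{v:.6f}" for v in (*p, *nv)))
    Path(path).write_text("\n".join(lines) + "\n")


def mesh_to_ply(mesh: NodeMesh, path: str | Path, fields: dict | None = None) -> None:
    """ASCII PLY of the triangulated node surface with scalar fields."""
    fields = fields or {}
    names = list(fields)
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float x", "property float y", "property float z",
        *[f"property float {nm}" for nm in names],
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    cols = [mesh.vertices] + [np.asarray(fields[nm])[:, None] for nm in names]
    for row in np.hstack(cols):
        lines.append(" ".join(f"{v:.6f}" for v in row))
    for f in mesh.faces:
        lines.append("3 " + " ".join(str(int(i)) for i in f))
    Path(path).write_text("\n".join(lines) + "\n")


def node_table_to_csv(mesh: NodeMesh, fields: dict, path: str | Path) -> None:
    df = pd.DataFrame({
        "x": mesh.vertices[:, 0], "y": mesh.vertices[:, 1], "z": mesh.vertices[:, 2],
        **{k: np.asarray(v) for k, v in fields.items()},
    })
    df.to_csv(path, index=False)


def surface_to_json(surface: HarmonicSurface, path: str | Path) -> None:
    """Harmonic coefficients with chart metadata."""
    Path(path).write_text(json.dumps({
        "degree": surface.L,
        "center_um": surface.center.tolist(),
        "coefficients_xyz": surface.coeffs.tolist(),
        "fit_rms_um": surface.fit_rms,
        "chart": "polar [0, pi], azimuth [0, 2pi), central projection",
    }, indent=2))


def surface_from_json(path: str | Path) -> HarmonicSurface:
    d = json.loads(Path(path).read_text())
    return HarmonicSurface(
        coeffs=np.asarray(d["coefficients_xyz"]),
        center=np.asarray(d["center_um"]),
        L=int(d["degree"]),
        fit_rms=float(d.get("fit_rms_um", 0.0)),
    )
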