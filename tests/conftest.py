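"""Shared fixtures: quadratures, rendered droplet stacks, reconstructions.

Expensive objects (rendered images, full reconstructions) are
session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from dropstress import (
    RenderConfig,
    SphereQuadrature,
    make_shape,
    reconstruct_pointcloud,
    render_image,
)

ISO_VOXEL = (0.5, 0.5, 0.5)   # recommended sampling: voxel < R/10


@pytest.fixture(scope="session")
def quad41() -> SphereQuadrature:
    """882-node rule, exact through degree 41 (inner products to 20)."""
    return SphereQuadrature.gauss_product(41)


@pytest.fixture(scope="session")
def quad95() -> SphereQuadrature:
    """4608-node rule for resolution-sensitive geometry checks."""
    return SphereQuadrature.gauss_product(95)


@pytest.fixture(scope="session")
def quad131() -> SphereQuadrature:
    """8712-node rule matching degree-65 inner-product exactness."""
    return SphereQuadrature.gauss_product(131)


@pytest.fixture(scope="session")
def sphere8_image():
    """Noiseless interior-labeled sphere, R = 8 μm, isotropic 0.5 μm voxels."""
    shape = make_shape("sphere", radius=8.0)
    img = render_image(shape, RenderConfig(label_mode="interior", spacing=ISO_VOXEL))
    return img, shape


@pytest.fixture(scope="session")
def sphere8_cloud(sphere8_image):
    img, shape = sphere8_image
    return reconstruct_pointcloud(img, "interior", n_rays=642), img, shape


@pytest.fixture(scope="session")
def sphere_cloud_exact():
    """Noise-free points exactly on a sphere (R = 10 μm), with chart angles."""
    rng = np.random.default_rng(42)
    polar = np.arccos(rng.uniform(-1.0, 1.0, 1500))
    azimuth = rng.uniform(0.0, 2.0 * np.pi, 1500)
    shape = make_shape("sphere", radius=10.0)
    return shape.point(polar, azimuth), polar, azimuth
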