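"""Render a synthetic droplet image and recover its surface point cloud.

A fluorescent oil droplet (interior label) of radius 10 μm is rendered
into an isotropic 0.5 μm stack; the reconstruction traces rays from the
segmented centroid, fits the attenuated-sigmoid edge model per ray, and
refines along surface normals.
"""

import numpy as np

from dropstress import RenderConfig, make_shape, reconstruct_pointcloud, render_image

shape = make_shape("sphere", radius=10.0)
image = render_image(shape, RenderConfig(label_mode="interior",
                                         spacing=(0.5, 0.5, 0.5)))
cloud = reconstruct_pointcloud(image, "interior", n_rays=642)

center = np.asarray(image.metadata["center_um"])
r = np.linalg.norm(cloud.points - center, axis=1)
print(f"{len(cloud)} surface points")
print(f"median radius       : {np.median(r):.4f} um (truth 10.0000)")
print(f"median radial error : {100 * np.median(np.abs(r - 10) / 10):.4f} %")
# The error is the sub-voxel localization accuracy of the edge fits:
# a small fraction of a percent on noiseless data.
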