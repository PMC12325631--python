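"""Mean curvature, volume and the Gauss-Bonnet quality metric.

The (3, 5, 7) μm ellipsoid has a closed-form volume of 140π μm³ and known
mean-curvature extremes; both are reproduced by the spherical-harmonic
representation with exact sphere quadrature.
"""

import numpy as np

from dropstress import (
    HarmonicSurface,
    SphereQuadrature,
    curvatures,
    make_shape,
    volume_from_radius,
)

shape = make_shape("ellipsoid", semiaxes=(3.0, 5.0, 7.0))
surface = HarmonicSurface(coeffs=shape.coeffs, center=shape.center, L=1)
quad = SphereQuadrature.gauss_product(131)   # exact to degree 131

curv = curvatures(surface, quad)
V_radial = volume_from_radius(shape.radial_function(quad.directions), quad)

print(f"volume (radial quadrature): {V_radial / np.pi:.10f} pi um^3 (truth 140)")
print(f"volume (surface integral) : {curv.volume / np.pi:.10f} pi um^3")
print(f"H range: {curv.H.min():.5f} .. {curv.H.max():.5f} 1/um "
      "(closed form 0.09061 .. 0.52889)")
print(f"Gauss-Bonnet error eps    : {curv.epsilon:.2e} (QC gate at 0.01)")
# eps measures |1 - integral(K dA)/4pi|: near machine precision for a
# faithful closed surface, large for corrupted reconstructions.
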