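# Methods

This note documents the models, numerical choices and limitations of
`dropstress`. Units throughout: lengths μm, interfacial tension γ mN/m,
curvature 1/μm, stress kPa (2γH: mN/m × μm⁻¹ = kPa), time min.

## Image formation and the synthetic generator

The generator renders a star-shaped droplet surface R(Ω) about a center
into a voxel grid through the signed radial distance ρ(x) = |x − c| −
R(x̂). Two labeling geometries are emulated:

* **surface label** — a Gaussian ridge exp(−ρ²/2w²) + baseline, with
  shell width 2× the in-plane voxel spacing by default (a PSF-limited
  ring);
* **interior label** — the attenuated sigmoid
  (d + cρ)/(1 + exp(aρ)) + e: a bright plateau d + e inside, a sharp drop
  of steepness a (default 4 μm⁻¹) at the interface, a mild linear
  attenuation c (default 0.01 μm⁻¹) inside, background e.

Because intensity depends on position only through ρ, the profile along
any centered ray is *exactly* the 1-D edge model fitted during
reconstruction, with the edge parameter b at the true surface — a
zero-residual fit is achievable on noiseless renders, which pins the
generator and the reconstruction to the same analytic family. Noise
(Gaussian or Poisson, seeded) is optional and off by default; tests that
need it state the magnitude.

Default render geometry mirrors typical droplet acquisitions (in-plane
0.346 μm, axial 4 μm); accuracy tests use the recommended near-isotropic
regime (voxel < R/10, typically 0.5 μm for R = 16 μm). Ground truth
(shape kind, coefficients, center, seed, units) accompanies every image
as a JSON sidecar.

What the generator does **not** emulate: PSF convolution and optical
anisotropy, spectral bleed-through, multi-droplet scenes, or a
cell-membrane channel. Passing tests therefore demonstrate correctness
of the geometry/stress machinery and the sub-voxel localization scheme,
not robustness to real optical artifacts.

Shape amplitudes are *peak* radial deviations: a "degree-3 mode of
amplitude 0.5 μm" deviates by exactly 0.5 μm at its antinode (each
harmonic is rescaled by its global maximum).

## Reconstruction

1. **Segmentation.** Otsu threshold, largest connected component (an
   image with zero or several large components is an error naming the
   count), hole filling, marching cubes, 10 Laplacian smoothing passes;
   the labeled region's centroid seeds the rays.
2. **Radial pass.** Rays from the centroid through the vertices of a
   subdivided icosahedron (2562 directions by default) sample intensity
   at half the smallest voxel spacing, via *cubic-spline* interpolation
   of the stack (the spline coefficients are prefiltered once per
   image). Trilinear sampling is available but leaves a deterministic
   sub-voxel ripple (~3×10⁻³ μm on the standard fixture) that the
   degree-20 harmonic fit amplifies into a ~0.7% curvature error; cubic
   interpolation halves it.
3. **Edge fits.** Levenberg-Marquardt per ray. Initialization: b at the
   extreme-gradient (sigmoid) or maximum (Gaussian) sample, steepness
   from the sampling step, plateau/background from profile quartile
   medians. A fit is accepted when the optimizer converges, b lies in
   the sampled window, and the relative RMS residual is < 0.5
   (configurable); rejected rays contribute no point and are counted.
4. **Normal refinement.** A provisional degree-10 harmonic fit supplies
   outward normals; each point is retraced ±5 μm along its normal and
   refit (1 iteration by default, configurable). More than 50% failed
   refits aborts — in practice this means the wrong edge model was
   chosen for the label mode.
5. **MLS smoothing.** Degree-2 Monge patch per point in the frame of its
   normal; search radius 10% of the mean radius, floored at 2.5 mean
   point spacings so sparse clouds still fill their patches. The patch
   also yields a local mean-curvature diagnostic (sphere-positive).

## Surface representation and geometry

Each Cartesian component of the surface is a real spherical-harmonic
series up to degree L (default 20) on a (polar, azimuth) chart assigned
by central projection from the cloud centroid. The fit is plain linear
least squares per component, with the degree capped so that coefficients
per component ≤ N/2 (at least two data points per degree of freedom).
An ellipsoid is exactly degree-1 *in its parametric chart* but not in
central-projection angles; `fit_harmonics` accepts explicit chart angles
for such cases. Radial-harmonic shapes (sphere + radial modes — the
fixtures used for accuracy claims) are exactly band-limited in the
central-projection chart.

Curvatures come from the first and second fundamental forms with
analytically differentiated basis functions (no finite differences); the
sign convention makes H = +1/R for a sphere with outward normals.
Degenerate metric points raise an error naming the nodes; chart poles
are avoided by construction (the quadrature excludes them) and nudged by
10⁻⁶ rad when arbitrary directions are evaluated.

**Quadrature.** Surface integrals use a Gauss-Legendre (polar) ×
trapezoidal (azimuth) product rule on the sphere, exact for
spherical-harmonic integrands up to a configurable degree (default 131,
i.e. inner products of degree-65 harmonics; 66 × 132 = 8712 nodes). The
weights are generated at run time — no tables are shipped — and sum to
4π to 10⁻¹⁵. Volume uses the divergence identity V = ⅓∮(x − c)·n̂ dA
(equal to the radial form ∮R³/3 dΩ for star-shaped surfaces, which is
also provided); the Gauss-Bonnet error ε = |1 − ∫K dA/4π| is the
per-frame QC metric with gate ε > 0.01, and sits at 10⁻¹⁵–10⁻¹¹ for
faithful reconstructions.

## Stresses

* σ^A = 2γ(H − H0) with H0 the area-weighted mean curvature (plain node
  averaging is biased and only exposed for comparison).
* Ellipsoid mode by least-squares quadric fit; principal frame from the
  eigendecomposition, semiaxes sorted a ≥ b ≥ c, eigenvector signs fixed
  deterministically (largest component positive). σ^A_T from the closed
  form; the nodal σ^A_T map evaluates the closed-form H_e at the
  ellipsoid point radially corresponding to each node about the common
  center, minus the area-weighted H_e0 (computed by running the exact
  degree-1 ellipsoid surface through the same curvature machinery).
* σ^A_C = σ^A − σ^A_T. The offset H0 − H_e0 is retained unless
  |H0 − H_e0|/H0 < 10⁻³, in which case it is dropped (the conventional
  approximation); `decompose_stress` keeps it exact so the decomposition
  identity holds nodewise to rounding.
* σ^A_TT evaluates the droplet's own H where the principal axes cross
  the surface (direct surface evaluation, both crossings averaged), not
  at nearest nodes.
* Percentile amplitudes default to area-weighted quantiles (quadrature
  nodes are not area-uniform); unweighted per-node percentiles are kept
  as an option for strict parity with node statistics.
* Mode spectra project a nodal residual onto the orthonormal real basis
  by quadrature (error if Lmax exceeds half the exactness degree), and
  combine ±m amplitudes in quadrature; Parseval holds to 10⁻⁸ for
  band-limited fields.
* Error propagation: (δσ^A)² = (2(H−H0)δγ)² + (2γδH)²; the relative
  bound √((δγ/γ)² + (δH/(H−H0))²) is reported as NaN where H = H0.

## Extrema, geodesics, correlations

Nodes are triangulated by the spherical Delaunay triangulation (convex
hull of directions), with vertices at the droplet surface positions.
Extrema are nodes ≥ (≤) all one-ring neighbors; plateau ties are
reported per node and flagged degenerate. Adjacent pairing assigns each
extremum its geodesically closest opposite extremum (ties → smaller
index).

Geodesic distances are shortest paths on the triangulation graph
augmented with k-ring edges (default k = 6) whose weights carry the
circular-arc correction ψ/(2 sin(ψ/2)) from the normal turning angle ψ —
exact on spheres, second-order on smooth surfaces. Against great-circle
truth on a sphere this is accurate to ~10⁻⁴ median and ≲2% worst case;
the residual error is direction quantization, which is nearly
scale-invariant in the node count. An exact polyhedral shortest-path
algorithm would remove it; none is available in the dependency set.

Spatial autocorrelation bins node-pair products over geodesic
separation with the bump kernel w(s) = exp(1 − 1/(ℓ² − s²)) for s < ℓ,
ℓ = 5% of the geodesic diameter (curves are stable under halving ℓ;
widths below the node spacing only add noise and warn). The curve is
normalized to C(0) = 1. Temporal autocorrelation compares fields at the
same node directions (radial parameterization) across frames, averaged
over all start times and normalized by the zero-lag term; no mean is
subtracted (stress fields are zero-mean by construction), and rejected
frames remain as gaps in the lag structure rather than being re-indexed.

## Pipeline defaults and problem sizes

γ = 3.3 mN/m with δγ = 5%, α = 0.05, L = 20, quadrature degree 131,
2562 rays, one refinement pass, ε gate 0.01. The identity lab frame
stands in for the AP/ML/DV axes unless provided. Spatial correlation of
every frame is off by default (it needs the all-pairs geodesic matrix,
the one quadratic-cost step); enable `compute_spatial_correlation` with
a moderate quadrature degree when curves per frame are wanted. The test
suite exercises reduced sizes (R = 8 μm droplets, 642 rays, degree-41
quadrature) for speed, and full-size fixtures (R = 16 μm, 2562 rays,
degree-131 quadrature) where the published error bounds are asserted:
point localization ≤ 1.2% (measured ~0.003%), mean curvature ≤ 0.5%
(measured ~0.4%), deformed-droplet point ≤ 2% and curvature ≤ 10%
(measured ~0.007% / ~0.6%).

## Known limitations

* Surfaces must be star-shaped about the droplet center (genus 0, global
  chart); partial reconstructions and non-spherical topology are out of
  scope.
* The percentile convention (area-weighted vs per-node) changes Δσ^A at
  the fraction-of-a-percent level on anisotropic node sets; both are
  exposed.
* Geodesics carry a ≲2% worst-case metrication error (see above).
* The renderer's idealized optics mean reconstruction-accuracy numbers
  are upper bounds on what identical settings achieve on real stacks.
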