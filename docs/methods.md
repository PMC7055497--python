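# Methods

This note documents the models, conventions, parameter choices and known
limitations of `cardiofiber`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Conventions

Volumes are indexed `(z, y, x)`, 0-based, voxel centers at integer
coordinates, with one isotropic voxel size in μm (anisotropic metadata is
rejected, since every formula below assumes a single pixel scale).
Direction vectors carry `(x, y, z)` components. Orientations are axial
(±v equivalent); the canonical representative has nonnegative z
component, ties broken toward +y, then +x.

## Sliding-window Fourier analysis

Each cubic probing window (edge `l`, default 48 voxels, stride 10) is
mean-subtracted, tapered, transformed, and its power spectrum reduced to
the intensity-weighted second-moment matrix of spatial frequency over the
band `q_min ≤ |q| ≤ q_max` (defaults 0.02–0.45 cycles/voxel).

*Window.* The taper is the separable product of identical 1-D
Kaiser–Bessel profiles, sampled in the DFT-even (periodic) convention:
exactly 1 at the center voxel `l/2` and `1/I0(β)` at the first sample.
β defaults to 8, a ≈ −60 dB sidelobe level, which keeps window leakage
far below the structural signal. A radial interpretation of the taper is
not usable — it would peak at the cube faces and be undefined at the
corners — so the separable form is the package's definition.

*Mean subtraction and DC removal.* Both are applied before the moment
computation; otherwise the normalization `∫I dq` would depend on an
arbitrary intensity offset. As a consequence, orientations are invariant
under adding a constant to the volume (asserted in tests).

*Eigen-analysis.* `numpy.linalg.eigh` on the symmetric 3×3 moment
matrix; eigenvalues descending; tiny negative λ3 from roundoff on
positive-semidefinite inputs is clamped to 0. Signs of b1 and b2 are
fixed by making each vector's largest-magnitude component positive;
b3 = b1 × b2 keeps the basis right-handed. Eigenvalue pairs within 5%
(relative to λ1) are flagged degenerate.

*Anisotropy.* Two eigenvalue-dispersion measures are exposed. The
fractional anisotropy ω uses the square-root form (0 sphere, 1 rod); its
trace form ½[3 − 1/tr(R²)] equals ω² and is exposed as `fa_squared`. The
reciprocal anisotropy Ω applies the dispersion to the inverse
eigenvalues; here the **trace form is canonical** because only it attains
the limits 0 (sphere), 1 (disk), 0.5 (rod) — the square-root variant
gives √0.5 ≈ 0.707 in the rod limit and is available behind
`form="sqrt"` for comparison. Ω is the alignment score used for
validity gating (default floor 0.05) because well-aligned fibers produce
disk-shaped spectra. A zero eigenvalue makes the reciprocal undefined;
such windows are flagged invalid rather than raising.

*Fiber distance.* The signal curve is the mean spectral intensity in
spherical shells (default width 1/l cycles/voxel; any finer width may be
configured — the acceptance runs use 0.002 on 128³ grids, where the 3-D
frequency lattice is dense enough to populate such shells). The
background curve is the same shell average restricted to a double cone
(default half-angle 15°) around the fiber axis, where periodic inter-fiber
structure contributes no peak; empty cone shells are interpolated from
neighbors. The ratio signal/background is maximized over the configured
q band, refined to sub-shell precision by a parabola through the three
shells around the argmax, and accepted only if the ratio exceeds 1.2
(`peak_threshold` 0.2); otherwise the window reports no distance. The
background is floored at 10⁻⁹ of the signal maximum before division: on
idealized phantoms the cone can be numerically zero and raw division
would amplify float noise into a spurious argmax; real tissue
backgrounds sit many orders above the floor. Distance = voxel_size /
q_peak.

*Tissue gating.* Windows whose fraction of voxels above
`tissue_threshold` falls below `min_tissue_fraction` (default 5%) are
skipped, so air/background regions produce no spurious vectors. The
volume is smoothed once with an isotropic Gaussian of σ = 1 voxel
(reflective boundaries, which conserve the mean on constant inputs)
before either analysis.

## Structure-tensor comparator

Gradients by central differences (one-sided at boundaries, via
`numpy.gradient`) on the same σ = 1 prefiltered volume; per window the
tensor of summed gradient products is eigen-analyzed with the same
operators, the orientation being the smallest-eigenvalue eigenvector
(least intensity change along the fiber). Window matching: the gradient
cube edge is `l_grad = l · m1(β)` with m1 the normalized mean of the
continuous 1-D Kaiser–Bessel profile by quadrature (m1(8) ≈ 0.436,
giving 20.9 for l = 48 — rounded to 21 by default; the rounding rule is
configurable and 20 is accepted by the tests, since the choice between
floor and round is not principled). ST windows are centered on the same
analysis grid as the Fourier windows so fields compare element-wise.
On fiber phantoms the two methods agree to well under a degree, while the
Fourier Ω is systematically lower than the gradient Ω — the
intensity-weighted moments emphasize low spatial frequencies — and the
tests assert only this sign, not a magnitude.

## Heart coordinate mapping

The frame is a point on the long axis, a unit long-axis direction and an
azimuth reference. It can be fitted as the centroid + principal axis of
the tissue mask's second moments (rejecting near-spherical masks, where
no axis exists) or given manually as base/apex points. At each window
center off the axis, the basis is radial / circumferential / longitudinal
(right-handed, `e_c = e_z × e_r`). With the axial representative chosen
to have nonnegative circumferential component, the helical angle ν is
`atan2(v·e_z, v·e_c)` and the transversal angle ψ is
`atan2(v·e_r, v·e_c)`, both in [−90°, 90°]. Purely longitudinal fibers
report ν = +90° with ψ flagged undefined; purely radial fibers the
converse. These sign conventions are fixed by this package; comparisons
with e.g. DTI helix-angle conventions may require a sign flip.

## Phase retrieval

The linearized transport-of-intensity forward model, the modified
Bronnikov inversion and the resharpening step share one Fourier Laplacian
convention (symbol −|q|², q in cycles/pixel) and a single
`propagation_factor` scalar that folds together wavelength, distance and
2π factors; users calibrating to hardware supply it directly. The
forward model multiplies the Laplacian term by this factor and the
inversion divides by it, so the pair is self-consistent by construction.
α regularizes the zero-frequency singularity; the retrieved phase's mean
is therefore meaningless and all closed-loop comparisons remove it.
The resharpening step is provided in two modes: the multiplicative form
(`as_printed`, the default in the CLI) and the divisive form used by the
closed-loop tests, because division by (1 − γ∇²φ) is what cancels the
linearized fringe factor to first order when γ matches the propagation
factor. The closed-loop tests operate in the method's design regime —
weakly absorbing homogeneous objects (absorption steps of order 0.01,
phase proportional to the absorption projection) — where the round trip
demonstrably reduces both the maximum edge deviation and the L2 distance
to the pure-absorption image on every seeded phantom; outside that
regime (strong absorbers) no such guarantee holds.

## Synthetic phantoms

The generators emulate the features of air-dried (solvent-evaporated)
heart preparations that the algorithms exploit — separated, locally
parallel muscle bundles with a characteristic spacing and strong
tissue/air contrast — not anatomy:

- **fibers**: parallel anti-aliased rods on a square lattice along an
  arbitrary axis (defaults: spacing 14 voxels, radius 3 voxels, matching
  the worked inter-fiber distance of 14 px at 5.3 μm/voxel);
- **lamellae**: a pure sinusoidal grating (the cleanest test of the
  spectral peak estimator);
- **tube**: a hollow cylinder whose wall (75 μm default) stands in for
  the polyimide mounting tube;
- **helical ring**: an annulus of rod texture whose direction at radius
  r is the circumferential direction tilted by a helical angle ν(r); the
  texture is a product of two sinusoidal modulations so its spectrum
  spans the plane perpendicular to the local fiber direction, as real
  bundles do.

Edges use a one-voxel distance-based ramp (hard edges would add
spectral ringing unrelated to the method under test). Noise is additive
Gaussian with σ given as a fraction of the foreground contrast, seeded;
generators are deterministic given the seed and embed their full
parameter set in the output metadata. What the phantoms do **not**
contain: multi-scale texture, intensity inhomogeneity, curvature beyond
the ring geometry, reconstruction artifacts (rings, streaks, beam
hardening), or correlated noise. Passing tests therefore demonstrate
correctness of the estimators under known geometry, not performance on
real scans. The helical ring also has a texture seam along one
azimuthal ray (the pattern phase is not periodic around the ring for
arbitrary ν profiles), which is why recovery tests use median statistics
per radial bin.

## Problem sizes and numerical choices

Test volumes are 48³–96³ with windows of 16–48 voxels, and the
acceptance computations use single 128³ windows with 0.002-wide shells —
sizes chosen so the full suite runs in well under a minute while keeping
≥ 9 periods of the structures of interest per window. Shell curves use
simple bin means; FSC excludes the DC shell and interpolates the
criterion crossing linearly; SNR uses the sample (n−1) standard
deviation; the FSC resolution criterion defaults to the fixed 0.5
threshold with the half-bit information criterion optional, and a curve
that never crosses reports a "better than Nyquist" sentinel rather than
a number.

## Known limitations

- Single dominant orientation per window; no multi-peak decomposition.
- The fiber-distance estimator reports one periodicity; nested scales
  (sarcomere vs bundle spacing) require external q-band masking.
- Near the long axis (radius ≲ 1 voxel) heart-frame angles are
  undefined; windows there are flagged, not extrapolated.
- The reciprocal anisotropy is undefined when an eigenvalue is exactly
  zero (ideal noise-free translational invariance); such windows are
  invalid by design, which on perfectly noiseless phantoms can gate out
  the structure-tensor method entirely.
- The phase-retrieval module handles parallel projections of the
  linearized TIE only; cone-beam effects and strong absorption are out
  of scope.
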