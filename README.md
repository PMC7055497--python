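# cardiofiber

Fiber orientation, alignment and spacing analysis for tomographic volumes
of heart tissue.

Cardiomyocyte chains wind around the ventricles in a transmurally varying
helical pattern, and resolving that three-dimensional architecture from
micro-CT reconstructions is a prerequisite for structural cardiology and
electromechanical heart models. `cardiofiber` extracts, per probing
subvolume of a reconstructed grayscale volume, the local fiber direction,
two scalar alignment scores, and the dominant inter-fiber distance. It is
aimed at users of laboratory or synchrotron propagation-based
phase-contrast micro-CT who want quantitative per-window vector fields
(e.g. for stream tracing or helical-angle maps) rather than renderings.

## Methods in brief

**Fourier method** (the primary analysis). Each cubic window of edge
`l` voxels is mean-subtracted, tapered by a separable 3-D Kaiser–Bessel
window

    w(x) = I0(β √(1 − ((x − l/2)/(l/2))²)) / I0(β),   β = 8, l = 48,

and transformed; the power spectrum `I(q)` is summarized by its
intensity-weighted second-moment matrix

    C_ij = ∫ I(q) q_i q_j dq / ∫ I(q) dq .

The eigenvalues λ1 ≥ λ2 ≥ λ3 of `C` describe the spectral ellipsoid:
aligned fibers concentrate power in the plane perpendicular to the fiber
axis, so the **fiber orientation is the eigenvector of λ3**. Two
anisotropy measures are derived: the fractional anisotropy

    ω = √( ((λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²) / (2(λ1²+λ2²+λ3²)) ),

which is 0 for a sphere and 1 for a rod, and a *reciprocal* anisotropy
Ω = ½[3 − 1/trace(R′²)] with R′ = D⁻¹/trace(D⁻¹), which scores the
disk-shaped spectra of well-aligned fibers as 1 (sphere 0, rod 0.5). The
dominant inter-fiber distance is `voxel_size / q_max`, where `q_max` is
the peak of the spherical-shell average of `I(q)` divided by a background
curve integrated over a cone around the fiber axis.

**Structure-tensor comparator.** The classical gradient method: the local
tensor `ST_ij = Σ g_i g_j` of intensity gradients over a window of edge
`l_grad = l·m1(β)` (matched window weight; ≈ 20 voxels for l = 48, β = 8)
is eigen-analyzed the same way.

**Heart coordinates.** Orientations are mapped to a cylindrical frame on
the ventricular long axis: helical angle ν (elevation out of the
short-axis plane, against the circumferential direction) and transversal
angle ψ (in-plane angle toward the radial direction).

**Phase retrieval.** A Bronnikov-aided correction front end for
propagation-based phase-contrast projections: flat-field correction, the
modified Bronnikov phase estimate
φ = (1/c)·F⁻¹[F[I−1]/(|q|²+α)], and Laplacian resharpening, plus a
linearized-TIE forward simulator for closed-loop validation.

Everything is validated on deterministic synthetic phantoms with known
ground truth (parallel fiber bundles, sinusoidal gratings, hollow tubes,
helical rings); no external data are required.

## Worked example

```python
import numpy as np
from cardiofiber import phantoms
from cardiofiber.fourier_fiber import analyze_volume
from cardiofiber.structure_tensor import structure_tensor_field, compare_fields
from cardiofiber.volume_io import AnalysisConfig

vol, truth = phantoms.fiber_phantom(
    (96, 96, 96), direction=(1, 1, 0), spacing=14, fiber_radius=3,
    voxel_size=5.3, noise_sigma=0.05, rng_seed=1)
config = AnalysisConfig(window_edge=48, stride=10, tissue_threshold=0.3)
ft = analyze_volume(vol, config)
st = structure_tensor_field(vol, config)
report = compare_fields(ft, st)

errs = np.degrees(np.arccos(np.clip(
    np.abs(ft.orientation[ft.valid] @ truth), -1, 1)))
print(f"valid windows:            {int(ft.valid.sum())} / {ft.valid.size}")
print(f"median orientation error: {np.median(errs):.2f} deg")
print(f"median FT-ST difference:  {report.median_angle:.2f} deg")
print(f"median anisotropy (FT):   {np.median(ft.omega_reciprocal[ft.valid]):.3f}")
print(f"median anisotropy (ST):   {np.median(st.omega_reciprocal[st.valid]):.3f}")
print(f"median fiber distance:    {np.nanmedian(ft.distance_um):.1f} um")
```

Output:

```
valid windows:            125 / 125
median orientation error: 0.03 deg
median FT-ST difference:  0.05 deg
median anisotropy (FT):   0.912
median anisotropy (ST):   0.997
median fiber distance:    74.7 um
```

Both methods recover the planted diagonal fiber direction essentially
exactly; the Fourier anisotropy is systematically lower than the gradient
one (low spatial frequencies carry most spectral weight), and the
recovered inter-fiber distance matches the planted 14-voxel rod lattice
at 5.3 μm/voxel (74.2 μm).

The same pipeline is available from the shell:

```bash
cardiofiber phantom --kind fibers --shape 96 96 96 --spacing 14 \
    --noise-sigma 0.05 --seed 1 --out phantom.h5
cardiofiber analyze --input phantom.h5 --method both --window 48 \
    --stride 10 --out-dir results/
cardiofiber angles --field results/field_ft.h5 --base 95 47.5 47.5 \
    --apex 0 47.5 47.5 --out-dir results/
```

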