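"""Sliding-window Fourier analysis of local fiber architecture.

For every cubic probing volume the method tapers the (mean-subtracted)
subvolume with a separable 3-D Kaiser–Bessel window, takes the power
spectrum, and summarizes it by the intensity-weighted second-moment matrix
of the spatial frequencies,

    C_ij = ∫ I(q) q_i q_j dq / ∫ I(q) dq .

A principal component analysis of C describes the spectral ellipsoid: well
aligned fibers concentrate power in the plane perpendicular to the fiber
axis, so the fiber orientation is the eigenvector of the *smallest*
eigenvalue.  Two scalar summaries are derived from the eigenvalues: the
fractional anisotropy ω (0 for a sphere, 1 for a rod) and a reciprocal
anisotropy Ω computed from the inverse eigenvalues, which is 0 for a
sphere, 1 for a disk (the well-aligned-fiber limit) and 0.5 for a rod.
A dominant inter-fiber distance is read off as 1/q of the peak of the
angular shell average of I(q), divided by a background curve integrated
over a cone around the fiber axis (where no peak occurs).

Direction vectors throughout carry (x, y, z) components while grids are
indexed (z, y, x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import kaiser

from cardiofiber.volume_io import AnalysisConfig, Volume3D, gaussian_prefilter

__all__ = [
    "KaiserBesselWindow", "SpectralCovariance", "EigenDecomposition",
    "OrientationResult", "DistancePeak", "FiberField",
    "kb_window", "windowed_power_spectrum", "spectral_covariance",
    "eigendecompose", "anisotropy_fa", "fa_squared", "reciprocal_anisotropy",
    "fiber_orientation", "radial_profile", "cone_background",
    "fiber_distance", "analyze_volume", "canonical_axial",
]


# --------------------------------------------------------------------------
# window
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KaiserBesselWindow:
    """Separable 3-D Kaiser–Bessel taper.

    ``profile`` is the 1-D window w(x) = I0(β·sqrt(1−((x−l/2)/(l/2))²))/I0(β)
    sampled at x = 0..l−1 (DFT-even convention: exactly 1 at x = l/2 for
    even l and 1/I0(β) at x = 0); ``weights`` is the outer product over the
    three axes.
    """

    edge: int
    beta: float
    profile: np.ndarray
    weights: np.ndarray

    @property
    def mean_weight(self) -> float:
        """Mean of the 1-D profile (used for window-size matching)."""
        return float(self.profile.mean())


def kb_window(l: int, beta: float) -> KaiserBesselWindow:
    """Build the separable 3-D Kaiser–Bessel window of edge ``l`` voxels."""
    if l < 8:
        raise ValueError(f"window edge must be >= 8 voxels, got {l}")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    profile = kaiser(l, beta, sym=False)
    weights = (profile[:, None, None] * profile[None, :, None]
               * profile[None, None, :])
    return KaiserBesselWindow(edge=int(l), beta=float(beta),
                              profile=profile, weights=weights)


# --------------------------------------------------------------------------
# spectrum and moments
# --------------------------------------------------------------------------

def _freq_grids(shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(qz, qy, qx) frequency grids in cycles/voxel, unshifted layout."""
    fz = np.fft.fftfreq(shape[0])
    fy = np.fft.fftfreq(shape[1])
    fx = np.fft.fftfreq(shape[2])
    return np.meshgrid(fz, fy, fx, indexing="ij")


def windowed_power_spectrum(sub: np.ndarray | Volume3D,
                            window: KaiserBesselWindow) -> np.ndarray:
    """Power spectrum of a tapered cubic subvolume.

    The cube mean is subtracted, the Kaiser–Bessel taper applied, and the
    squared modulus of the 3-D DFT returned on the unshifted frequency grid
    (cycles/voxel) with the zero-frequency bin set to 0.  A constant cube
    yields the all-zero spectrum, which downstream operations treat as
    invalid.
    """
    data = sub.data if isinstance(sub, Volume3D) else np.asarray(sub)
    l = window.edge
    if data.shape != (l, l, l):
        raise ValueError(f"subvolume shape {data.shape} != window edge {l}")
    tapered = (data - data.mean()) * window.weights
    spec = np.abs(np.fft.fftn(tapered)) ** 2
    spec[0, 0, 0] = 0.0
    return spec


@dataclass(frozen=True)
class SpectralCovariance:
    """Intensity-weighted second moments of spatial frequency.

    ``C`` is the symmetric 3×3 matrix of ⟨q_i q_j⟩ in (x, y, z) index
    order, units cycles²/voxel²; ``total_weight`` the summed masked
    intensity.  ``valid`` is False when no intensity fell inside the band.
    """

    C: np.ndarray
    total_weight: float
    valid: bool


def spectral_covariance(spectrum: np.ndarray, q_min: float, q_max: float
                        ) -> SpectralCovariance:
    """Second-moment matrix of a power spectrum over the band
    q_min <= |q| <= q_max (cycles/voxel)."""
    qz, qy, qx = _freq_grids(spectrum.shape)
    qr = np.sqrt(qx**2 + qy**2 + qz**2)
    mask = (qr >= q_min) & (qr <= q_max)
    w = spectrum * mask
    total = float(w.sum())
    if total <= 0:
        return SpectralCovariance(np.zeros((3, 3)), 0.0, False)
    comps = (qx, qy, qz)
    C = np.empty((3, 3))
    for i in range(3):
        for j in range(i, 3):
            C[i, j] = C[j, i] = float((w * comps[i] * comps[j]).sum()) / total
    return SpectralCovariance(C, total, True)


@dataclass(frozen=True)
class EigenDecomposition:
    """Eigenpairs of a symmetric 3×3 matrix, eigenvalues descending.

    ``eigenvectors`` holds b1, b2, b3 as rows, (x, y, z) components; signs
    are fixed so each of b1, b2 has its largest-magnitude component
    positive and b3 = b1 × b2 (right-handed).  ``degenerate_pairs`` flags
    (λ1≈λ2, λ2≈λ3) within relative tolerance.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    degenerate_pairs: tuple[bool, bool]

    @property
    def degenerate(self) -> bool:
        return any(self.degenerate_pairs)


def eigendecompose(C: np.ndarray, degeneracy_tol: float = 0.05
                   ) -> EigenDecomposition:
    """Descending-ordered eigen-analysis of a symmetric 3×3 matrix."""
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got {C.shape}")
    if not np.allclose(C, C.T, rtol=1e-8, atol=1e-12 * max(1.0, abs(C).max())):
        raise ValueError("matrix is not symmetric")
    vals, vecs = np.linalg.eigh(C)          # ascending
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    # clamp eigh roundoff on PSD inputs (tiny negative lambda_3) to zero
    tiny = 1e-12 * max(abs(vals[0]), 1e-300)
    vals = np.where((vals < 0) & (vals > -tiny), 0.0, vals)
    vecs = vecs[:, order].T                 # rows b1, b2, b3
    for i in (0, 1):
        k = int(np.argmax(np.abs(vecs[i])))
        if vecs[i, k] < 0:
            vecs[i] = -vecs[i]
    vecs[2] = np.cross(vecs[0], vecs[1])
    scale = max(abs(vals[0]), 1e-300)
    deg = (abs(vals[0] - vals[1]) <= degeneracy_tol * scale,
           abs(vals[1] - vals[2]) <= degeneracy_tol * scale)
    return EigenDecomposition(vals, vecs, deg)


# --------------------------------------------------------------------------
# anisotropy measures
# --------------------------------------------------------------------------

def anisotropy_fa(l1: float, l2: float, l3: float) -> float:
    """Fractional anisotropy ω of three nonnegative eigenvalues.

    ω = sqrt(((λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²) / (2(λ1²+λ2²+λ3²)));
    0 for equal eigenvalues (sphere), 1 for a single dominant eigenvalue
    (infinitely long rod).
    """
    lam = np.array([l1, l2, l3], dtype=float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative")
    denom = 2.0 * float(lam @ lam)
    if denom == 0:
        raise ValueError("all eigenvalues are zero")
    num = float((lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2
                + (lam[2] - lam[0]) ** 2)
    return float(np.sqrt(num / denom))


def fa_squared(l1: float, l2: float, l3: float) -> float:
    """Trace form of the anisotropy: (1/2)[3 − 1/trace(R²)] with
    R = D/trace(D); equals ω² of :func:`anisotropy_fa`."""
    lam = np.array([l1, l2, l3], dtype=float)
    tr = lam.sum()
    if tr == 0:
        raise ValueError("all eigenvalues are zero")
    R = lam / tr
    return float(0.5 * (3.0 - 1.0 / float(R @ R)))


def reciprocal_anisotropy(l1: float, l2: float, l3: float,
                          form: str = "trace") -> float:
    """Reciprocal anisotropy Ω, the eigenvalue-dispersion measure applied
    to the inverse eigenvalues (λi → 1/λi).

    The canonical ``form="trace"`` is Ω = (1/2)[3 − 1/trace(R′²)] with
    R′ = D⁻¹/trace(D⁻¹): 0 for a sphere, → 1 for a disk (λ1≈λ2≫λ3),
    → 0.5 for a rod (λ1≫λ2≈λ3).  Because the spectral ellipsoid of well
    aligned fibers is a disk, Ω is the natural alignment score.
    ``form="sqrt"`` gives the square-root (fractional-anisotropy style)
    variant for comparison.

    Returns NaN when any eigenvalue is zero (reciprocal undefined).
    """
    lam = np.array([l1, l2, l3], dtype=float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative")
    if np.any(lam == 0):
        return float("nan")
    inv = 1.0 / lam
    if form == "trace":
        R = inv / inv.sum()
        return float(0.5 * (3.0 - 1.0 / float(R @ R)))
    if form == "sqrt":
        num = float((inv[0] - inv[1]) ** 2 + (inv[1] - inv[2]) ** 2
                    + (inv[2] - inv[0]) ** 2)
        return float(np.sqrt(num / (2.0 * float(inv @ inv))))
    raise ValueError(f"unknown form {form!r}")


# --------------------------------------------------------------------------
# orientation
# --------------------------------------------------------------------------

def canonical_axial(vec: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Canonical representative of an axial (±v equivalent) direction:
    nonnegative z component, ties broken by nonnegative y, then x."""
    v = np.asarray(vec, dtype=float)
    for comp in (2, 1, 0):
        if v[comp] > tol:
            return v
        if v[comp] < -tol:
            return -v
    return np.abs(v)


@dataclass(frozen=True)
class OrientationResult:
    """Axial fiber orientation extracted from a spectral eigen-analysis."""

    vector: np.ndarray
    valid: bool
    degenerate: bool
    omega_reciprocal: float


def fiber_orientation(decomp: EigenDecomposition,
                      omega_floor: float = 0.05) -> OrientationResult:
    """Fiber orientation: eigenvector of the smallest eigenvalue.

    Fibers change slowly along their own axis, so spectral variance is
    lowest there.  The returned vector is the canonical axial
    representative (nonnegative z, ties toward +y then +x).  The result is
    flagged invalid when the reciprocal anisotropy is below
    ``omega_floor`` (no preferred plane) and degenerate when λ2 ≈ λ3.
    """
    l1, l2, l3 = decomp.eigenvalues
    omega = reciprocal_anisotropy(l1, l2, l3)
    vec = canonical_axial(decomp.eigenvectors[2])
    valid = bool(np.isfinite(omega) and omega >= omega_floor)
    return OrientationResult(vec, valid, decomp.degenerate_pairs[1], omega)


# --------------------------------------------------------------------------
# shell averages and the distance peak
# --------------------------------------------------------------------------

def radial_profile(spectrum: np.ndarray, shell_width: float,
                   q_max: float | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Angular (spherical-shell) average of a power spectrum.

    Returns shell-center frequencies (cycles/voxel) and the mean intensity
    per shell of width ``shell_width``, covering radii up to ``q_max``
    (default: the full grid including corners, 0.5·√3).  Empty shells are
    NaN.
    """
    if shell_width <= 0:
        raise ValueError("shell_width must be > 0")
    qz, qy, qx = _freq_grids(spectrum.shape)
    qr = np.sqrt(qx**2 + qy**2 + qz**2)
    top = 0.5 * np.sqrt(3.0) if q_max is None else q_max
    n_shells = int(np.ceil(top / shell_width))
    idx = np.minimum((qr / shell_width).astype(int), n_shells)
    counts = np.bincount(idx.ravel(), minlength=n_shells + 1)[:n_shells]
    sums = np.bincount(idx.ravel(), weights=spectrum.ravel(),
                       minlength=n_shells + 1)[:n_shells]
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    q_centers = (np.arange(n_shells) + 0.5) * shell_width
    return q_centers, prof


def cone_background(spectrum: np.ndarray, axis: np.ndarray,
                    half_angle: float, shell_width: float,
                    q_max: float | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Shell average restricted to a double cone of ``half_angle`` degrees
    around ±``axis`` ((x, y, z) components).

    Along the fiber axis the spectrum carries no inter-fiber peak, so this
    curve serves as the structureless background for peak normalization.
    Shells with no bins inside the cone are filled by linear interpolation
    from neighboring shells.
    """
    if not 0 < half_angle <= 90:
        raise ValueError("half_angle must be in (0, 90] degrees")
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    qz, qy, qx = _freq_grids(spectrum.shape)
    qr = np.sqrt(qx**2 + qy**2 + qz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.abs(qx * a[0] + qy * a[1] + qz * a[2]) / np.where(
            qr > 0, qr, np.inf)
    # exact 0 threshold at 90 deg so the full sphere is included
    thresh = 0.0 if half_angle == 90 else np.cos(np.deg2rad(half_angle))
    in_cone = cos_t >= thresh
    masked = np.where(in_cone, spectrum, 0.0)
    top = 0.5 * np.sqrt(3.0) if q_max is None else q_max
    n_shells = int(np.ceil(top / shell_width))
    idx = np.minimum((qr / shell_width).astype(int), n_shells)
    counts = np.bincount(idx.ravel(), weights=in_cone.ravel().astype(float),
                         minlength=n_shells + 1)[:n_shells]
    sums = np.bincount(idx.ravel(), weights=masked.ravel(),
                       minlength=n_shells + 1)[:n_shells]
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    empty = ~np.isfinite(prof)
    if empty.any() and (~empty).any():
        q_all = (np.arange(n_shells) + 0.5) * shell_width
        prof = prof.copy()
        prof[empty] = np.interp(q_all[empty], q_all[~empty], prof[~empty])
    q_centers = (np.arange(n_shells) + 0.5) * shell_width
    return q_centers, prof


@dataclass(frozen=True)
class DistancePeak:
    """Accepted peak of the background-divided shell spectrum."""

    q_peak: float          # cycles/voxel, parabolically refined
    distance_um: float     # voxel_size / q_peak
    ratio: float           # signal/background at the peak shell


def fiber_distance(q: np.ndarray, signal: np.ndarray, background: np.ndarray,
                   q_range: tuple[float, float], voxel_size: float,
                   peak_threshold: float = 0.2) -> DistancePeak | None:
    """Dominant real-space periodicity from the shell-spectrum peak.

    The signal curve is divided by the cone background, the argmax of the
    ratio located inside ``q_range`` and refined to sub-shell precision by
    a parabolic fit through the three shells around the maximum.  The peak
    is accepted only if the ratio exceeds 1 + ``peak_threshold``; otherwise
    None is returned (no characteristic distance in this window).
    """
    q = np.asarray(q, float)
    signal = np.asarray(signal, float)
    background = np.asarray(background, float)
    # floor the background at a tiny fraction of the signal scale so that a
    # structureless (numerically zero) cone cannot turn division noise into
    # a spurious argmax; real backgrounds sit far above this floor
    floor = 1e-9 * np.nanmax(signal) if np.any(np.isfinite(signal)) else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        bg = np.maximum(background, floor)
        ratio = np.where(bg > 0, signal / bg, np.nan)
    sel = (q >= q_range[0]) & (q <= q_range[1]) & np.isfinite(ratio)
    if not sel.any():
        return None
    i_sel = np.flatnonzero(sel)
    i = i_sel[int(np.nanargmax(ratio[i_sel]))]
    if not ratio[i] >= 1.0 + peak_threshold:
        return None
    q_peak = q[i]
    if 0 < i < len(q) - 1 and np.isfinite(ratio[i - 1]) and np.isfinite(ratio[i + 1]):
        y0, y1, y2 = ratio[i - 1], ratio[i], ratio[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # proper local maximum
            delta = 0.5 * (y0 - y2) / denom
            q_peak = q[i] + np.clip(delta, -1, 1) * (q[1] - q[0])
    return DistancePeak(float(q_peak), float(voxel_size / q_peak),
                        float(ratio[i]))


# --------------------------------------------------------------------------
# sliding-window driver
# --------------------------------------------------------------------------

@dataclass
class FiberField:
    """Sparse regular grid of per-window fiber properties.

    Window centers lie on the grid ``centers_z × centers_y × centers_x``
    (voxel coordinates); per-window arrays share the shape
    ``(len(centers_z), len(centers_y), len(centers_x))``.  ``orientation``
    has a trailing axis of 3 (x, y, z components; canonical axial
    representative).  ``distance_um`` is NaN where no peak was accepted,
    all per-window values are meaningless where ``valid`` is False.
    """

    centers_z: np.ndarray
    centers_y: np.ndarray
    centers_x: np.ndarray
    orientation: np.ndarray
    omega: np.ndarray
    omega_reciprocal: np.ndarray
    distance_um: np.ndarray
    tissue_fraction: np.ndarray
    valid: np.ndarray
    degenerate: np.ndarray
    voxel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return (len(self.centers_z), len(self.centers_y), len(self.centers_x))

    def to_table(self):
        """Flatten to a pandas DataFrame
        (x, y, z, ox, oy, oz, omega, Omega, distance_um, tissue_fraction,
        valid)."""
        import pandas as pd

        zz, yy, xx = np.meshgrid(self.centers_z, self.centers_y,
                                 self.centers_x, indexing="ij")
        return pd.DataFrame({
            "x": xx.ravel(), "y": yy.ravel(), "z": zz.ravel(),
            "ox": self.orientation[..., 0].ravel(),
            "oy": self.orientation[..., 1].ravel(),
            "oz": self.orientation[..., 2].ravel(),
            "omega": self.omega.ravel(),
            "Omega": self.omega_reciprocal.ravel(),
            "distance_um": self.distance_um.ravel(),
            "tissue_fraction": self.tissue_fraction.ravel(),
            "valid": self.valid.ravel().astype(int),
        })

    def write_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    def write_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            for name in ("centers_z", "centers_y", "centers_x", "orientation",
                         "omega", "omega_reciprocal", "distance_um",
                         "tissue_fraction", "valid", "degenerate"):
                fh.create_dataset(name, data=getattr(self, name))
            fh.attrs["voxel_size_um"] = self.voxel_size

    @classmethod
    def read_hdf5(cls, path) -> "FiberField":
        import h5py

        with h5py.File(path, "r") as fh:
            kw = {name: fh[name][()]
                  for name in ("centers_z", "centers_y", "centers_x",
                               "orientation", "omega", "omega_reciprocal",
                               "distance_um", "tissue_fraction", "valid",
                               "degenerate")}
            kw["valid"] = kw["valid"].astype(bool)
            kw["degenerate"] = kw["degenerate"].astype(bool)
            vs = float(fh.attrs.get("voxel_size_um", 1.0))
        return cls(voxel_size=vs, **kw)

    def write_vtk(self, path) -> None:
        """Legacy ASCII VTK structured-points export of the vector field
        (for stream tracing in external viewers)."""
        nz, ny, nx = self.grid_shape
        vec = np.where(self.valid[..., None], self.orientation, 0.0)
        aniso = np.where(self.valid, self.omega_reciprocal, 0.0)
        sz = float(self.centers_z[1] - self.centers_z[0]) if nz > 1 else 1.0
        sy = float(self.centers_y[1] - self.centers_y[0]) if ny > 1 else 1.0
        sx = float(self.centers_x[1] - self.centers_x[0]) if nx > 1 else 1.0
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write("cardiofiber orientation field\nASCII\n")
            fh.write("DATASET STRUCTURED_POINTS\n")
            fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
            fh.write(f"ORIGIN {self.centers_x[0]} {self.centers_y[0]} "
                     f"{self.centers_z[0]}\n")
            fh.write(f"SPACING {sx} {sy} {sz}\n")
            fh.write(f"POINT_DATA {nx * ny * nz}\n")
            fh.write("VECTORS orientation float\n")
            for row in vec.reshape(-1, 3):
                fh.write(f"{row[0]:.6g} {row[1]:.6g} {row[2]:.6g}\n")
            fh.write("SCALARS anisotropy float 1\nLOOKUP_TABLE default\n")
            for val in aniso.ravel():
                fh.write(f"{val:.6g}\n")


def _window_starts(extent: int, l: int, stride: int) -> np.ndarray:
    return np.arange(0, extent - l + 1, stride)


def analyze_volume(vol: Volume3D, config: AnalysisConfig,
                   prefilter_sigma: float = 1.0,
                   compute_distance: bool = True) -> FiberField:
    """Run the sliding-window Fourier fiber analysis over a whole volume.

    Windows of edge ``config.window_edge`` are placed at every
    ``config.stride`` voxels (fully inside the volume).  Windows whose
    tissue fraction (voxels above ``config.tissue_threshold``) falls below
    ``config.min_tissue_fraction`` are marked invalid and skipped.  The
    volume is smoothed once with a Gaussian of ``prefilter_sigma`` voxels
    before analysis (0 disables).
    """
    l = config.window_edge
    if min(vol.shape) < l:
        raise ValueError(
            f"volume shape {vol.shape} smaller than window edge {l}")
    work = gaussian_prefilter(vol, prefilter_sigma) if prefilter_sigma > 0 \
        else vol
    tissue = vol.data >= config.tissue_threshold
    window = kb_window(l, config.kb_beta)
    sw = config.effective_shell_width

    sz = _window_starts(vol.shape[0], l, config.stride)
    sy = _window_starts(vol.shape[1], l, config.stride)
    sx = _window_starts(vol.shape[2], l, config.stride)
    gshape = (len(sz), len(sy), len(sx))

    orientation = np.zeros(gshape + (3,))
    omega = np.full(gshape, np.nan)
    omega_rec = np.full(gshape, np.nan)
    distance = np.full(gshape, np.nan)
    tissue_frac = np.zeros(gshape)
    valid = np.zeros(gshape, dtype=bool)
    degenerate = np.zeros(gshape, dtype=bool)

    for iz, z0 in enumerate(sz):
        for iy, y0 in enumerate(sy):
            for ix, x0 in enumerate(sx):
                cube = work.data[z0:z0 + l, y0:y0 + l, x0:x0 + l]
                tf = float(tissue[z0:z0 + l, y0:y0 + l, x0:x0 + l].mean())
                tissue_frac[iz, iy, ix] = tf
                if tf < config.min_tissue_fraction:
                    continue
                spec = windowed_power_spectrum(cube, window)
                cov = spectral_covariance(spec, config.q_min, config.q_max)
                if not cov.valid:
                    continue
                dec = eigendecompose(cov.C)
                res = fiber_orientation(dec, omega_floor=config.omega_floor)
                omega[iz, iy, ix] = anisotropy_fa(*dec.eigenvalues)
                omega_rec[iz, iy, ix] = res.omega_reciprocal
                degenerate[iz, iy, ix] = res.degenerate
                if not res.valid:
                    continue
                orientation[iz, iy, ix] = res.vector
                valid[iz, iy, ix] = True
                if compute_distance:
                    q, sig = radial_profile(spec, sw, q_max=config.q_max)
                    _, bg = cone_background(spec, res.vector,
                                            config.cone_half_angle, sw,
                                            q_max=config.q_max)
                    peak = fiber_distance(
                        q, sig, bg, (config.q_min, config.q_max),
                        vol.voxel_size, config.peak_threshold)
                    if peak is not None:
                        distance[iz, iy, ix] = peak.distance_um

    return FiberField(
        centers_z=sz + l // 2, centers_y=sy + l // 2, centers_x=sx + l // 2,
        orientation=orientation, omega=omega, omega_reciprocal=omega_rec,
        distance_um=distance, tissue_fraction=tissue_frac, valid=valid,
        degenerate=degenerate, voxel_size=vol.voxel_size,
        meta={"config": config.__dict__.copy(), "method": "ft"},
    )
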