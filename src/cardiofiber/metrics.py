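"""Image-quality and geometry metrics.

Signal-to-noise ratio from two regions of interest, Fourier shell
correlation (FSC) resolution from two independent reconstructions,
cone-beam effective pixel size, and the absorption-coefficient scaling of
reconstructed gray values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cardiofiber.volume_io import Volume3D

__all__ = ["RoiSpec", "GeometrySpec", "snr", "fsc", "resolution_at",
           "effective_pixel_size", "absorption_coefficient",
           "BETTER_THAN_NYQUIST"]

#: Sentinel returned when the FSC never drops below the criterion.
BETTER_THAN_NYQUIST = "better than Nyquist"


@dataclass(frozen=True)
class RoiSpec:
    """Two voxel-index boxes: a signal ROI (~100 voxels of the strongest
    tissue) and a disjoint noise ROI in the surrounding medium.  Each box
    is ((z0, z1), (y0, y1), (x0, x1)), half-open."""

    signal: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    noise: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def _slices(self, box):
        return tuple(slice(a, b) for a, b in box)

    def validate(self, shape) -> None:
        for name, box in (("signal", self.signal), ("noise", self.noise)):
            for (a, b), ext in zip(box, shape):
                if not 0 <= a < b <= ext:
                    raise ValueError(f"{name} ROI {box} outside volume "
                                     f"shape {shape}")
        s = {(z, y, x)
             for z in range(*self.signal[0])
             for y in range(*self.signal[1])
             for x in range(*self.signal[2])}
        n = {(z, y, x)
             for z in range(*self.noise[0])
             for y in range(*self.noise[1])
             for x in range(*self.noise[2])}
        if s & n:
            raise ValueError("signal and noise ROIs overlap")

    def extract(self, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        self.validate(data.shape)
        return (data[self._slices(self.signal)],
                data[self._slices(self.noise)])


@dataclass(frozen=True)
class GeometrySpec:
    """Cone-beam acquisition geometry: detector pixel size dx (μm),
    source–sample distance x1 and source–detector distance x1+x2 (cm),
    and the horizontal detector pixel count N."""

    dx: float
    x1: float
    x2: float
    n_pixels: int = 1944

    def __post_init__(self) -> None:
        if min(self.dx, self.x1, self.n_pixels) <= 0 or self.x2 < 0:
            raise ValueError("geometry parameters must be positive "
                             "(x2 may be zero for contact geometry)")

    @property
    def magnification(self) -> float:
        return (self.x1 + self.x2) / self.x1


def snr(vol: Volume3D | np.ndarray, roi: RoiSpec) -> float:
    """Signal-to-noise ratio (mean(signal) − mean(noise)) / std(noise),
    with the sample (n−1) standard deviation."""
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol, float)
    sig, noi = roi.extract(data)
    sd = float(noi.std(ddof=1))
    if sd == 0:
        raise ValueError("noise ROI has zero variance")
    return float((sig.mean() - noi.mean()) / sd)


def fsc(vol_a: Volume3D | np.ndarray, vol_b: Volume3D | np.ndarray,
        shell_width: float | None = None
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fourier shell correlation of two independent reconstructions.

    Returns (shell-center frequencies in cycles/voxel, FSC curve,
    effective number of independent Fourier voxels per shell).  Shell 0
    (the DC term) is excluded; shells run to the Nyquist frequency 0.5.
    """
    a = vol_a.data if isinstance(vol_a, Volume3D) else np.asarray(vol_a)
    b = vol_b.data if isinstance(vol_b, Volume3D) else np.asarray(vol_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if shell_width is None:
        shell_width = 1.0 / max(a.shape)
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    grids = np.meshgrid(*(np.fft.fftfreq(n) for n in a.shape), indexing="ij")
    qr = np.sqrt(sum(g**2 for g in grids))
    n_shells = int(np.ceil(0.5 / shell_width))
    idx = np.minimum((qr / shell_width).astype(int), n_shells)
    flat = idx.ravel()
    cross = np.bincount(flat, weights=np.real(fa * np.conj(fb)).ravel(),
                        minlength=n_shells + 1)[:n_shells]
    pa = np.bincount(flat, weights=(np.abs(fa)**2).ravel(),
                     minlength=n_shells + 1)[:n_shells]
    pb = np.bincount(flat, weights=(np.abs(fb)**2).ravel(),
                     minlength=n_shells + 1)[:n_shells]
    counts = np.bincount(flat, minlength=n_shells + 1)[:n_shells]
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = cross / np.sqrt(pa * pb)
    q = (np.arange(n_shells) + 0.5) * shell_width
    return q[1:], curve[1:], counts[1:]


def _half_bit_threshold(n_eff: np.ndarray) -> np.ndarray:
    """Half-bit information criterion curve (van Heel & Schatz)."""
    n = np.maximum(np.asarray(n_eff, float), 1.0)
    return (0.2071 + 1.9102 / np.sqrt(n)) / (1.2071 + 0.9102 / np.sqrt(n))


def resolution_at(q: np.ndarray, curve: np.ndarray, voxel_size: float,
                  criterion: float | str = 0.5,
                  n_eff: np.ndarray | None = None):
    """Resolution (same length units as ``voxel_size``) at the first
    crossing of the FSC curve below the criterion.

    ``criterion`` is a fixed threshold (default 0.5) or ``"half-bit"``
    (requires the per-shell counts ``n_eff``).  The crossing frequency is
    linearly interpolated between shells.  If the curve never drops below
    the criterion the resolution is reported as the sentinel
    ``BETTER_THAN_NYQUIST``.
    """
    q = np.asarray(q, float)
    curve = np.asarray(curve, float)
    if criterion == "half-bit":
        if n_eff is None:
            raise ValueError("half-bit criterion needs the shell counts")
        thresh = _half_bit_threshold(n_eff)
    else:
        thresh = np.full_like(q, float(criterion))
    below = curve < thresh
    if not below.any():
        return BETTER_THAN_NYQUIST
    i = int(np.argmax(below))
    if i == 0:
        q_cross = q[0]
    else:
        d0 = curve[i - 1] - thresh[i - 1]
        d1 = curve[i] - thresh[i]
        frac = d0 / (d0 - d1) if d0 != d1 else 0.0
        q_cross = q[i - 1] + frac * (q[i] - q[i - 1])
    return float(voxel_size / q_cross)


def effective_pixel_size(geom: GeometrySpec) -> float:
    """Effective (demagnified) pixel size dx / M = dx·x1/(x1+x2), in the
    units of ``geom.dx``."""
    return geom.dx / geom.magnification


def absorption_coefficient(i_ratio: float, geom: GeometrySpec) -> float:
    """Effective absorption coefficient μ from a transmitted intensity
    ratio: ln(I/I0) = −μ·N·dx_eff, so μ = −ln(i_ratio)/(N·dx_eff)
    (units 1/μm when dx is in μm)."""
    if not 0 < i_ratio <= 1:
        raise ValueError(f"intensity ratio must be in (0, 1], got {i_ratio}")
    return float(-np.log(i_ratio)
                 / (geom.n_pixels * effective_pixel_size(geom)))
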