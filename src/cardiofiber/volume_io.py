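"""Volume I/O, metadata and shared preprocessing.

All volumes use axis order ``(z, y, x)``, 0-based indexing, voxel centers at
integer coordinates, and a single isotropic voxel size in μm.  Anisotropic
voxel metadata is rejected on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml
from scipy import ndimage

log = logging.getLogger("cardiofiber")

VOXEL_SIZE_ATTR = "voxel_size_um"


@dataclass(frozen=True)
class Volume3D:
    """A 3-D scalar grid with an isotropic physical voxel size.

    Parameters
    ----------
    data
        3-D array, axis order (z, y, x); arbitrary intensity units.
    voxel_size
        Edge length of one voxel in μm (one scalar; voxels are isotropic).
    meta
        Free-form provenance metadata (phantom specs, source path, ...).
    """

    data: np.ndarray
    voxel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={data.ndim}")
        if min(data.shape) < 1:
            raise ValueError(f"all extents must be >= 1, got {data.shape}")
        if np.ndim(self.voxel_size) != 0:
            raise ValueError(
                "voxel_size must be a single scalar; anisotropic voxels are "
                "not supported"
            )
        if not float(self.voxel_size) > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", float(self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume3D":
        return replace(self, data=data)


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the sliding-window fiber analysis.

    Attributes
    ----------
    window_edge
        Edge length l of the cubic probing volume in voxels (default 48).
    stride
        Shift between analysis points in voxels (default 10).
    kb_beta
        Kaiser–Bessel taper parameter β (default 8).
    shell_width
        Width of the spherical shells for angular averaging, cycles/voxel
        (default 1/window_edge when set to None).
    cone_half_angle
        Half-opening angle of the background integration cone, degrees.
    q_min, q_max
        Radial frequency band (cycles/voxel) used for the spectral
        covariance and the fiber-distance peak search.
    tissue_threshold
        Intensity threshold separating tissue from air/background.
    min_tissue_fraction
        Windows with a smaller tissue fraction are marked invalid.
    omega_floor
        Minimum reciprocal anisotropy Ω for a trusted orientation.
    peak_threshold
        Minimum peak-to-background excess for an accepted distance peak.
    rng_seed
        Seed for any stochastic step (phantom generation, noise).
    """

    window_edge: int = 48
    stride: int = 10
    kb_beta: float = 8.0
    shell_width: float | None = None
    cone_half_angle: float = 15.0
    q_min: float = 0.02
    q_max: float = 0.45
    tissue_threshold: float = 0.1
    min_tissue_fraction: float = 0.05
    omega_floor: float = 0.05
    peak_threshold: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stride <= self.window_edge:
            raise ValueError(
                f"require 0 < stride <= window_edge, got stride={self.stride},"
                f" window_edge={self.window_edge}"
            )
        sw = self.effective_shell_width
        if not 0 < sw <= 0.5:
            raise ValueError(f"require 0 < shell_width <= 0.5, got {sw}")
        if not 0 < self.q_min < self.q_max <= 0.5:
            raise ValueError(
                f"require 0 < q_min < q_max <= 0.5, got "
                f"q_min={self.q_min}, q_max={self.q_max}"
            )
        if not 0 < self.cone_half_angle < 90:
            raise ValueError("cone_half_angle must be in (0, 90) degrees")

    @property
    def effective_shell_width(self) -> float:
        """Shell width actually used: the configured value or 1/l."""
        if self.shell_width is not None:
            return self.shell_width
        return 1.0 / self.window_edge

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a config from a YAML mapping; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def read_volume(path: str | Path, voxel_size: float | None = None) -> Volume3D:
    """Read a volume from a multipage TIFF, a directory of TIFF slices, or
    an HDF5 file holding one 3-D dataset.

    For HDF5 the voxel size is taken from the dataset/file attribute
    ``voxel_size_um`` unless given explicitly; TIFF input requires an
    explicit ``voxel_size``.  Gray values are returned unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        slices = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not slices:
            raise FileNotFoundError(f"no .tif/.tiff slices in {path}")
        planes = [tifffile.imread(s) for s in slices]
        shapes = {p.shape for p in planes}
        if len(shapes) != 1:
            raise ValueError(f"non-uniform slice shapes in {path}: {shapes}")
        data = np.stack(planes, axis=0)
        if voxel_size is None:
            raise ValueError("voxel_size is required for TIFF input")
        return Volume3D(data, voxel_size, meta={"source": str(path)})
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        with h5py.File(path, "r") as fh:
            dsets = [k for k in fh if isinstance(fh[k], h5py.Dataset)
                     and fh[k].ndim == 3]
            name = "volume" if "volume" in fh else (dsets[0] if dsets else None)
            if name is None:
                raise ValueError(f"no 3-D dataset found in {path}")
            ds = fh[name]
            data = ds[()]
            vs = voxel_size
            if vs is None:
                vs = ds.attrs.get(VOXEL_SIZE_ATTR, fh.attrs.get(VOXEL_SIZE_ATTR))
            if vs is None:
                raise ValueError(
                    f"{path} lacks a '{VOXEL_SIZE_ATTR}' attribute; pass "
                    "voxel_size explicitly"
                )
            if np.ndim(vs) != 0:
                raise ValueError(
                    f"anisotropic voxel metadata {vs!r} not supported"
                )
        return Volume3D(data, float(vs), meta={"source": str(path)})
    # multipage TIFF
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise ValueError(f"{path} holds a single 2-D page, not a volume")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D data, got shape {data.shape}")
    if voxel_size is None:
        raise ValueError("voxel_size is required for TIFF input")
    return Volume3D(data, voxel_size, meta={"source": str(path)})


def write_volume(vol: Volume3D, path: str | Path,
                 extra_datasets: dict[str, np.ndarray] | None = None) -> Path:
    """Write a volume to multipage TIFF or HDF5 (chosen by extension).

    HDF5 output stores the grid under ``volume`` with a ``voxel_size_um``
    attribute plus any ``extra_datasets`` (e.g. phantom ground truth).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("volume", data=vol.data)
            ds.attrs[VOXEL_SIZE_ATTR] = vol.voxel_size
            for key, val in vol.meta.items():
                try:
                    fh.attrs[key] = val
                except TypeError:
                    fh.attrs[key] = str(val)
            for name, arr in (extra_datasets or {}).items():
                fh.create_dataset(name, data=arr)
    else:
        tifffile.imwrite(path, vol.data)
    return path


def gaussian_prefilter(vol: Volume3D, sigma: float = 1.0) -> Volume3D:
    """Smooth a volume with an isotropic 3-D Gaussian of the given σ (voxels).

    Reflective boundary handling conserves the mean intensity on constant
    inputs; ``sigma=0`` returns the input values unchanged.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return vol.with_data(vol.data.copy())
    out = ndimage.gaussian_filter(vol.data.astype(float), sigma=sigma,
                                  mode="reflect")
    return vol.with_data(out)


def tissue_mask(vol: Volume3D, threshold: float) -> np.ndarray:
    """Boolean grid marking voxels with intensity >= threshold as tissue."""
    mask = vol.data >= threshold
    frac = float(mask.mean())
    log.info("tissue_mask: threshold=%g, tissue fraction=%.4f", threshold, frac)
    return mask
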