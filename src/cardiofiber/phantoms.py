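"""Deterministic synthetic phantoms with known ground truth.

These generators emulate the features of air-dried (evaporation-of-solvent)
heart tissue that the fiber-tracking algorithms exploit — separated parallel
muscle bundles with a characteristic spacing, the polyimide mounting tube
with a known wall thickness, and a transmurally varying helical angle —
without attempting anatomical realism.  Everything is seeded and the full
parameter set is embedded in the output metadata.

Edges are rendered with a one-voxel anti-aliased (distance-based) ramp so
that phantom spectra are not dominated by voxelization ringing unrelated to
the structure under test.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np

from cardiofiber.volume_io import Volume3D

_AXES = {"z": np.array([0.0, 0.0, 1.0]),
         "y": np.array([0.0, 1.0, 0.0]),
         "x": np.array([1.0, 0.0, 0.0])}


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a generated phantom (embedded in metadata)."""

    kind: str
    shape: tuple[int, int, int]
    voxel_size: float
    params: dict
    noise_sigma: float
    rng_seed: int


def _unit(vec) -> np.ndarray:
    """Normalize a direction given as an axis name or 3-vector (x, y, z)."""
    if isinstance(vec, str):
        if vec not in _AXES:
            raise ValueError(f"unknown axis {vec!r}")
        return _AXES[vec].copy()
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("direction vector must be nonzero")
    return v / n


def _coords(shape: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinate grids (z, y, x) for a (z, y, x) shape."""
    nz, ny, nx = shape
    return np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                       indexing="ij")


def _soft_edge(signed_dist: np.ndarray) -> np.ndarray:
    """Map a signed distance (positive inside) to [0, 1] over a 1-voxel ramp."""
    return np.clip(signed_dist + 0.5, 0.0, 1.0)


def _add_noise(data: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    if sigma <= 0:
        return data
    rng = np.random.default_rng(seed)
    # sigma is a fraction of the foreground-background contrast
    contrast = float(data.max() - data.min()) or 1.0
    return data + rng.normal(0.0, sigma * contrast, size=data.shape)


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors spanning the plane perpendicular to d."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def fiber_phantom(shape: Sequence[int], direction, spacing: float,
                  fiber_radius: float = 3.0, voxel_size: float = 1.0,
                  noise_sigma: float = 0.0, rng_seed: int = 0
                  ) -> tuple[Volume3D, np.ndarray]:
    """Parallel cylindrical rods on a square lattice, all along one axis.

    Parameters
    ----------
    shape
        Grid extents (z, y, x).
    direction
        Common rod axis: ``"x"|"y"|"z"`` or a 3-vector (x, y, z components).
    spacing
        Center-to-center rod spacing in voxels; must exceed twice the rod
        radius and be resolvable (> 2 voxels).
    fiber_radius
        Rod radius in voxels.
    noise_sigma
        Additive Gaussian noise, as a fraction of the rod/background
        contrast.

    Returns
    -------
    (volume, orientation)
        The phantom volume and the per-voxel ground-truth axial unit vector
        (constant here), shape (3,), components ordered (x, y, z).
    """
    d = _unit(direction)
    if spacing <= 2:
        raise ValueError(f"spacing {spacing} voxels is below resolvability")
    if spacing < 2 * fiber_radius:
        raise ValueError("spacing must be >= 2 * fiber_radius")
    u, v = _perp_basis(d)
    zz, yy, xx = _coords(shape)
    # coordinates in the plane perpendicular to the rod axis
    pu = xx * u[0] + yy * u[1] + zz * u[2]
    pv = xx * v[0] + yy * v[1] + zz * v[2]
    # distance to the nearest lattice point of the square rod lattice
    du = (pu + spacing / 2) % spacing - spacing / 2
    dv = (pv + spacing / 2) % spacing - spacing / 2
    dist = np.hypot(du, dv)
    data = _soft_edge(fiber_radius - dist)
    data = _add_noise(data, noise_sigma, rng_seed)
    spec = PhantomSpec("fibers", tuple(shape), voxel_size,
                       {"direction": d.tolist(), "spacing": spacing,
                        "fiber_radius": fiber_radius},
                       noise_sigma, rng_seed)
    vol = Volume3D(data, voxel_size, meta={"phantom": asdict(spec)})
    return vol, d


def lamellar_phantom(shape: Sequence[int], period_voxels: float, direction,
                     voxel_size: float = 1.0, noise_sigma: float = 0.0,
                     rng_seed: int = 0) -> Volume3D:
    """Sinusoidal lamellar grating: 0.5·(1 + cos(2π u / period)) along
    ``direction``, constant in the orthogonal plane.
    """
    d = _unit(direction)
    if not 2 < period_voxels < min(shape) / 2:
        raise ValueError(
            f"period {period_voxels} out of range (2, {min(shape) / 2})"
        )
    zz, yy, xx = _coords(shape)
    u = xx * d[0] + yy * d[1] + zz * d[2]
    data = 0.5 * (1.0 + np.cos(2 * np.pi * u / period_voxels))
    data = _add_noise(data, noise_sigma, rng_seed)
    spec = PhantomSpec("lamellae", tuple(shape), voxel_size,
                       {"direction": d.tolist(), "period_voxels": period_voxels},
                       noise_sigma, rng_seed)
    return Volume3D(data, voxel_size, meta={"phantom": asdict(spec)})


def tube_phantom(shape: Sequence[int], outer_radius_um: float, wall_um: float,
                 voxel_size: float, noise_sigma: float = 0.0,
                 rng_seed: int = 0) -> Volume3D:
    """Hollow cylindrical shell along z (a mounting-tube stand-in).

    The wall (inner radius = outer − wall) has value 1, inside and outside
    are 0.  ``wall_um == outer_radius_um`` degenerates to a solid cylinder.
    """
    r_out = outer_radius_um / voxel_size
    w = wall_um / voxel_size
    if w > r_out:
        raise ValueError("wall thickness exceeds the outer radius")
    if w < 2:
        raise ValueError(f"wall of {w:.2f} voxels is below resolvability")
    r_in = r_out - w
    nz, ny, nx = shape
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    rho = np.hypot(yy - cy, xx - cx)
    ring = _soft_edge(r_out - rho) * _soft_edge(rho - r_in)
    data = np.broadcast_to(ring, (nz, ny, nx)).copy()
    data = _add_noise(data, noise_sigma, rng_seed)
    spec = PhantomSpec("tube", tuple(shape), voxel_size,
                       {"outer_radius_um": outer_radius_um, "wall_um": wall_um},
                       noise_sigma, rng_seed)
    return Volume3D(data, voxel_size, meta={"phantom": asdict(spec)})


def helical_ring_phantom(shape: Sequence[int],
                         nu_profile: Callable[[np.ndarray], np.ndarray],
                         r_inner: float, r_outer: float,
                         fiber_spacing: float = 6.0, voxel_size: float = 1.0,
                         noise_sigma: float = 0.0, rng_seed: int = 0
                         ) -> tuple[Volume3D, dict]:
    """Annulus around the z axis filled with thin rods whose direction at
    radius r is the circumferential direction tilted out of the short-axis
    plane by the helical angle ν(r).

    The rod texture is the product of two sinusoidal modulations of period
    ``fiber_spacing``: one across the fibers within the (unrolled) cylinder
    surface and one along the radius.  Its spectrum therefore spans the
    plane perpendicular to the local fiber direction, as real fiber bundles
    do.

    Parameters
    ----------
    nu_profile
        Vectorized map from radius (voxels) to helical angle in degrees,
        defined on [r_inner, r_outer], values in [−90, 90].
    r_inner, r_outer
        Annulus radii in voxels around the volume center.

    Returns
    -------
    (volume, ground_truth)
        ``ground_truth`` maps ``"orientation"`` to a (z, y, x, 3) unit
        vector field (components ordered x, y, z; zero outside the
        annulus), ``"nu"`` / ``"psi"`` to per-voxel angle grids in degrees,
        and ``"mask"`` to the annulus mask.
    """
    if not 0 <= r_inner < r_outer:
        raise ValueError("require 0 <= r_inner < r_outer")
    nz, ny, nx = shape
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    zz, yy, xx = _coords(shape)
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)

    r_probe = np.clip(rho, r_inner, r_outer)
    nu = np.deg2rad(np.asarray(nu_profile(r_probe), dtype=float))
    if np.any(np.abs(nu) > np.pi / 2 + 1e-9):
        raise ValueError("nu_profile must stay within [-90, 90] degrees")

    # pattern coordinate across the fibers within the cylinder surface
    across = zz * np.cos(nu) - rho * phi * np.sin(nu)
    tex = 0.25 * (1 + np.cos(2 * np.pi * across / fiber_spacing)) \
              * (1 + np.cos(2 * np.pi * rho / fiber_spacing))
    annulus = _soft_edge(rho - r_inner) * _soft_edge(r_outer - rho)
    data = tex * annulus
    data = _add_noise(data, noise_sigma, rng_seed)

    # ground-truth fiber direction: cos(nu) e_c + sin(nu) e_z
    ec_x, ec_y = -np.sin(phi), np.cos(phi)
    ox = np.cos(nu) * ec_x
    oy = np.cos(nu) * ec_y
    oz = np.sin(nu)
    mask = annulus > 0.5
    orientation = np.stack([ox, oy, oz], axis=-1)
    orientation[~mask] = 0.0

    spec = PhantomSpec("helical_ring", tuple(shape), voxel_size,
                       {"r_inner": r_inner, "r_outer": r_outer,
                        "fiber_spacing": fiber_spacing},
                       noise_sigma, rng_seed)
    vol = Volume3D(data, voxel_size, meta={"phantom": asdict(spec)})
    gt = {"orientation": orientation, "nu": np.rad2deg(nu),
          "psi": np.zeros_like(rho), "mask": mask}
    return vol, gt
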