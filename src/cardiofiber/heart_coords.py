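"""Cardiac cylindrical coordinates and fiber angle maps.

A heart frame is a cylindrical coordinate system: origin on the left
ventricular long axis, z along the long axis, azimuth φ and radius r in
the short-axis plane.  At every point off the axis the local orthonormal
basis is (e_r, e_c, e_z) — radial, circumferential, longitudinal.  A fiber
orientation is then described by two angles:

* helical angle ν — elevation of the fiber out of the short-axis plane,
  measured against e_c in the (e_c, e_z) plane, positive toward +e_z,
  range [−90°, 90°];
* transversal (in-plane) angle ψ — angle of the fiber's short-axis-plane
  projection against e_c, positive toward +e_r, range [−90°, 90°].

Sign conventions are fixed here (axial representative chosen with
nonnegative e_c component); comparisons with other conventions (e.g. the
DTI helix angle) may need a sign flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cardiofiber.fourier_fiber import FiberField

__all__ = ["HeartFrame", "fit_long_axis", "local_basis", "fiber_angles",
           "angle_maps", "AngleMaps"]


@dataclass(frozen=True)
class HeartFrame:
    """Cylindrical heart coordinate frame.

    ``origin`` is a point on the long axis in voxel coordinates
    (z, y, x); ``z_dir`` the unit long-axis direction and ``phi0_dir`` the
    azimuth-zero reference, both with (x, y, z) components,
    ``phi0_dir ⟂ z_dir``.
    """

    origin: np.ndarray
    z_dir: np.ndarray
    phi0_dir: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_dir, float)
        p = np.asarray(self.phi0_dir, float)
        if abs(np.linalg.norm(z) - 1) > 1e-8 or abs(np.linalg.norm(p) - 1) > 1e-8:
            raise ValueError("z_dir and phi0_dir must be unit vectors")
        if abs(z @ p) > 1e-8:
            raise ValueError("phi0_dir must be orthogonal to z_dir")
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "z_dir", z)
        object.__setattr__(self, "phi0_dir", p)

    @classmethod
    def from_points(cls, base, apex) -> "HeartFrame":
        """Frame from two voxel-coordinate points (z, y, x) on the long
        axis, pointing from apex toward base."""
        base = np.asarray(base, float)
        apex = np.asarray(apex, float)
        d = base - apex
        # (z, y, x) displacement -> (x, y, z) direction components
        z_dir = np.array([d[2], d[1], d[0]])
        n = np.linalg.norm(z_dir)
        if n == 0:
            raise ValueError("base and apex coincide")
        z_dir /= n
        phi0 = _project_unit(np.array([1.0, 0.0, 0.0]), z_dir)
        return cls(origin=(base + apex) / 2, z_dir=z_dir, phi0_dir=phi0)


def _project_unit(v: np.ndarray, z_dir: np.ndarray) -> np.ndarray:
    """Unit projection of v onto the plane orthogonal to z_dir."""
    p = v - (v @ z_dir) * z_dir
    n = np.linalg.norm(p)
    if n < 1e-8:
        p = np.array([0.0, 1.0, 0.0]) - z_dir[1] * z_dir
        n = np.linalg.norm(p)
    return p / n


def fit_long_axis(mask: np.ndarray) -> HeartFrame:
    """Estimate the heart frame from a tissue mask.

    The origin is the mask centroid; the long axis is the principal axis
    of largest spread of the mask's second-moment tensor, signed toward
    larger z.  For nearly spherical masks (principal spreads within 1%)
    no axis is defined and a manual frame is required.
    """
    mask = np.asarray(mask, bool)
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("mask is empty")
    centroid = idx.mean(axis=0)                 # (z, y, x)
    # second moments in (x, y, z) component order
    d = (idx - centroid)[:, ::-1]
    cov = d.T @ d / len(d)
    vals, vecs = np.linalg.eigh(cov)
    if vals[2] - vals[0] <= 0.01 * vals[2]:
        raise ValueError(
            "mask is spherical within 1%; supply the frame manually "
            "(e.g. HeartFrame.from_points)")
    z_dir = vecs[:, 2]
    if z_dir[2] < 0:
        z_dir = -z_dir
    phi0 = _project_unit(np.array([1.0, 0.0, 0.0]), z_dir)
    return HeartFrame(origin=centroid, z_dir=z_dir, phi0_dir=phi0)


def local_basis(point, frame: HeartFrame,
                min_radius: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local orthonormal basis (e_r, e_c, e_z) at a voxel point (z, y, x).

    e_z is the long axis, e_r the unit radial vector from the axis to the
    point, e_c = e_z × e_r the circumferential direction (right-handed).
    Points on (or within ``min_radius`` voxels of) the axis have no
    defined radial direction and raise ValueError.
    """
    p = np.asarray(point, float)
    d = p - frame.origin                        # (z, y, x)
    d_xyz = np.array([d[2], d[1], d[0]])
    radial = d_xyz - (d_xyz @ frame.z_dir) * frame.z_dir
    r = np.linalg.norm(radial)
    if r <= min_radius:
        raise ValueError(f"point {point} lies on the long axis (r={r:.2f})")
    e_r = radial / r
    e_z = frame.z_dir
    e_c = np.cross(e_z, e_r)
    return e_r, e_c, e_z


@dataclass(frozen=True)
class FiberAngles:
    """Helical and transversal angle of one fiber orientation (degrees)."""

    psi: float
    nu: float
    psi_defined: bool
    nu_defined: bool


def fiber_angles(orientation: np.ndarray,
                 basis: tuple[np.ndarray, np.ndarray, np.ndarray],
                 tol: float = 1e-6) -> FiberAngles:
    """Helical angle ν and in-plane angle ψ of an axial orientation.

    The sign representative with nonnegative circumferential component is
    used.  A purely longitudinal fiber has ν = +90° by convention and an
    undefined ψ (flagged); a purely radial fiber has ψ = +90° and an
    undefined ν.
    """
    e_r, e_c, e_z = basis
    v = np.asarray(orientation, float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("orientation vector is zero")
    v = v / n
    if v @ e_c < 0:
        v = -v
    vr, vc, vz = v @ e_r, v @ e_c, v @ e_z
    nu_defined = np.hypot(vc, vz) > tol
    psi_defined = np.hypot(vc, vr) > tol
    nu = float(np.degrees(np.arctan2(vz, vc))) if nu_defined else 90.0
    psi = float(np.degrees(np.arctan2(vr, vc))) if psi_defined else 90.0
    if vc <= tol:
        # fiber ⟂ circumferential direction: one angle hits ±90 and the
        # other is poorly conditioned
        if abs(vz) >= abs(vr):
            nu = 90.0 if vz >= 0 else -90.0
            psi_defined = False
        else:
            psi = 90.0 if vr >= 0 else -90.0
            nu_defined = False
    return FiberAngles(psi=psi, nu=nu, psi_defined=psi_defined,
                       nu_defined=nu_defined)


@dataclass
class AngleMaps:
    """Per-window ψ and ν grids on a FiberField analysis grid."""

    psi: np.ndarray
    nu: np.ndarray
    valid: np.ndarray
    radius: np.ndarray       # distance of each window center from the axis


def angle_maps(field: FiberField, frame: HeartFrame) -> AngleMaps:
    """Map a fiber field's orientations to heart-frame angles.

    Windows that are invalid in the field, lie on the long axis, or have
    an undefined angle are propagated as invalid (NaN angle).
    """
    gshape = field.grid_shape
    psi = np.full(gshape, np.nan)
    nu = np.full(gshape, np.nan)
    radius = np.full(gshape, np.nan)
    valid = np.zeros(gshape, dtype=bool)
    for iz, cz in enumerate(field.centers_z):
        for iy, cy in enumerate(field.centers_y):
            for ix, cx in enumerate(field.centers_x):
                d = np.array([float(cx), float(cy), float(cz)]) - np.array(
                    [frame.origin[2], frame.origin[1], frame.origin[0]])
                radial = d - (d @ frame.z_dir) * frame.z_dir
                radius[iz, iy, ix] = np.linalg.norm(radial)
                if not field.valid[iz, iy, ix]:
                    continue
                try:
                    basis = local_basis((cz, cy, cx), frame)
                except ValueError:
                    continue
                ang = fiber_angles(field.orientation[iz, iy, ix], basis)
                nu[iz, iy, ix] = ang.nu
                psi[iz, iy, ix] = ang.psi
                valid[iz, iy, ix] = ang.nu_defined or ang.psi_defined
    return AngleMaps(psi=psi, nu=nu, valid=valid, radius=radius)
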