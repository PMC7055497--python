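"""Gradient structure-tensor comparator for the Fourier fiber analysis.

The local structure tensor is the sum of outer products of the intensity
gradient over a cubic window,

    ST_ij = Σ g_i g_j ,

whose eigenvector of the smallest eigenvalue points along the direction of
least intensity change — the fiber axis.  The reciprocal anisotropy Ω of
the ST eigenvalues scores filament alignment just as in the Fourier
method.  To compare the two methods on equal footing, the gradient window
edge is matched so that both probing volumes carry the same weight:
l_grad = l_FT · m1(β), with m1 the normalized mean of the 1-D
Kaiser–Bessel profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from cardiofiber.fourier_fiber import (
    FiberField,
    anisotropy_fa,
    eigendecompose,
    fiber_orientation,
)
from cardiofiber.volume_io import AnalysisConfig, Volume3D, gaussian_prefilter

__all__ = [
    "StructureTensorField", "gradient_volumes", "structure_tensor_field",
    "match_window_size", "kb_mean_weight", "compare_fields",
    "FieldComparison",
]

StructureTensorField = FiberField  # same grid layout; distance_um stays NaN


def gradient_volumes(vol: Volume3D | np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intensity gradients (gx, gy, gz) by central differences, one-sided
    at the boundaries.  Apply the Gaussian prefilter beforehand (the
    sliding-window driver does this once at volume level)."""
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol, float)
    if min(data.shape) < 3:
        raise ValueError(f"volume extents must be >= 3, got {data.shape}")
    gz, gy, gx = np.gradient(data.astype(float))
    return gx, gy, gz


def kb_mean_weight(beta: float) -> float:
    """Normalized mean m1(β) of the continuous 1-D Kaiser–Bessel profile,
    computed by numerical quadrature: ∫₀¹ I0(β√(1−u²)) du / I0(β)."""
    if beta == 0:
        return 1.0
    val, _ = quad(lambda u: np.i0(beta * np.sqrt(1.0 - u * u)), 0.0, 1.0)
    return float(val / np.i0(beta))


def match_window_size(l_ft: int, beta: float, rounding: str = "round") -> int:
    """Gradient window edge matched to a Kaiser–Bessel-tapered Fourier
    window: l_grad = l_ft · m1(β) (equal window weight), rounded to an
    integer (``rounding``: "round", "floor" or "ceil")."""
    if l_ft < 8:
        raise ValueError(f"l_ft must be >= 8, got {l_ft}")
    raw = l_ft * kb_mean_weight(beta)
    rules = {"round": round, "floor": np.floor, "ceil": np.ceil}
    if rounding not in rules:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    return int(rules[rounding](raw))


def structure_tensor_field(vol: Volume3D, config: AnalysisConfig,
                           l_grad: int | None = None,
                           prefilter_sigma: float = 1.0
                           ) -> StructureTensorField:
    """Sliding-window structure-tensor analysis on the FiberField grid.

    Windows of edge ``l_grad`` (default: matched to the Fourier window via
    :func:`match_window_size`) are centered on the same analysis points as
    the Fourier method (window edge ``config.window_edge``, stride
    ``config.stride``) so the two fields compare element by element.
    """
    if l_grad is None:
        l_grad = match_window_size(config.window_edge, config.kb_beta)
    if l_grad < 3:
        raise ValueError(f"l_grad must be >= 3, got {l_grad}")
    l_ft = config.window_edge
    if min(vol.shape) < l_ft:
        raise ValueError(
            f"volume shape {vol.shape} smaller than window edge {l_ft}")
    work = gaussian_prefilter(vol, prefilter_sigma) if prefilter_sigma > 0 \
        else vol
    gx, gy, gz = gradient_volumes(work)
    tissue = vol.data >= config.tissue_threshold
    grads = (gx, gy, gz)

    # same centers as the Fourier field
    sz = np.arange(0, vol.shape[0] - l_ft + 1, config.stride) + l_ft // 2
    sy = np.arange(0, vol.shape[1] - l_ft + 1, config.stride) + l_ft // 2
    sx = np.arange(0, vol.shape[2] - l_ft + 1, config.stride) + l_ft // 2
    gshape = (len(sz), len(sy), len(sx))
    half = l_grad // 2

    orientation = np.zeros(gshape + (3,))
    omega = np.full(gshape, np.nan)
    omega_rec = np.full(gshape, np.nan)
    tissue_frac = np.zeros(gshape)
    valid = np.zeros(gshape, dtype=bool)
    degenerate = np.zeros(gshape, dtype=bool)

    def window(c, extent):
        lo = max(0, c - half)
        return slice(lo, min(extent, lo + l_grad))

    for iz, cz in enumerate(sz):
        wz = window(cz, vol.shape[0])
        for iy, cy in enumerate(sy):
            wy = window(cy, vol.shape[1])
            for ix, cx in enumerate(sx):
                wx = window(cx, vol.shape[2])
                tf = float(tissue[wz, wy, wx].mean())
                tissue_frac[iz, iy, ix] = tf
                if tf < config.min_tissue_fraction:
                    continue
                ST = np.empty((3, 3))
                blocks = [g[wz, wy, wx] for g in grads]
                for i in range(3):
                    for j in range(i, 3):
                        ST[i, j] = ST[j, i] = float(
                            (blocks[i] * blocks[j]).sum())
                if ST.trace() <= 0:
                    continue
                dec = eigendecompose(ST)
                res = fiber_orientation(dec, omega_floor=config.omega_floor)
                omega[iz, iy, ix] = anisotropy_fa(*dec.eigenvalues)
                omega_rec[iz, iy, ix] = res.omega_reciprocal
                degenerate[iz, iy, ix] = res.degenerate
                if not res.valid:
                    continue
                orientation[iz, iy, ix] = res.vector
                valid[iz, iy, ix] = True

    return StructureTensorField(
        centers_z=sz, centers_y=sy, centers_x=sx,
        orientation=orientation, omega=omega, omega_reciprocal=omega_rec,
        distance_um=np.full(gshape, np.nan), tissue_fraction=tissue_frac,
        valid=valid, degenerate=degenerate, voxel_size=vol.voxel_size,
        meta={"config": config.__dict__.copy(), "method": "st",
              "l_grad": int(l_grad)},
    )


@dataclass(frozen=True)
class FieldComparison:
    """Per-window agreement between two orientation fields."""

    angle_deg: np.ndarray        # axial angular difference, NaN if invalid
    omega_diff: np.ndarray       # Ω(field a) − Ω(field b)
    n_common: int
    quantiles: dict = field(default_factory=dict)

    @property
    def median_angle(self) -> float:
        return self.quantiles["angle_p50"]


def compare_fields(field_a: FiberField, field_b: FiberField
                   ) -> FieldComparison:
    """Compare two fields on the same analysis grid.

    The angular difference per window is the axial angle
    arccos(|a·b|) in degrees (minimum over the ± ambiguity); summary
    quantiles (p25/p50/p75/p95) and the Ω difference are reported over
    windows valid in both fields.
    """
    if field_a.grid_shape != field_b.grid_shape or \
            not (np.array_equal(field_a.centers_z, field_b.centers_z)
                 and np.array_equal(field_a.centers_y, field_b.centers_y)
                 and np.array_equal(field_a.centers_x, field_b.centers_x)):
        raise ValueError("fields are not on the same analysis grid")
    both = field_a.valid & field_b.valid
    dots = np.abs(np.sum(field_a.orientation * field_b.orientation, axis=-1))
    ang = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    ang = np.where(both, ang, np.nan)
    omega_diff = np.where(
        both, field_a.omega_reciprocal - field_b.omega_reciprocal, np.nan)
    vals = ang[both]
    quants = {}
    if vals.size:
        for p in (25, 50, 75, 95):
            quants[f"angle_p{p}"] = float(np.percentile(vals, p))
        quants["omega_diff_median"] = float(np.median(omega_diff[both]))
    return FieldComparison(ang, omega_diff, int(both.sum()), quants)
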