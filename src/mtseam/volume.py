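"""Density-map container and local-symmetry volume operations.

The central operation is :func:`apply_local_symmetry`: given a soft mask
delimiting one asymmetric unit (a protofilament) and a table of rigid
operators mapping that unit onto every other protofilament, the masked
region is gathered from each operator-related location, averaged, and the
average written back to every location.  Averaging f independent copies
raises the signal-to-noise ratio by sqrt(f), which is what makes the seam
survive refinement of pseudo-helical tubules.

Resampling for the symmetry average is done in Fourier space by default: the
operators are z-rotations plus translations, and a shear-decomposed rotation
(three FFT phase-ramp passes) plus a phase-ramp shift is an all-pass filter —
it neither blurs the signal nor eats noise variance, so the sqrt(f) law is
actually observable on the output.  Real-space cubic / trilinear resampling
is available for general transforms and is what the correlation searches use.

Grids are indexed (z, y, x); physical coordinates, voxel sizes and origins
are (x, y, z) Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateCorrelationError,
    EmptyDensityError,
    EmptyMaskError,
    GeometryError,
    ParameterError,
)
from .lattice import OperatorSet, RigidTransform, SymOperator, operator_to_transform

__all__ = [
    "DensityMap",
    "SoftMask",
    "FSCCurve",
    "SearchGrid",
    "make_mask_from_density",
    "render_template_density",
    "transform_map",
    "apply_local_symmetry",
    "refine_operators",
    "compute_fsc",
    "lowpass_filter",
]

Interp = Literal["trilinear", "cubic", "fourier"]
_SPLINE_ORDER = {"trilinear": 1, "cubic": 3}


@dataclass
class _Volume:
    """Shared geometry of voxel grids: (z, y, x) array + physical frame."""

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise GeometryError(f"grid must be 3D with dims >= 2, got {self.grid.shape}")
        if not (self.voxel_size > 0):
            raise GeometryError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.grid)):
            raise GeometryError("grid contains non-finite values")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def center(self) -> np.ndarray:
        """Physical (x, y, z) of the geometric centre of the grid."""
        nz, ny, nx = self.grid.shape
        return self.origin + self.voxel_size * (np.array([nx, ny, nz]) - 1) / 2.0

    def index_to_phys(self, idx_zyx: np.ndarray) -> np.ndarray:
        """(N, 3) (z, y, x) indices -> (N, 3) physical (x, y, z)."""
        idx = np.asarray(idx_zyx, dtype=float)
        return self.origin + self.voxel_size * idx[..., ::-1]

    def phys_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """(N, 3) physical (x, y, z) -> fractional (z, y, x) indices."""
        p = (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size
        return p[..., ::-1]

    def same_geometry(self, other: "_Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel_size - other.voxel_size) <= tol
            and bool(np.all(np.abs(self.origin - other.origin) <= tol))
        )


@dataclass
class DensityMap(_Volume):
    """A 3D scalar density on a voxel grid with physical frame information."""

    @classmethod
    def zeros(
        cls, shape: tuple[int, int, int], voxel_size: float, origin: Sequence[float] = (0, 0, 0)
    ) -> "DensityMap":
        return cls(np.zeros(shape), voxel_size, np.asarray(origin, dtype=float))

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size, self.origin.copy())

    def with_grid(self, grid: np.ndarray) -> "DensityMap":
        return DensityMap(grid, self.voxel_size, self.origin.copy())


@dataclass
class SoftMask(_Volume):
    """A [0, 1]-valued voxel grid delimiting one asymmetric unit."""

    soft_edge_width: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.grid.min() < -1e-9 or self.grid.max() > 1.0 + 1e-9:
            raise GeometryError("mask values must lie in [0, 1]")
        self.grid = np.clip(self.grid, 0.0, 1.0)
        if self.grid.max() == 0.0:
            raise EmptyMaskError("mask has empty support")

    def copy(self) -> "SoftMask":
        return SoftMask(self.grid.copy(), self.voxel_size, self.origin.copy(), self.soft_edge_width)


# ---------------------------------------------------------------------------
# mask construction and template rendering


def make_mask_from_density(
    template: DensityMap,
    threshold: float = 0.1,
    extend: float = 0.0,
    soft_edge: float = 0.0,
) -> SoftMask:
    """Threshold a template density into a soft-edged mask.

    The binary support is every voxel >= ``threshold * max``, dilated by
    ``extend`` Angstrom, then surrounded by a cosine-shaped falloff of width
    ``soft_edge`` Angstrom (the relion_mask_create recipe).
    """
    if not (0.0 < threshold < 1.0):
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    if extend < 0 or soft_edge < 0:
        raise ParameterError("extend and soft_edge must be >= 0")
    peak = template.grid.max()
    support = template.grid >= threshold * peak
    if peak <= 0 or not support.any():
        raise EmptyMaskError("thresholded template has empty support")
    vs = template.voxel_size
    if extend > 0:
        d_out = ndimage.distance_transform_edt(~support, sampling=vs)
        support = d_out <= extend
    if soft_edge > 0:
        d_out = ndimage.distance_transform_edt(~support, sampling=vs)
        grid = np.where(
            support,
            1.0,
            np.where(d_out < soft_edge, 0.5 * (1.0 + np.cos(np.pi * d_out / soft_edge)), 0.0),
        )
    else:
        grid = support.astype(float)
    return SoftMask(grid, vs, template.origin.copy(), soft_edge_width=soft_edge)


def render_template_density(
    points: np.ndarray,
    weights: np.ndarray | float,
    sigma: float,
    shape: tuple[int, int, int],
    voxel_size: float,
    origin: Sequence[float] = (0, 0, 0),
) -> DensityMap:
    """Sum of isotropic 3D Gaussians placed at physical (x, y, z) points.

    Each Gaussian is normalised so the voxel sum times voxel volume equals
    its weight (for points well inside the frame).  This is the pdb2mrc-style
    primitive both the synthetic generator and docking templates use.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ParameterError("points must be (N, 3) (x, y, z) in Angstrom")
    w = np.broadcast_to(np.asarray(weights, dtype=float), pts.shape[0])
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    out = DensityMap.zeros(shape, voxel_size, origin)
    nz, ny, nx = shape
    vs = voxel_size
    half = max(1, int(np.ceil(4.0 * sigma / vs)))
    norm = vs**3 / ((2.0 * np.pi) ** 1.5 * sigma**3)
    n_inside = 0
    for (x, y, z), wi in zip(pts, w):
        fz, fy, fx = (z - origin[2]) / vs, (y - origin[1]) / vs, (x - origin[0]) / vs
        if not (0 <= fx < nx and 0 <= fy < ny and 0 <= fz < nz):
            continue
        n_inside += 1
        z0, z1 = max(0, int(fz) - half), min(nz, int(fz) + half + 1)
        y0, y1 = max(0, int(fy) - half), min(ny, int(fy) + half + 1)
        x0, x1 = max(0, int(fx) - half), min(nx, int(fx) + half + 1)
        iz = np.arange(z0, z1)[:, None, None]
        iy = np.arange(y0, y1)[None, :, None]
        ix = np.arange(x0, x1)[None, None, :]
        r2 = (iz - fz) ** 2 + (iy - fy) ** 2 + (ix - fx) ** 2
        out.grid[z0:z1, y0:y1, x0:x1] += wi * norm * np.exp(-r2 * vs**2 / (2.0 * sigma**2))
    if n_inside == 0:
        raise EmptyDensityError("no points fall inside the frame")
    return out


# ---------------------------------------------------------------------------
# rigid resampling


def _is_z_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    return (
        abs(R[2, 2] - 1.0) < tol
        and abs(R[0, 2]) < tol
        and abs(R[1, 2]) < tol
        and abs(R[2, 0]) < tol
        and abs(R[2, 1]) < tol
    )


def _shear_pass(vol: np.ndarray, axis: int, shift_per_row: np.ndarray, row_axis: int) -> np.ndarray:
    """Circularly shift each row along ``axis`` by a per-row fractional amount,
    exactly, via an FFT phase ramp."""
    n = vol.shape[axis]
    k = np.fft.fftfreq(n)
    shp_k = [1, 1, 1]
    shp_k[axis] = n
    shp_s = [1, 1, 1]
    shp_s[row_axis] = vol.shape[row_axis]
    F = np.fft.fft(vol, axis=axis)
    F *= np.exp(-2j * np.pi * k.reshape(shp_k) * np.asarray(shift_per_row).reshape(shp_s))
    return np.fft.ifft(F, axis=axis).real


def _fourier_rotate_shift(
    grid: np.ndarray, psi_deg: float, shift_xyz_vox: np.ndarray
) -> np.ndarray:
    """Actively rotate content by ``psi_deg`` (right-handed about +z) about the
    grid centre, then translate by ``shift_xyz_vox`` voxels.  All-pass;
    content wraps circularly at the box edge."""
    nz, ny, nx = grid.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    # the shear/rot90 composition below realises a content rotation of -th,
    # so negate once here to make +psi right-handed about +z
    th = -np.deg2rad(psi_deg)
    q = int(np.round(th / (np.pi / 2.0)))
    res = th - q * np.pi / 2.0
    out = grid
    # exact 90-degree steps about the array centre (even boxes rotate about
    # the half-voxel centre consistently with cx, cy above)
    for _ in range(q % 4):
        out = np.rot90(out, k=1, axes=(1, 2))  # maps +x -> +y content motion
    if abs(res) > 1e-15:
        a = np.tan(res / 2.0)  # sign: shear composition below rotates by +res
        b = -np.sin(res)
        y = np.arange(ny) - cy
        x = np.arange(nx) - cx
        out = _shear_pass(out, axis=2, shift_per_row=a * y, row_axis=1)
        out = _shear_pass(out, axis=1, shift_per_row=b * x, row_axis=2)
        out = _shear_pass(out, axis=2, shift_per_row=a * y, row_axis=1)
    sx, sy, sz = shift_xyz_vox
    if any(abs(s) > 1e-15 for s in (sx, sy, sz)):
        F = np.fft.fftn(out)
        kz = np.fft.fftfreq(nz)[:, None, None]
        ky = np.fft.fftfreq(ny)[None, :, None]
        kx = np.fft.fftfreq(nx)[None, None, :]
        F *= np.exp(-2j * np.pi * (kx * sx + ky * sy + kz * sz))
        out = np.fft.ifftn(F).real
    return out


def transform_map(
    dmap: DensityMap,
    transform: RigidTransform,
    interpolation: Interp = "cubic",
) -> DensityMap:
    """Resample a map under an active rigid transform.

    The output voxel at physical position x takes the value of the input at
    ``T^-1(x)`` (pull-back), so the content moves by T.  ``fourier`` requires
    the rotation to be about the z axis and wraps at the box edge; the spline
    modes fill out-of-frame regions with zero.
    """
    R, t = transform.rotation, transform.translation
    if interpolation == "fourier":
        if not _is_z_rotation(R):
            raise ParameterError("fourier resampling supports z-rotations only")
        psi = np.rad2deg(np.arctan2(R[1, 0], R[0, 0]))
        c0 = dmap.center
        shift_phys = R @ c0 + t - c0  # translation left over after rotating about the grid centre
        out = _fourier_rotate_shift(dmap.grid, psi, shift_phys / dmap.voxel_size)
        return dmap.with_grid(out)
    order = _SPLINE_ORDER[interpolation]
    Rinv = R.T
    # index-space (z, y, x) matrix: permute the xyz inverse rotation
    p = [2, 1, 0]
    M = Rinv[np.ix_(p, p)]
    off_xyz = (Rinv @ (dmap.origin - t) - dmap.origin) / dmap.voxel_size
    out = ndimage.affine_transform(
        dmap.grid, M, offset=off_xyz[::-1], order=order, mode="constant", cval=0.0
    )
    return dmap.with_grid(out)


# ---------------------------------------------------------------------------
# local symmetry averaging


def _operator_transforms(
    ops: OperatorSet, center: np.ndarray
) -> list[tuple[SymOperator, RigidTransform]]:
    return [(op, operator_to_transform(op, center)) for op in ops.included]


def apply_local_symmetry(
    dmap: DensityMap,
    mask: SoftMask,
    ops: OperatorSet,
    interpolation: Interp = "fourier",
    center: Sequence[float] | None = None,
    overlap_warn_fraction: float = 0.05,
) -> DensityMap:
    """Average the masked unit over all included operator copies.

    For each included operator k the masked region is gathered from the map
    at the operator-transformed location; the mask-weighted average is
    computed once and written back to every copy's location.  Voxels outside
    all transformed mask supports are left untouched; where transformed
    supports overlap, per-voxel weight normalisation is applied (a warning is
    emitted when the overlap exceeds ``overlap_warn_fraction`` of the mask
    volume).
    """
    if not dmap.same_geometry(mask):
        raise GeometryError("map and mask grids must share geometry")
    included = ops.included
    if len(included) < 2:
        raise ParameterError("need at least 2 included operators to average")
    c = np.asarray(center, dtype=float) if center is not None else dmap.center
    pairs = _operator_transforms(ops, c)
    if interpolation == "fourier" and not all(op.is_axial for op, _ in pairs):
        interpolation = "cubic"  # tilt/rot operators need the general path

    # gather: copy k seen in the reference frame is map(T_k(x))
    acc = np.zeros_like(dmap.grid)
    for op, T in pairs:
        if op.is_identity:
            acc += dmap.grid
        else:
            acc += transform_map(dmap, T.inverse(), interpolation).grid
    avg = acc / float(len(pairs))

    # scatter the (smooth) average and the mask separately, with spline
    # resampling for the mask: a sharp-edged mask pushed through the Fourier
    # path would ring at its boundary.  Using the same transformed-mask field
    # both to add the average and to remove the original makes mask
    # resampling error cancel exactly wherever the average equals the map.
    scatter_interp = "cubic" if interpolation == "fourier" else interpolation
    avg_map = dmap.with_grid(avg)
    mask_map = dmap.with_grid(mask.grid)
    scatter = np.zeros_like(dmap.grid)
    weight = np.zeros_like(dmap.grid)
    for op, T in pairs:
        if op.is_identity:
            scatter += avg * mask.grid
            weight += mask.grid
        else:
            # clip to [0, 1]: spline overshoot at the mask edge is not
            # physical overlap
            w_k = np.clip(transform_map(mask_map, T, scatter_interp).grid, 0.0, 1.0)
            scatter += transform_map(avg_map, T, interpolation).grid * w_k
            weight += w_k

    mask_volume = mask.grid.sum()
    overlap = np.clip(weight - 1.0, 0.0, None).sum()
    if overlap > overlap_warn_fraction * mask_volume:
        warnings.warn(
            f"transformed masks overlap by {overlap / mask_volume:.1%} of the mask volume; "
            "averaging proceeds with per-voxel weight normalisation",
            stacklevel=2,
        )
    out = (scatter + np.clip(1.0 - weight, 0.0, 1.0) * dmap.grid) / np.maximum(weight, 1.0)
    return dmap.with_grid(out)


# ---------------------------------------------------------------------------
# operator refinement by masked correlation


@dataclass(frozen=True)
class SearchGrid:
    """Coarse-to-fine grid-search schedule for operator refinement.

    Ranges are half-widths around the current operator values; setting a
    range to 0 freezes that degree of freedom.  Defaults follow the
    exhaustive 0.5-unit coarse / 0.1-unit fine schedule.
    """

    psi_range: float = 2.0
    dz_range: float = 2.0
    dx_range: float = 0.0
    dy_range: float = 0.0
    coarse_step_deg: float = 0.5
    coarse_step_ang: float = 0.5
    fine_step_deg: float = 0.1
    fine_step_ang: float = 0.1


def _delta_axis(half_range: float, step: float) -> np.ndarray:
    if half_range <= 0 or step <= 0:
        return np.array([0.0])
    n = int(np.floor(half_range / step + 1e-9))
    return np.arange(-n, n + 1) * step


def _masked_ncc(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    """Weighted normalised cross-correlation of two sample vectors."""
    wsum = w.sum()
    am = a - (w * a).sum() / wsum
    bm = b - (w * b).sum() / wsum
    va = (w * am * am).sum()
    vb = (w * bm * bm).sum()
    if va <= 0 or vb <= 0:
        raise DegenerateCorrelationError("zero variance inside the mask")
    return float((w * am * bm).sum() / np.sqrt(va * vb))


class _MaskedSampler:
    """Samples a spline-prefiltered map at transformed mask-support points."""

    def __init__(self, dmap: DensityMap, mask: SoftMask, order: int = 3):
        support = mask.grid > 1e-3
        if not support.any():
            raise EmptyMaskError("mask has empty support")
        idx = np.argwhere(support)
        self.points = mask.index_to_phys(idx)  # (N, 3) xyz
        self.weights = mask.grid[support]
        self.ref_vals = dmap.grid[support]
        self.dmap = dmap
        self.order = order
        self.filtered = ndimage.spline_filter(dmap.grid, order=order) if order > 1 else dmap.grid

    def sample(self, T: RigidTransform) -> np.ndarray:
        xyz = T.apply(self.points)
        zyx = self.dmap.phys_to_index(xyz)
        return ndimage.map_coordinates(
            self.filtered, zyx.T, order=self.order, prefilter=False, mode="constant", cval=0.0
        )

    def ncc(self, T: RigidTransform) -> float:
        return _masked_ncc(self.ref_vals, self.sample(T), self.weights)


def refine_operators(
    dmap: DensityMap,
    mask: SoftMask,
    ops: OperatorSet,
    search: SearchGrid = SearchGrid(),
    center: Sequence[float] | None = None,
    interpolation: Interp = "cubic",
) -> OperatorSet:
    """Adjust each non-identity operator to maximise masked correlation.

    Every included operator is refined independently: the reference unit (map
    values under the mask) is compared against the map sampled at the
    perturbed-operator-transformed support, with an exhaustive coarse grid
    followed by a fine grid around the coarse optimum.  Ties break toward the
    smallest-magnitude adjustment, and the unperturbed operator is always a
    candidate, so the returned correlation never decreases.
    """
    if not dmap.same_geometry(mask):
        raise GeometryError("map and mask grids must share geometry")
    order = _SPLINE_ORDER.get(interpolation, 3)
    sampler = _MaskedSampler(dmap, mask, order=order)
    c = np.asarray(center, dtype=float) if center is not None else dmap.center

    refined = ops
    for op in ops.included:
        if op.is_identity:
            continue

        def objective(dpsi: float, ddz: float, ddx: float, ddy: float) -> float:
            cand = SymOperator(
                index=op.index,
                psi_deg=op.psi_deg + dpsi,
                dz=op.dz + ddz,
                dx=op.dx + ddx,
                dy=op.dy + ddy,
                tilt_deg=op.tilt_deg,
                rot_deg=op.rot_deg,
            )
            return sampler.ncc(operator_to_transform(cand, c))

        best = (0.0, 0.0, 0.0, 0.0)
        best_val = objective(*best)
        for coarse in (True, False):
            if coarse:
                dpsis = _delta_axis(search.psi_range, search.coarse_step_deg)
                dzs = _delta_axis(search.dz_range, search.coarse_step_ang)
                dxs = _delta_axis(search.dx_range, search.coarse_step_ang)
                dys = _delta_axis(search.dy_range, search.coarse_step_ang)
                cands = [(p, z, x, y) for p in dpsis for z in dzs for x in dxs for y in dys]
            else:
                b = best
                dpsis = b[0] + _delta_axis(search.coarse_step_deg, search.fine_step_deg)
                dzs = b[1] + _delta_axis(search.coarse_step_ang, search.fine_step_ang)
                dxs = b[2] + (
                    _delta_axis(search.coarse_step_ang, search.fine_step_ang)
                    if search.dx_range > 0
                    else np.array([0.0])
                )
                dys = b[3] + (
                    _delta_axis(search.coarse_step_ang, search.fine_step_ang)
                    if search.dy_range > 0
                    else np.array([0.0])
                )
                cands = [(p, z, x, y) for p in dpsis for z in dzs for x in dxs for y in dys]
            # smallest-magnitude first, strict improvement required: ties
            # resolve toward the smallest adjustment
            cands.sort(key=lambda d: (abs(d[0]), abs(d[1]), abs(d[2]), abs(d[3])))
            for cand in cands:
                v = objective(*cand)
                if v > best_val + 1e-12:
                    best_val, best = v, cand
        refined = refined.replace_operator(
            SymOperator(
                index=op.index,
                psi_deg=op.psi_deg + best[0],
                dz=op.dz + best[1],
                dx=op.dx + best[2],
                dy=op.dy + best[3],
                tilt_deg=op.tilt_deg,
                rot_deg=op.rot_deg,
            )
        )
    return refined


# ---------------------------------------------------------------------------
# FSC and filtering


@dataclass
class FSCCurve:
    """Fourier shell correlation between two half maps.

    ``shell_centers`` are spatial frequencies in 1/Angstrom (one Fourier
    voxel per shell); ``correlations`` the normalised complex correlation of
    the two transforms in each shell.
    """

    shell_centers: np.ndarray
    correlations: np.ndarray

    def resolution_at(self, threshold: float = 0.143) -> float:
        """Resolution in Angstrom at the first crossing below ``threshold``,
        linearly interpolated; the finest sampled shell if never crossed."""
        f, c = self.shell_centers, self.correlations
        for i in range(1, len(c)):
            if c[i] < threshold:
                if c[i - 1] <= threshold or c[i - 1] == c[i]:
                    return float(1.0 / f[i])
                fc = f[i - 1] + (c[i - 1] - threshold) / (c[i - 1] - c[i]) * (f[i] - f[i - 1])
                return float(1.0 / fc)
        return float(1.0 / f[-1])


def compute_fsc(
    half1: DensityMap, half2: DensityMap, mask: SoftMask | None = None
) -> FSCCurve:
    """Shell-wise normalised correlation of the two half-map transforms.

    Shells are one Fourier voxel wide.  Symmetric in its arguments and
    invariant to positive rescaling of either map.
    """
    if not half1.same_geometry(half2):
        raise GeometryError("half maps must share grid geometry")
    if mask is not None:
        if not mask.same_geometry(half1):
            raise GeometryError("mask must share the half-map geometry")
        g1 = half1.grid * mask.grid
        g2 = half2.grid * mask.grid
    else:
        g1, g2 = half1.grid, half2.grid
    F1 = np.fft.fftn(g1)
    F2 = np.fft.fftn(g2)
    vs = half1.voxel_size
    freqs = [np.fft.fftfreq(n, d=vs) for n in g1.shape]
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    dshell = 1.0 / (min(g1.shape) * vs)
    shell = np.minimum(np.round(r / dshell).astype(int), int(0.5 / vs / dshell))
    nsh = shell.max() + 1
    num = np.bincount(shell.ravel(), weights=(F1 * np.conj(F2)).real.ravel(), minlength=nsh)
    p1 = np.bincount(shell.ravel(), weights=np.abs(F1).ravel() ** 2, minlength=nsh)
    p2 = np.bincount(shell.ravel(), weights=np.abs(F2).ravel() ** 2, minlength=nsh)
    den = np.sqrt(p1 * p2)
    corr = np.divide(num, den, out=np.ones_like(num), where=den > 0)
    centers = np.arange(nsh) * dshell
    return FSCCurve(shell_centers=centers, correlations=corr)


def lowpass_filter(dmap: DensityMap, cutoff: float, edge_width: int = 2) -> DensityMap:
    """Attenuate Fourier amplitudes beyond ``1/cutoff`` with a raised cosine.

    ``cutoff`` is in Angstrom and must be above the Nyquist limit
    ``2 * voxel_size``; ``edge_width`` is the width of the cosine edge in
    Fourier shells.  The DC term (mean value) is preserved exactly.
    """
    if cutoff <= 2.0 * dmap.voxel_size:
        raise ParameterError(
            f"cutoff {cutoff} A is at or below the Nyquist limit {2 * dmap.voxel_size} A"
        )
    vs = dmap.voxel_size
    freqs = [np.fft.fftfreq(n, d=vs) for n in dmap.shape]
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    rc = 1.0 / cutoff
    w = max(edge_width, 1) / (min(dmap.shape) * vs)
    H = np.where(
        r <= rc, 1.0, np.where(r >= rc + w, 0.0, 0.5 * (1.0 + np.cos(np.pi * (r - rc) / w)))
    )
    out = np.fft.ifftn(np.fft.fftn(dmap.grid) * H).real
    return dmap.with_grid(out)
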