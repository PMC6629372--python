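"""Cross-sectional distortion and decoration analysis of tubule maps.

Quantifies what decorator binding does to a microtubule's cross-section:

* per-protofilament centres from a binarised maximum-intensity projection,
* inter-protofilament rotation angles by registering a single-protofilament
  template density to each protofilament and differencing fitted azimuths,
* ellipticity (short/long diameter ratio, <= 1) of the centre locus by a
  direct least-squares ellipse fit,
* decoration level per protofilament as thresholded voxel volume inside a
  decorator zone (relative to the best-decorated protofilament),
* the decoration-versus-local-curvature ordinary least-squares regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.measure import EllipseModel

from .errors import (
    DetectionError,
    FitError,
    ParameterError,
    RegressionError,
)
from .lattice import SymOperator, operator_to_transform
from .volume import (
    DensityMap,
    SoftMask,
    _MaskedSampler,
    lowpass_filter,
    make_mask_from_density,
)

__all__ = [
    "PFTrace",
    "EllipseFit",
    "DistortionProfile",
    "DecorationProfile",
    "RegressionResult",
    "AngleSearch",
    "trace_protofilaments",
    "measure_pf_angles",
    "fit_ellipse",
    "measure_decoration",
    "regress_decoration_vs_curvature",
    "curvature_decoration_report",
]


@dataclass
class PFTrace:
    """Per-protofilament (x, y) centres in Angstrom, ordered counter-clockwise
    by polar angle about the tubule axis."""

    points: np.ndarray  # (n_pf, 2)
    azimuths_deg: np.ndarray  # (n_pf,) in [-180, 180)
    center: np.ndarray  # (2,) axis position used
    threshold: float
    method: Literal["components", "sectors"]


def trace_protofilaments(
    dmap: DensityMap,
    n_pf: int,
    threshold: float = 0.3,
    z_range: tuple[float, float] | None = None,
    sector_fallback: bool = True,
) -> PFTrace:
    """Locate protofilament centres on a binarised maximum-intensity projection.

    The map is projected along z (optionally over a physical ``z_range``),
    binarised at ``threshold`` times the projection maximum, and connected
    components give intensity-weighted centres.  When thresholding does not
    split into exactly ``n_pf`` components, centres fall back to
    intensity-weighted centroids per angular sector of width 360/n_pf about
    the projection centroid.
    """
    grid = dmap.grid
    if z_range is not None:
        zlo = int(np.floor((z_range[0] - dmap.origin[2]) / dmap.voxel_size))
        zhi = int(np.ceil((z_range[1] - dmap.origin[2]) / dmap.voxel_size)) + 1
        grid = grid[max(zlo, 0) : max(zhi, 1)]
        if grid.shape[0] < 1:
            raise ParameterError("z_range selects no slices")
    mip = grid.max(axis=0)
    if mip.max() <= mip.min():
        raise DetectionError("projection has no contrast")
    binary = mip >= threshold * mip.max()
    labels, n_comp = ndimage.label(binary)

    vs = dmap.voxel_size
    ox, oy = dmap.origin[0], dmap.origin[1]
    yy, xx = np.indices(mip.shape)

    if n_comp == n_pf:
        method = "components"
        pts = []
        for lab in range(1, n_comp + 1):
            sel = labels == lab
            w = mip * sel
            tot = w.sum()
            pts.append([ (w * xx).sum() / tot * vs + ox, (w * yy).sum() / tot * vs + oy ])
        pts = np.asarray(pts)
        w_all = mip * binary
        cx = (w_all * xx).sum() / w_all.sum() * vs + ox
        cy = (w_all * yy).sum() / w_all.sum() * vs + oy
        center = np.array([cx, cy])
    else:
        if not sector_fallback and n_comp < 3:
            raise DetectionError(
                f"found {n_comp} components (expected {n_pf}) and sector fallback is off"
            )
        method = "sectors"
        w_all = mip * binary
        cx = (w_all * xx).sum() / w_all.sum() * vs + ox
        cy = (w_all * yy).sum() / w_all.sum() * vs + oy
        center = np.array([cx, cy])
        px = xx * vs + ox - cx
        py = yy * vs + oy - cy
        ang = np.rad2deg(np.arctan2(py, px))
        # anchor sector boundaries half a sector before the brightest pixel so
        # a protofilament sits mid-sector rather than on a boundary
        iy, ix = np.unravel_index(np.argmax(mip), mip.shape)
        a0 = ang[iy, ix] - 180.0 / n_pf
        sector = np.floor(np.mod(ang - a0, 360.0) / (360.0 / n_pf)).astype(int)
        pts = []
        for s in range(n_pf):
            sel = binary & (sector == s)
            if not sel.any():
                raise DetectionError(f"no density in angular sector {s}")
            w = mip * sel
            tot = w.sum()
            pts.append([(w * xx).sum() / tot * vs + ox, (w * yy).sum() / tot * vs + oy])
        pts = np.asarray(pts)

    az = np.rad2deg(np.arctan2(pts[:, 1] - center[1], pts[:, 0] - center[0]))
    order = np.argsort(az)
    return PFTrace(
        points=pts[order],
        azimuths_deg=az[order],
        center=center,
        threshold=threshold,
        method=method,
    )


@dataclass
class EllipseFit:
    center: np.ndarray  # (2,)
    semi_major: float  # a >= b
    semi_minor: float
    orientation_deg: float  # of the major axis, in [0, 180)
    ellipticity: float  # b / a, in (0, 1]


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares conic fit constrained to an ellipse.

    Invariant to rotation, translation and uniform scaling of the input
    (points are centred and scaled internally for conditioning).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise FitError("need at least 5 (x, y) points")
    mean = pts.mean(axis=0)
    scale = np.sqrt(((pts - mean) ** 2).sum(axis=1).mean())
    if scale <= 0:
        raise FitError("degenerate points (all identical)")
    norm = (pts - mean) / scale
    # collinearity check: smallest singular value of the centred cloud
    s = np.linalg.svd(norm, compute_uv=False)
    if s[-1] < 1e-9:
        raise FitError("points are collinear; no ellipse is defined")
    if hasattr(EllipseModel, "from_estimate"):  # skimage >= 0.26
        model = EllipseModel.from_estimate(norm)
        if not model:
            raise FitError("ellipse fit failed")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:
        model = EllipseModel()
        if not model.estimate(norm):
            raise FitError("ellipse fit failed")
        xc, yc, a, b, theta = model.params
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise FitError("ellipse fit failed")
    if a < b:
        a, b = b, a
        theta += np.pi / 2.0
    return EllipseFit(
        center=mean + scale * np.array([xc, yc]),
        semi_major=float(a * scale),
        semi_minor=float(b * scale),
        orientation_deg=float(np.rad2deg(theta) % 180.0),
        ellipticity=float(b / a),
    )


@dataclass(frozen=True)
class AngleSearch:
    """Coarse-to-fine schedule for template azimuth registration.

    The azimuth is searched within ``phi_half`` degrees of each traced
    centre; the axial shift within ``dz_half`` Angstrom (default: half a
    monomer spacing plus 2 A, so some axial registration always exists
    whatever the protofilament's lattice offset)."""

    phi_half: float = 4.0
    phi_coarse: float = 0.5
    phi_fine: float = 0.1
    dz_half: float | None = None
    dz_coarse: float = 1.0
    dz_fine: float = 0.1


@dataclass
class DistortionProfile:
    """Inter-protofilament rotation angles and the cross-section ellipse.

    ``angles_deg[i]`` is the counter-clockwise rotation from traced
    protofilament i to i+1 (the last entry wraps around and is the one that
    crosses the extra axial rise at the seam, flagged by ``wrap_index``)."""

    angles_deg: np.ndarray  # (n_pf,)
    mean_deg: float
    sd_deg: float
    fitted_azimuths_deg: np.ndarray  # (n_pf,)
    correlations: np.ndarray  # (n_pf,) template NCC per protofilament
    low_confidence: np.ndarray  # (n_pf,) bool
    ellipse: EllipseFit
    wrap_index: int
    trace: PFTrace

    @property
    def ellipticity(self) -> float:
        return self.ellipse.ellipticity


def measure_pf_angles(
    dmap: DensityMap,
    template: DensityMap,
    trace: PFTrace,
    center: Sequence[float] | None = None,
    template_mask: SoftMask | None = None,
    mask_threshold: float = 0.1,
    monomer_rise: float = 41.1465,
    search: AngleSearch = AngleSearch(),
    corr_floor: float = 0.2,
) -> DistortionProfile:
    """Measure inter-protofilament rotations by independent template docking.

    The single-protofilament ``template`` is registered to each traced
    protofilament by searching a rotation about the tubule axis (plus axial
    shift freedom) that maximises the masked normalised cross-correlation;
    adjacent fitted azimuths are differenced.  A protofilament whose best
    correlation stays below ``corr_floor`` is flagged low-confidence, not
    dropped.
    """
    if template_mask is None:
        template_mask = make_mask_from_density(
            template, threshold=mask_threshold, extend=2.0, soft_edge=3.0
        )
    if center is None:
        # the ellipse-fit centre of the traced ring is a much better axis
        # estimate than the projection centroid (sub-voxel accurate)
        c3 = dmap.center.copy()
        c3[:2] = fit_ellipse(trace.points).center
    else:
        c3 = np.asarray(center, dtype=float).reshape(3)

    # reference = template values under the mask; candidates sample the map
    sampler = _MaskedSampler(dmap, template_mask, order=3)
    tpl_sampler_vals = template.grid[template_mask.grid > 1e-3]
    sampler.ref_vals = tpl_sampler_vals

    # azimuth of the template's own centre of mass about the axis
    idx = np.argwhere(template.grid > 0.05 * template.grid.max())
    vals = template.grid[tuple(idx.T)]
    com_xyz = (template.index_to_phys(idx) * vals[:, None]).sum(axis=0) / vals.sum()
    phi_t = np.rad2deg(np.arctan2(com_xyz[1] - c3[1], com_xyz[0] - c3[0]))

    dz_half = search.dz_half if search.dz_half is not None else monomer_rise / 2.0 + 2.0

    def ncc_at(phi: float, dz: float) -> float:
        op = SymOperator(index=1, psi_deg=phi, dz=dz)
        return sampler.ncc(operator_to_transform(op, c3))

    n = len(trace.points)
    fitted = np.zeros(n)
    corrs = np.zeros(n)
    for i in range(n):
        phi0 = trace.azimuths_deg[i] - phi_t
        # separable coarse stage: the protofilament column is straight, so
        # azimuth and axial registration decouple.  Register axially first
        # (the traced azimuth is already close), then in azimuth.
        dzs = np.arange(-dz_half, dz_half + 1e-9, search.dz_coarse)
        best_dz = max(dzs, key=lambda d: ncc_at(phi0, d))
        phis = phi0 + np.arange(-search.phi_half, search.phi_half + 1e-9, search.phi_coarse)
        best_phi = max(phis, key=lambda p: ncc_at(p, best_dz))
        fine_p = best_phi + np.arange(-search.phi_coarse, search.phi_coarse + 1e-9, search.phi_fine)
        fine_d = best_dz + np.arange(-search.dz_coarse, search.dz_coarse + 1e-9, search.dz_fine)
        best = (-np.inf, best_phi, best_dz)
        for p in fine_p:
            for d in fine_d:
                v = ncc_at(p, d)
                if v > best[0]:
                    best = (v, p, d)
        corrs[i] = best[0]
        fitted[i] = best[1] + phi_t

    angles = np.mod(np.roll(fitted, -1) - fitted, 360.0)
    ell = fit_ellipse(trace.points)
    return DistortionProfile(
        angles_deg=angles,
        mean_deg=float(angles.mean()),
        sd_deg=float(angles.std(ddof=1)),
        fitted_azimuths_deg=fitted,
        correlations=corrs,
        low_confidence=corrs < corr_floor,
        ellipse=ell,
        wrap_index=n - 1,
        trace=trace,
    )


@dataclass
class DecorationProfile:
    """Per-protofilament decorator volume above threshold (Angstrom^3) and
    the same normalised to the best-decorated protofilament."""

    volumes_A3: np.ndarray
    relative: np.ndarray
    threshold: float | None
    mode: Literal["voxel", "integrated"]
    flagged_empty: bool


def measure_decoration(
    dmap: DensityMap,
    zones: Sequence[SoftMask],
    threshold: float | None,
    mode: Literal["voxel", "integrated"] = "voxel",
) -> DecorationProfile:
    """Zoned decorator density at a set absolute threshold.

    ``voxel`` mode counts voxels >= threshold times voxel volume (the zoned-
    volume-at-threshold recipe); ``integrated`` sums intensity above the
    threshold instead.  ``threshold=None`` with ``integrated`` sums the
    signed intensity over the whole zone — the only estimator that is
    strictly linear in decorator occupancy, hence the right choice for
    quantitative regression (zero-mean noise cancels in the sum).
    """
    if threshold is None and mode != "integrated":
        raise ParameterError("threshold=None requires integrated mode")
    supports = [z.grid > 0.5 for z in zones]
    if len(supports) >= 2:
        counts = np.zeros(dmap.shape, dtype=np.int16)
        for s in supports:
            if s.shape != dmap.shape:
                raise ParameterError("zone geometry does not match the map")
            counts += s
        min_vol = min(s.sum() for s in supports)
        overlap = (counts > 1).sum()
        if overlap > 0.01 * min_vol:
            warnings.warn(
                f"decorator zones overlap on {overlap} voxels (> 1% of a zone)", stacklevel=2
            )
    vol = dmap.voxel_size**3
    vals = []
    for s in supports:
        if mode == "voxel":
            vals.append((dmap.grid[s] >= threshold).sum() * vol)
        elif threshold is None:
            vals.append(float(dmap.grid[s].sum()) * vol)
        else:
            vals.append(float(np.clip(dmap.grid[s] - threshold, 0.0, None).sum()) * vol)
    vals = np.asarray(vals, dtype=float)
    peak = vals.max()
    flagged = peak <= 0
    rel = np.clip(vals / peak, 0.0, 1.0) if peak > 0 else np.zeros_like(vals)
    return DecorationProfile(
        volumes_A3=vals, relative=rel, threshold=threshold, mode=mode, flagged_empty=flagged
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def regress_decoration_vs_curvature(
    angles: Sequence[float], decorations: Sequence[float]
) -> RegressionResult:
    """Ordinary least squares of decoration (Y) on local angle (X, degrees)."""
    x = np.asarray(angles, dtype=float)
    y = np.asarray(decorations, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("angles and decorations must be equal-length 1D")
    if len(x) < 3:
        raise ParameterError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise RegressionError("zero variance in the predictor (angles)")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y.mean()), 0.0, len(x))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


@dataclass
class CurvatureDecorationReport:
    distortion: DistortionProfile
    decoration: DecorationProfile
    regression: RegressionResult
    paired_angles_deg: np.ndarray  # angle paired with each protofilament zone
    zone_to_trace: np.ndarray  # trace index matched to each zone
    metadata: dict

    def table(self):
        """Per-protofilament TSV-ready table (pandas DataFrame)."""
        import pandas as pd

        n = len(self.decoration.relative)
        tr = self.zone_to_trace
        return pd.DataFrame(
            {
                "pf_index": np.arange(n),
                "azimuth_deg": self.distortion.fitted_azimuths_deg[tr],
                "angle_deg": self.paired_angles_deg,
                "low_confidence": self.distortion.low_confidence[tr],
                "decoration_abs": self.decoration.volumes_A3,
                "decoration_rel": self.decoration.relative,
            }
        )

    def to_tsv(self, path: str) -> None:
        self.table().to_csv(path, sep="\t", index=False, float_format="%.4f")


def _zone_azimuth(zone: SoftMask) -> float:
    idx = np.argwhere(zone.grid > 0.5)
    xyz = zone.index_to_phys(idx).mean(axis=0)
    c = zone.center
    return float(np.rad2deg(np.arctan2(xyz[1] - c[1], xyz[0] - c[0])))


def curvature_decoration_report(
    dmap: DensityMap,
    template: DensityMap,
    zones: Sequence[SoftMask],
    n_pf: int | None = None,
    handedness: Literal["left", "right"] = "left",
    lowpass: float | None = 10.0,
    trace_threshold: float = 0.3,
    deco_threshold: float | None = None,
    deco_threshold_sigma: float = 5.0,
    deco_mode: Literal["voxel", "integrated"] = "integrated",
    monomer_rise: float = 41.1465,
    search: AngleSearch = AngleSearch(),
) -> CurvatureDecorationReport:
    """Orchestrate tracing, angle measurement, decoration and regression.

    The map (and template) are lowpass filtered first (default 10 A) so the
    thresholded decoration count is not dominated by voxel-level noise.  The
    decoration threshold defaults to ``deco_threshold_sigma`` times the
    map's robust (MAD) sigma.  Each decorator zone is matched to the nearest
    fitted protofilament azimuth and paired with the inter-protofilament
    angle of the junction on the protofilament's lattice-winding side (set
    by ``handedness``), then decoration is regressed on angle.
    """
    if n_pf is None:
        n_pf = len(zones)
    work = lowpass_filter(dmap, lowpass) if lowpass else dmap
    tpl = lowpass_filter(template, lowpass) if lowpass else template
    trace = trace_protofilaments(work, n_pf, threshold=trace_threshold)
    distortion = measure_pf_angles(
        work, tpl, trace, monomer_rise=monomer_rise, search=search
    )
    if deco_threshold is None and deco_mode == "voxel":
        # set threshold from the map's robust (MAD) sigma
        med = np.median(work.grid)
        mad = np.median(np.abs(work.grid - med))
        deco_threshold = float(med + deco_threshold_sigma * 1.4826 * mad)
    decoration = measure_decoration(work, zones, deco_threshold, mode=deco_mode)

    zone_az = np.array([_zone_azimuth(z) for z in zones])
    fitted = distortion.fitted_azimuths_deg
    zone_to_trace = np.array(
        [int(np.argmin(np.abs((fitted - a + 180.0) % 360.0 - 180.0))) for a in zone_az]
    )
    # angles_deg[i] spans traced PFs i -> i+1 counter-clockwise; the junction
    # on a left-handed lattice's winding side is the one entering the PF
    # clockwise, i.e. angle index i-1
    n = len(fitted)
    if handedness == "left":
        pair_idx = (zone_to_trace - 1) % n
    else:
        pair_idx = zone_to_trace
    paired = distortion.angles_deg[pair_idx]
    regression = regress_decoration_vs_curvature(paired, decoration.relative)
    meta = {
        "lowpass_A": lowpass,
        "trace_threshold": trace_threshold,
        "deco_threshold": deco_threshold,
        "deco_mode": deco_mode,
        "n_pf": n_pf,
        "handedness": handedness,
        "trace_method": trace.method,
    }
    return CurvatureDecorationReport(
        distortion=distortion,
        decoration=decoration,
        regression=regression,
        paired_angles_deg=paired,
        zone_to_trace=zone_to_trace,
        metadata=meta,
    )
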