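# Methods

## The lattice model

A microtubule is modelled as N protofilaments (default N = 13) of
alpha/beta-tubulin dimers. Along one protofilament, dimers repeat every
`dimer_rise` Angstrom (default 82.293 A, the refined value for GDP-taxol
lattices); the monomer repeat is half that, 41.147 A. Laterally, stepping
from one protofilament to the next is a rotation of 360/N degrees about the
tubule axis plus an axial rise of

    rise_per_pf = dimer_rise * starts_dimers / N

where `starts_dimers` is the helical start number expressed in dimers per
360-degree turn (1.5 for the canonical 3-start monomer lattice; 9.495 A per
step for N = 13). Because 1.5 is not an integer, one full turn accumulates
1.5 dimers of rise: the lattice cannot close with like-for-like contacts and
exactly one lateral junction — the seam — pairs an alpha monomer with a
beta monomer. `seam_mismatch` returns this fractional dimer offset
(`starts_dimers mod 1`); 0 means a seamless lattice, 0.5 the canonical
heterotypic seam.

The sign convention: psi is measured right-handed about +z, and the default
`handedness="left"` steps protofilament-to-protofilament in the negative
direction (psi = -27.69 deg for N = 13) when the tubule is viewed plus-end
up. Handedness is stored explicitly; flipping it negates every psi and
leaves the rises unchanged.

Operators are stored in physical units (degrees, Angstrom) and converted to
pixels only at file I/O. In STAR files, angles and translations are written
to 3 decimal places, which makes a write-read-write cycle byte-stable; a
header comment and a bookkeeping block record whether origins are Angstrom
or pixels.

## Local-symmetry averaging

`apply_local_symmetry` takes a map, a soft [0,1] mask delimiting one
asymmetric unit (one protofilament column plus, optionally, its decorator),
and the operator table. For each included operator k the masked region is
*gathered* — the map is resampled at the operator-transformed location and
brought back to the reference frame — the gathered copies are averaged, and
the average is *scattered* back to every copy's location. Voxels outside
all transformed mask supports are untouched; where transformed supports
overlap, per-voxel weight normalisation applies (overlap beyond 5% of the
mask volume emits a warning, not an error — distorted lattices create mild
overlaps). Seam-adjacent protofilaments can be withheld from the average
via `excluded_indices`; the number actually averaged is the `fold`
(13 for an ideal tubule, 9 when the seam region is excluded).

Averaging f independent copies multiplies the signal-to-noise ratio by
sqrt(f). Making that law *measurable* dictated the resampling scheme:
cardinal-spline interpolation of white noise destroys 25-45% of its
variance (measured on this implementation), which would make the averaged
noise look over-reduced. The gather step therefore uses a Fourier
resampler by default: the in-plane rotation is decomposed into three FFT
phase-ramp shears (plus exact 90-degree array rotations for large angles)
and translations are pure phase ramps. This is an all-pass operation —
white-noise variance retention is ~0.97-0.98, and round-tripping a smooth
map through rotate/unrotate errs at ~1e-9. Its one caveat is circular
wrap-around at the box edge, so the lattice must keep a margin of about 8%
of the half-box (the worst-case shear excursion) — the synthetic defaults
respect this. Cubic and trilinear real-space resampling remain available
(`interpolation=`), and operators with out-of-axis tilt/rot components fall
back to the cubic path automatically.

The scatter step resamples the *smooth average* and the *mask* separately
(mask via cubic spline — pushing a near-binary mask through the Fourier path
would ring at its edge) and uses the same transformed-mask field both to
blend the average in and to blend the original out. At a voxel where the
average equals the map, mask-resampling error then cancels identically;
this is what makes the operation an honest fixed point on an already
symmetric map (deviation < 1e-3 of the map maximum) and idempotent to the
same tolerance.

The asymmetric-unit mask built by `make_pf_mask` is thresholded from a
noiseless single-protofilament render, dilated, given a cosine soft edge
(relion_mask_create-style), and then *tapered axially* to the monomer-column
span: the unit is one lattice repeat, and keeping the Gaussian tails beyond
the top monomer would push the highest protofilament's copy outside the box.

## Operator refinement

`refine_operators` adjusts each non-identity operator independently to
maximise the mask-weighted normalised cross-correlation between the
reference unit (map values under the mask) and the map sampled at the
perturbed-operator-transformed support. The schedule is an exhaustive
coarse grid (default 0.5 deg / 0.5 A over the caller's search ranges)
followed by a fine grid (0.1 deg / 0.1 A) around the coarse optimum.
Candidates are visited smallest-adjustment-first and must improve strictly,
so ties break toward the smallest change and the unperturbed operator is
always a candidate — the objective never decreases. Sampling uses cubic
spline interpolation over the mask support only (the map is spline-filtered
once); noise-variance fidelity is irrelevant for a correlation search, and
this path is ~20x faster than transforming full volumes.

## FSC and filtering

`compute_fsc` is the standard shell-wise normalised complex correlation of
the two half-map Fourier transforms (optionally mask-multiplied), with
shells one Fourier voxel wide; `resolution_at(t)` interpolates the first
crossing below the threshold linearly in frequency and returns its inverse.
If the curve never crosses, the finest sampled shell is returned — "at
least this good". `lowpass_filter` applies a raised-cosine edge (default
two shells wide) beyond 1/cutoff and preserves the DC term exactly.

## The synthetic generator

`simulate_map` renders monomers as isotropic 3D Gaussians (sigma 5 A,
normalised so the voxel sum carries the point weight) at the closed-form
lattice coordinates; protofilament k is axially offset by
`((k - seam_index) mod N) * rise_per_pf`, which makes the heterotypic
junction land at `seam_index` and — for `seam_index = 0` — makes the map
*exactly* N-fold locally symmetric under the ideal operators (the
fixed-point tests rely on this). Alpha and beta monomers have equal weight
by default, so the seam is geometric rather than visible; an optional
alpha/beta weight contrast supports seam-detection experiments.

Defaults: a 160^3 box at 2 A/voxel, protofilament-centre radius 115 A
(matching a ~250 A decorated-tubule footprint), and **two** axial dimer
repeats. Two rather than three: the 13-step axial ladder spans
12 x 9.495 = 113.9 A on its own, and three 82.3 A repeats on top of it no
longer fit a 320 A box; two repeats still cover two full dimer periods.
A render takes a few seconds on one CPU.

Cross-section distortion comes in two mutually exclusive flavours:

* `pf_angles`: an explicit list of N inter-protofilament angles (must sum
  to 360), protofilament k placed at the cumulative azimuth;
* `ellipse_ratio` e: centres placed at equal parametric angles on an
  ellipse with axes `radius/sqrt(e)` and `radius*sqrt(e)` (geometric-mean
  radius preserved), so the fitted ellipticity equals e exactly and the
  polar-angle spacing varies around 360/N.

Individual protofilaments can additionally be nudged (`pf_azimuth_offsets`,
`pf_z_offsets`) — this is how operator-recovery truth is injected. The
ground truth records exact coordinates, angles, ellipticity, occupancies and
the *true operator set* (for distorted lattices the operator carries a small
in-plane dx/dy correcting the radius change, since an elliptical ring is not
rotation-symmetric).

The decorator emulates an MTBD: one larger Gaussian (sigma 8 A, weight 3)
per dimer at the intradimer interface, displaced 25 A radially outward,
intensity-weighted by a per-protofilament occupancy in [0,1]. Occupancy
weighting is deterministic by design (tests first); Bernoulli site sampling
is deliberately not the default. Noise is i.i.d. Gaussian added voxel-wise
under an explicit seed; half maps share the signal and draw noise from
(seed, seed+1). In tests, "SNR x" means `noise_sigma = peak_signal / x`.

What the generator does **not** emulate: CTF and defocus effects, projection
image formation, per-particle alignment error, atomic-detail density,
solvent background, B-factor envelopes, or doublet/B-tubule geometry.
Passing tests therefore demonstrate the correctness of the geometry,
averaging, registration and measurement machinery on ideal tubules — not
performance on experimental reconstructions, where alignment error and
resolution anisotropy add variance the suite does not model.

## Distortion and decoration analysis

`trace_protofilaments` projects the map along z (maximum intensity),
binarises at a fraction of the projection maximum, and takes
intensity-weighted component centroids. If thresholding does not yield
exactly N components (merged or split blobs), it falls back to
intensity-weighted centroids per angular sector of width 360/N about the
projection centroid, with sector boundaries anchored half a sector before
the brightest pixel. A projection with no contrast is a detection error.

`measure_pf_angles` registers a single-protofilament template to each
traced protofilament independently — a rotation about the tubule axis plus
axial shift freedom — and differences the fitted azimuths; adjacent-angle
sums close to 360 degrees by construction. The axis defaults to the
ellipse-fit centre of the traced ring, which is sub-voxel accurate (the raw
projection centroid is biased by ~0.5 A and visibly tilts the angle
profile). The axial search half-window defaults to half a monomer spacing
plus 2 A: protofilament identities (hence absolute lattice offsets) are
unknown at analysis time, but a straight column's azimuth is insensitive to
axial misregistration by whole monomers, so searching one monomer period is
sufficient and keeps every protofilament registrable. The search is
separable-coarse (axial first at the traced azimuth, then azimuthal) plus a
fine 2D grid; a brute-force 0.05-degree scan agrees within 0.1 deg on test
maps. Registrations whose correlation stays below `corr_floor` (default
0.2) are flagged low-confidence, never dropped. The angle between the last
and first protofilament crosses the seam's extra axial rise and is flagged
by `wrap_index`.

`fit_ellipse` is a direct least-squares conic fit constrained to an ellipse
(points centred and scaled first for conditioning); ellipticity is the
short/long diameter ratio, <= 1. `measure_decoration` supports two modes:

* `voxel` (default for the standalone function): count of zone voxels at or
  above an absolute threshold, times voxel volume — the zoned-volume
  recipe. Faithful, but *nonlinear* in occupancy: for a Gaussian blob the
  volume above threshold grows as `(ln(A/t))^{3/2}`, which in measurements
  on this generator inflates a decoration-vs-angle slope by roughly 2x.
* `integrated`, and with `threshold=None` the signed intensity integral
  over the zone — the only estimator strictly linear in occupancy, with
  zero-mean noise cancelling in the sum. The report orchestrator defaults
  to this mode for exactly that reason.

`curvature_decoration_report` lowpass-filters map and template (default
10 A — at low SNR voxel-level noise otherwise dominates any thresholded
measure; reconstruction averages are effectively filtered anyway), traces,
registers, fits the ellipse, measures decoration per zone, pairs each
protofilament's decoration with the inter-protofilament angle of the
junction on its lattice-winding side (set by handedness), and regresses
relative decoration on angle by ordinary least squares. All thresholds and
modes used are echoed in the report metadata and in each CLI run's
`.meta.json` sidecar.

## Numerical choices and degenerate inputs

* Stochastic steps always take an explicit seed (generator default 0);
  regenerating from the same spec is bit-exact.
* Flat (zero-variance) masked regions are a degenerate-correlation error;
  uniform projections a detection error; collinear points an ellipse-fit
  error; zero predictor variance a regression error. A constant decoration
  vector regresses to slope 0 with R^2 = 0 rather than erroring.
* A decoration threshold above the map maximum yields an all-zero, flagged
  profile.
* Operator angles are normalised to (-360, 360]; transforms round-trip with
  their inverses to 1e-10.
* MRC output is mode-2 float32 with the voxel size in the cell header and
  the physical origin in the MRC2014 ORIGIN words.

## Known limitations

* The Fourier resampler assumes z-axis rotations and an adequate box
  margin; arbitrary tilted operators use cubic interpolation, where the
  sqrt(fold) noise law holds only approximately.
* Protofilament identity assignment in the report matches zones to fitted
  azimuths; it assumes the map is not rotated by more than half an
  inter-protofilament angle relative to the zone table.
* `trace_protofilaments` requires the tubule axis roughly parallel to z;
  pre-alignment is the caller's job.
* Analysis defaults are tuned for maps in the 2 A/voxel, 100-150 A radius
  regime of the synthetic defaults; very different scales may need explicit
  search ranges and thresholds.
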