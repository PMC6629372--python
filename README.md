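# mtseam

Local-symmetry averaging and cross-section distortion analysis for
pseudo-helical microtubule density maps with a seam.

## The problem

A canonical 13-protofilament microtubule is *almost* helical: stepping from
one protofilament to the next is a rotation of 360/13 = 27.69 degrees about
the tubule axis plus an axial rise of 82.293 x 1.5/13 = 9.495 A. But the
3-start monomer lattice closes a full turn with 1.5 tubulin dimers of rise,
so exactly one lateral junction — the seam — pairs alpha-tubulin with
beta-tubulin. Helical symmetry averaging would smear the seam away;
instead, cryo-EM reconstructions of such tubules use *local,
non-point-group symmetry*: an explicit table of rigid operators

    psi_k = -k * 360/N        (degrees, about the tubule axis)
    dz_k  =  k * r * S / N    (A;  r = dimer rise, S = starts in dimers)

that superimposes the N tubulin units so they can be averaged, raising the
signal-to-noise ratio by sqrt(fold). Decorating proteins need not share the
tubulin fold (a decorator that skips the seam is averaged 12-fold against
tubulin's 13), and seam-adjacent protofilaments can be excluded (a 9-fold
average) when the seam is poorly aligned.

The package serves structural biologists who process such maps: it builds
and refines the operator tables (RELION local-symmetry STAR dialect),
applies the averaging to maps and half maps (MRC2014), validates with
masked FSC, and quantifies what a decorator does to the tubule
cross-section — per-protofilament angles measured by template docking,
ellipticity b/a from a least-squares ellipse fit to protofilament centres,
per-protofilament decoration levels, and the ordinary least-squares
regression of relative decoration Y on local inter-protofilament angle X
(reported as slope, intercept, R^2, N). A built-in, fully ground-truthed
synthetic tubule generator (seam included, distortion and decorator
occupancy controllable) makes the whole pipeline testable without any
experimental data.

## Worked example

```python
import numpy as np
import mtseam as ms

# operator table for the canonical lattice
ops = ms.make_operators(ms.LatticeSpec(n_pf=13, dimer_rise=82.293, starts_dimers=1.5))
print(round(ops.operators[1].psi_deg, 2), round(ops.operators[1].dz, 3))
# -27.69 9.495

# a synthetic 13-PF tubule, squashed to an elliptical cross-section
dmap, truth = ms.simulate_map(ms.SyntheticSpec(ellipse_ratio=0.936))
trace = ms.trace_protofilaments(dmap, n_pf=13, threshold=0.3)
print(round(ms.fit_ellipse(trace.points).ellipticity, 3))
# 0.936

# noisy map: 13-fold averaging cuts masked noise sigma by sqrt(13)
spec = ms.SyntheticSpec(box=128, voxel_size=2.0, radius=85.0, n_repeats=2)
clean, truth = ms.simulate_map(spec)
mask = ms.make_pf_mask(spec, threshold=0.1, extend=3.0, soft_edge=8.0)
sigma = 0.25 * clean.grid.max()
noisy = clean.with_grid(clean.grid + sigma * np.random.default_rng(17).standard_normal(clean.shape))
sym = ms.apply_local_symmetry(noisy, mask, truth.operators)
ref = ms.apply_local_symmetry(clean, mask, truth.operators)
support = mask.grid > 0.9
print(round(sigma / (sym.grid - ref.grid)[support].std(), 2), round(np.sqrt(13), 2))
# 3.64 3.61
```

The same workflow from the shell:

```
mtseam make-operators --n-pf 13 --dimer-rise 82.293 --starts 1.5 -o ops.star
mtseam simulate --decorate --noise-sigma 2e-4 --seed 1 -o tub
mtseam apply --map tub.mrc --mask mask.mrc --operators tub_operators.star -o sym.mrc
mtseam analyze --map sym.mrc --ground-truth tub_truth.json -o report
```

`analyze` prints a per-protofilament table (angle, decoration) and the
regression line, e.g. `decoration-vs-angle slope -0.0555 /deg (R^2 0.911,
N 13)` on a map generated with occupancy falling linearly in local angle.
Every command writes a `.meta.json` sidecar with parameters, seed, version
and output checksums, sufficient to regenerate the run.

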