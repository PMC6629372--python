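"""MRC2014 map and STAR operator-table I/O.

Maps are written as mode-2 float MRC with the voxel size in the cell header
and the physical origin in the MRC2014 ORIGIN words.  Operator tables use
the RELION local-symmetry STAR dialect: one data block holding a loop with
``_rlnAngleRot/_rlnAngleTilt/_rlnAnglePsi/_rlnOriginX/Y/Z`` columns, plus a
bookkeeping block recording the lattice, the excluded indices and whether
origins are Angstrom or pixels.  Values are written to 3 decimal places so a
write-read-write cycle is byte-stable.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .errors import GeometryError, ParameterError
from .lattice import LatticeSpec, OperatorSet, SymOperator
from .volume import DensityMap, SoftMask

__all__ = ["read_mrc", "write_mrc", "read_operators_star", "write_operators_star"]

_OPERATOR_COLUMNS = ("AngleRot", "AngleTilt", "AnglePsi", "OriginX", "OriginY", "OriginZ")


def write_mrc(volume: DensityMap | SoftMask, path: str | Path) -> None:
    """Write a map (or mask) as MRC2014 mode-2 float."""
    nz, ny, nx = volume.shape
    vs = volume.voxel_size
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(grid)[...] = volume.grid.T.astype(np.float32)  # (z,y,x) -> (x,y,z)
    grid.unit_cell = gemmi.UnitCell(nx * vs, ny * vs, nz * vs, 90.0, 90.0, 90.0)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), volume.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 map; requires isotropic voxels."""
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))
    arr = np.array(m.grid, copy=True).T.astype(np.float64)  # (x,y,z) -> (z,y,x)
    if np.isnan(arr).any():
        raise GeometryError(f"{path}: map does not cover its unit cell")
    sp = m.grid.spacing
    if max(sp) - min(sp) > 1e-3 * max(sp):
        raise GeometryError(f"{path}: anisotropic voxel size {sp} is not supported")
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    return DensityMap(arr, float(np.mean(sp)), origin)


def write_operators_star(
    ops: OperatorSet,
    path: str | Path,
    origin_unit: str = "angstrom",
    voxel_size: float | None = None,
    block_name: str = "local_symmetry_operators",
) -> None:
    """Write an operator table in the RELION local-symmetry STAR dialect.

    ``origin_unit="pixels"`` converts translations using ``voxel_size`` for
    interchange with tools that expect pixel origins.
    """
    if origin_unit not in ("angstrom", "pixels"):
        raise ParameterError("origin_unit must be 'angstrom' or 'pixels'")
    scale = 1.0
    if origin_unit == "pixels":
        if voxel_size is None or voxel_size <= 0:
            raise ParameterError("pixel origins require a positive voxel_size")
        scale = 1.0 / voxel_size

    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    loop = block.init_loop("_rln", list(_OPERATOR_COLUMNS))
    for op in ops.operators:
        loop.add_row(
            [
                f"{op.rot_deg:.3f}",
                f"{op.tilt_deg:.3f}",
                f"{op.psi_deg:.3f}",
                f"{op.dx * scale:.3f}",
                f"{op.dy * scale:.3f}",
                f"{op.dz * scale:.3f}",
            ]
        )
    lat = ops.lattice
    meta = doc.add_new_block("mtseam_lattice")
    meta.set_pair("_mtseamNPf", str(lat.n_pf))
    meta.set_pair("_mtseamDimerRise", f"{lat.dimer_rise:.6f}")
    meta.set_pair("_mtseamStartsDimers", f"{lat.starts_dimers:.6f}")
    meta.set_pair("_mtseamHandedness", lat.handedness)
    meta.set_pair("_mtseamSeamIndex", str(lat.seam_index))
    meta.set_pair("_mtseamOriginUnit", origin_unit)
    meta.set_pair(
        "_mtseamExcludedIndices",
        ",".join(str(i) for i in sorted(ops.excluded_indices)) or "none",
    )
    header = (
        f"# mtseam local-symmetry operators; origins are in {origin_unit}\n"
        "# psi rotates about the tubule (z) axis; identity operator first\n"
    )
    Path(path).write_text(header + doc.as_string())


def read_operators_star(
    path: str | Path,
    voxel_size: float | None = None,
    lattice: LatticeSpec | None = None,
) -> OperatorSet:
    """Read an operator STAR file (mtseam or plain RELION dialect).

    Files without the bookkeeping block need ``lattice`` supplied (and are
    assumed to use Angstrom origins unless ``voxel_size`` is given together
    with a pixel-unit file).
    """
    doc = gemmi.cif.read_file(str(path))
    meta = doc.find_block("mtseam_lattice")
    origin_unit = "angstrom"
    excluded: frozenset[int] = frozenset()
    if meta is not None:
        lattice = LatticeSpec(
            n_pf=int(meta.find_value("_mtseamNPf")),
            dimer_rise=float(meta.find_value("_mtseamDimerRise")),
            starts_dimers=float(meta.find_value("_mtseamStartsDimers")),
            handedness=meta.find_value("_mtseamHandedness"),
            seam_index=int(meta.find_value("_mtseamSeamIndex")),
        )
        origin_unit = meta.find_value("_mtseamOriginUnit")
        exc = meta.find_value("_mtseamExcludedIndices")
        if exc and exc != "none":
            excluded = frozenset(int(t) for t in exc.split(","))
    if lattice is None:
        raise ParameterError(
            f"{path}: no lattice bookkeeping block; pass lattice= explicitly"
        )
    scale = 1.0
    if origin_unit == "pixels":
        if voxel_size is None or voxel_size <= 0:
            raise ParameterError(f"{path}: pixel origins require voxel_size")
        scale = voxel_size

    block = next(
        (b for b in doc if b.name != "mtseam_lattice" and b.find_loop("_rlnAnglePsi")), None
    )
    if block is None:
        raise ParameterError(f"{path}: no _rlnAnglePsi operator loop found")
    cols = [list(block.find_loop(f"_rln{c}")) for c in _OPERATOR_COLUMNS]
    n_rows = len(cols[2])
    if any(len(c) not in (0, n_rows) for c in cols):
        raise ParameterError(f"{path}: ragged operator loop")
    ops = []
    for k in range(n_rows):
        get = lambda j: float(cols[j][k]) if cols[j] else 0.0
        ops.append(
            SymOperator(
                index=k,
                rot_deg=get(0),
                tilt_deg=get(1),
                psi_deg=get(2),
                dx=get(3) * scale,
                dy=get(4) * scale,
                dz=get(5) * scale,
            )
        )
    return OperatorSet(lattice, tuple(ops), excluded)
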