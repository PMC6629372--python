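"""Seam-containing microtubule lattice geometry and local-symmetry operators.

A microtubule built from N protofilaments with S helix starts (expressed in
tubulin *dimers* per 360-degree turn, 1.5 for the canonical 3-start monomer
lattice) is only pseudo-helical: stepping from one protofilament to the next
is a rotation of 360/N degrees about the tubule axis plus an axial rise of
``dimer_rise * starts_dimers / n_pf``.  Going all the way around accumulates a
non-integer number of dimers whenever ``starts_dimers`` is non-integer, which
forces one lateral junction — the seam — to make heterotypic (alpha-to-beta)
contacts.  Local, non-point-group symmetry averaging therefore uses an
explicit table of rigid operators rather than a helical symmetry group; this
module produces, composes and (de)serialises those operators.

Angles are degrees, translations are Angstroms throughout; conversion to
pixels happens only at file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import InvalidLatticeError, ParameterError

__all__ = [
    "LatticeSpec",
    "SymOperator",
    "OperatorSet",
    "RigidTransform",
    "make_operators",
    "seam_mismatch",
    "operator_to_transform",
]


def _wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into (-360, 360] preserving its winding sign."""
    a = float(a)
    if a > 360.0:
        a = a % 360.0
    elif a <= -360.0:
        a = -(-a % 360.0)
    return a + 0.0  # normalises -0.0


@dataclass(frozen=True)
class LatticeSpec:
    """Geometric model of an N-protofilament, S-start microtubule lattice.

    Parameters
    ----------
    n_pf:
        Number of protofilaments (13 for the canonical microtubule).
    dimer_rise:
        Axial spacing in Angstrom between tubulin dimers along one
        protofilament (82.293 for GDP-taxol lattices).
    starts_dimers:
        Helical start number in dimers per 360-degree turn; 1.5 for the
        3-start monomer helix.  Non-integer values imply a seam.
    handedness:
        Direction of the protofilament-to-protofilament rotation about +z;
        ``"left"`` reproduces the conventional negative psi step when the
        tubule is viewed plus-end-up.
    seam_index:
        Protofilament index k in [0, n_pf) such that the lateral junction
        between protofilaments k-1 and k is the heterotypic seam.
    """

    n_pf: int = 13
    dimer_rise: float = 82.293
    starts_dimers: float = 1.5
    handedness: Literal["left", "right"] = "left"
    seam_index: int = 0

    def __post_init__(self) -> None:
        if int(self.n_pf) != self.n_pf or self.n_pf < 2:
            raise InvalidLatticeError(f"n_pf must be an integer >= 2, got {self.n_pf}")
        if not (self.dimer_rise > 0):
            raise InvalidLatticeError(f"dimer_rise must be > 0, got {self.dimer_rise}")
        if not (self.starts_dimers > 0):
            raise InvalidLatticeError(
                f"starts_dimers must be > 0, got {self.starts_dimers}"
            )
        if self.handedness not in ("left", "right"):
            raise InvalidLatticeError(f"handedness must be 'left' or 'right'")
        if not (0 <= self.seam_index < self.n_pf):
            raise InvalidLatticeError(
                f"seam_index {self.seam_index} outside [0, {self.n_pf})"
            )

    @property
    def psi_step(self) -> float:
        """Signed protofilament-to-protofilament rotation in degrees."""
        sign = -1.0 if self.handedness == "left" else 1.0
        return sign * 360.0 / self.n_pf

    @property
    def rise_per_pf(self) -> float:
        """Axial rise in Angstrom between laterally adjacent protofilaments."""
        return self.dimer_rise * self.starts_dimers / self.n_pf

    @property
    def has_seam(self) -> bool:
        return seam_mismatch(self) != 0.0


@dataclass(frozen=True)
class SymOperator:
    """One rigid local-symmetry operator: z-rotation plus translation.

    ``psi_deg`` rotates about the tubule (z) axis; ``dz`` is the axial shift
    in Angstrom.  ``dx, dy`` and the out-of-axis Euler angles ``tilt_deg,
    rot_deg`` are zero for an ideal lattice and only become nonzero after
    refinement against a distorted map.
    """

    index: int
    psi_deg: float = 0.0
    dz: float = 0.0
    dx: float = 0.0
    dy: float = 0.0
    tilt_deg: float = 0.0
    rot_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("psi_deg", "dz", "dx", "dy", "tilt_deg", "rot_deg"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ParameterError(f"operator field {name} is not finite: {v}")
        object.__setattr__(self, "psi_deg", _wrap_angle(self.psi_deg))

    @property
    def is_identity(self) -> bool:
        return all(
            getattr(self, f) == 0.0
            for f in ("psi_deg", "dz", "dx", "dy", "tilt_deg", "rot_deg")
        )

    @property
    def is_axial(self) -> bool:
        """True when the operator is a pure z-rotation plus translation."""
        return self.tilt_deg == 0.0 and self.rot_deg == 0.0


@dataclass(frozen=True)
class OperatorSet:
    """Ordered operator table with seam-adjacent exclusions.

    ``fold`` is the number of copies actually averaged, i.e. operators whose
    index is not excluded.  Excluding 4 of 13 protofilaments (the seam pair
    plus flanks) gives the 9-fold averaging used for strongly distorted
    seam-blurred maps.
    """

    lattice: LatticeSpec
    operators: tuple[SymOperator, ...]
    excluded_indices: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        idx = [op.index for op in self.operators]
        if len(set(idx)) != len(idx):
            raise ParameterError("operators must be unique by index")
        bad = set(self.excluded_indices) - set(idx)
        if bad:
            raise ParameterError(f"excluded indices {sorted(bad)} not in operator table")
        object.__setattr__(self, "operators", tuple(self.operators))
        object.__setattr__(self, "excluded_indices", frozenset(self.excluded_indices))

    @property
    def fold(self) -> int:
        return len(self.operators) - len(self.excluded_indices)

    @property
    def included(self) -> tuple[SymOperator, ...]:
        return tuple(op for op in self.operators if op.index not in self.excluded_indices)

    def with_excluded(self, excluded: Iterable[int]) -> "OperatorSet":
        return OperatorSet(self.lattice, self.operators, frozenset(excluded))

    def replace_operator(self, op: SymOperator) -> "OperatorSet":
        ops = tuple(op if o.index == op.index else o for o in self.operators)
        return OperatorSet(self.lattice, ops, self.excluded_indices)


def make_operators(
    lattice: LatticeSpec,
    fold: int | Literal["all"] = "all",
    excluded: Iterable[int] = (),
) -> OperatorSet:
    """Build the ideal operator table for a lattice.

    Operator k carries ``psi = sign(handedness) * k * 360 / n_pf`` and
    ``dz = k * dimer_rise * starts_dimers / n_pf``; for the canonical
    13-protofilament lattice this is the familiar -27.69 degree / 9.495 A
    ladder.  ``fold`` limits the table to the first ``fold`` protofilaments;
    ``excluded`` marks indices withheld from averaging (they stay in the
    table so the file still documents the full lattice).
    """
    n = lattice.n_pf
    if fold == "all":
        fold = n
    if not (1 <= fold <= n):
        raise ParameterError(f"fold must be in [1, {n}], got {fold}")
    excluded = frozenset(int(e) for e in excluded)
    if any(e < 0 or e >= n for e in excluded):
        raise ParameterError(f"excluded indices must lie in [0, {n})")
    ops = tuple(
        SymOperator(
            index=k,
            psi_deg=_wrap_angle(lattice.psi_step * k),
            dz=lattice.rise_per_pf * k,
        )
        for k in range(fold)
    )
    return OperatorSet(lattice, ops, excluded & set(range(fold)))


def seam_mismatch(lattice: LatticeSpec) -> float:
    """Fractional dimer offset accumulated over one full turn, in [0, 1).

    0 means the lattice closes seamlessly; 0.5 (the 3-start case) means the
    closing junction pairs an alpha monomer with a beta monomer.
    """
    return float(lattice.starts_dimers % 1.0)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R x + t`` in physical (x, y, z) Angstrom."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one (3,) point or an (N, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-10) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=tol)
            and np.allclose(self.translation, other.translation, atol=tol)
        )


def _euler_zyz(rot_deg: float, tilt_deg: float, psi_deg: float) -> np.ndarray:
    """RELION-convention rotation matrix Rz(rot) @ Ry(tilt) @ Rz(psi)."""
    def rz(a):
        c, s = np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(a):
        c, s = np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(rot_deg) @ ry(tilt_deg) @ rz(psi_deg)


def operator_to_transform(op: SymOperator, center: Sequence[float]) -> RigidTransform:
    """Realise an operator as a rigid transform about a rotation centre.

    The rotation axis passes through ``center`` (physical Angstrom, normally
    the centre of the microtubule lumen); the translation (dx, dy, dz) is
    applied after the rotation:  ``x -> R (x - c) + c + t``.
    """
    c = np.asarray(center, dtype=float).reshape(3)
    R = _euler_zyz(op.rot_deg, op.tilt_deg, op.psi_deg)
    t = np.array([op.dx, op.dy, op.dz], dtype=float)
    return RigidTransform(R, c - R @ c + t)
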