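"""Unit-cell math and crystallographic symmetry-image search.

Fractional coordinates exist only inside this module; every public result is
Cartesian Å. The image search enumerates operator × lattice-shift combinations
in an integer box guaranteed to cover the requested radius for any cell shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .model import StructureModel, SymOp, UnitCell

# images closer than this to their source atom sit on a special position and
# would duplicate the atom in a cluster
SPECIAL_POSITION_TOL = 0.1


def fractionalize(position, cell: UnitCell) -> np.ndarray:
    """Cartesian Å → fractional. Accepts a triple or an (N, 3) array."""
    pos = np.asarray(position, dtype=float)
    return pos @ cell.fractionalization_matrix().T


def orthogonalize(fractional, cell: UnitCell) -> np.ndarray:
    """Fractional → Cartesian Å (a along x, b in the xy-plane)."""
    frac = np.asarray(fractional, dtype=float)
    return frac @ cell.orthogonalization_matrix().T


def axis_heights(cell: UnitCell) -> np.ndarray:
    """Perpendicular distance between lattice planes along each cell axis.

    height_i = V / area of the face spanned by the other two axes; this is
    the correct per-axis length scale for converting a Cartesian search
    radius into a number of lattice shifts, also for very oblique cells.
    """
    m = cell.orthogonalization_matrix()
    a, b, c = m[:, 0], m[:, 1], m[:, 2]
    volume = abs(np.dot(a, np.cross(b, c)))
    return np.array([
        volume / np.linalg.norm(np.cross(b, c)),
        volume / np.linalg.norm(np.cross(c, a)),
        volume / np.linalg.norm(np.cross(a, b)),
    ])


@dataclass(frozen=True)
class SymmetryImageAtom:
    source_serial: int
    operator_index: int
    lattice_shift: tuple[int, int, int]
    position: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float))


def spacegroup_operators(symbol: str) -> list[SymOp]:
    """Operators for a Hermann–Mauguin symbol (from gemmi's full table)."""
    import gemmi

    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise ConfigurationError(f"unknown space group {symbol!r}")
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append(SymOp.from_arrays(rot, tran))
    return ops


def symmetry_images_within(model: StructureModel, center_serials,
                           radius: float) -> list[SymmetryImageAtom]:
    """All symmetry-image atoms within *radius* of the selection.

    Every (operator, lattice shift) pair other than identity-with-zero-shift
    is considered; returned atoms carry their provenance. Images that land on
    their own source atom (special positions, within 0.1 Å) are dropped.
    The identity-zero-shift copies are excluded by construction: they are the
    model atoms themselves and are found by plain neighbor search.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if model.cell is None:
        raise ConfigurationError("model has no unit cell")
    cell = model.cell

    atoms = list(model.atoms())
    serials = np.array([a.serial for a in atoms])
    cart = np.array([a.position for a in atoms])
    frac = fractionalize(cart, cell)

    center_serials = set(center_serials)
    sel_cart = cart[[i for i, s in enumerate(serials) if s in center_serials]]
    if len(sel_cart) == 0:
        raise ValueError("empty center selection")
    tree = cKDTree(sel_cart)
    sel_center_frac = fractionalize(sel_cart.mean(axis=0), cell)

    pad = np.ceil(radius / axis_heights(cell)).astype(int) + 1
    offsets = np.array([
        (i, j, k)
        for i in range(-pad[0], pad[0] + 1)
        for j in range(-pad[1], pad[1] + 1)
        for k in range(-pad[2], pad[2] + 1)
    ])

    images: list[SymmetryImageAtom] = []
    for op_index, op in enumerate(model.symmetry_ops):
        f_op = op.apply(frac)                      # (N, 3)
        base_shift = np.round(sel_center_frac - f_op)  # per-atom centering
        for off in offsets:
            shift = base_shift + off
            if op_index == 0 and op.is_identity:
                pass  # identity op: zero total shift excluded per atom below
            pos = orthogonalize(f_op + shift, cell)
            dist, _ = tree.query(pos, k=1)
            near = dist <= radius + 1e-6
            if not np.any(near):
                continue
            for i in np.flatnonzero(near):
                total_shift = tuple(int(x) for x in shift[i])
                if op.is_identity and total_shift == (0, 0, 0):
                    continue
                if np.linalg.norm(pos[i] - cart[i]) < SPECIAL_POSITION_TOL:
                    continue
                images.append(SymmetryImageAtom(
                    int(serials[i]), op_index, total_shift, pos[i]))
    return images


def apply_image(position, cell: UnitCell, op: SymOp, shift) -> np.ndarray:
    """Transform a Cartesian position by (operator, lattice shift)."""
    frac = fractionalize(position, cell)
    return orthogonalize(op.apply(frac) + np.asarray(shift, dtype=float), cell)
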