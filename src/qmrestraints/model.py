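"""Hierarchical structure model: atoms, residues, unit cell, symmetry.

Coordinates are Cartesian ångströms everywhere; fractional coordinates exist
only inside :mod:`qmrestraints.symcell`.
"""

from __future__ import annotations

import copy
import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import ConfigurationError

WATER_SYNONYMS: frozenset[str] = frozenset({"HOH", "WAT", "H2O", "DOD"})


class ResidueKind(enum.Enum):
    amino_acid = "amino_acid"
    nucleotide = "nucleotide"
    water = "water"
    ligand = "ligand"
    other = "other"


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0
    altloc: str = ""
    serial: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a Cartesian triple")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy {self.occupancy} out of [0,1] for atom {self.name!r}"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(),
                    self.occupancy, self.b_iso, self.altloc, self.serial)


@dataclass
class Residue:
    comp_id: str
    chain_id: str
    seq_id: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    kind: ResidueKind = ResidueKind.other
    # provenance: "model" for native copies, ("sym", op_index, shift) for
    # symmetry-image copies made by the cluster builder
    provenance: object = "model"

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.chain_id, self.comp_id, self.seq_id, self.icode)

    def get_atom(self, name: str, altloc: Optional[str] = None) -> Optional[Atom]:
        for atom in self.atoms:
            if atom.name == name and (altloc is None or atom.altloc == altloc):
                return atom
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def copy(self) -> "Residue":
        r = Residue(self.comp_id, self.chain_id, self.seq_id, self.icode,
                    [a.copy() for a in self.atoms], self.kind, self.provenance)
        return r

    def __repr__(self) -> str:  # compact for error messages
        return f"{self.chain_id}/{self.comp_id} {self.seq_id}{self.icode}"


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell lengths (Å) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ConfigurationError(f"cell angle {ang} outside (0, 180)")
        if min(self.a, self.b, self.c) <= 0:
            raise ConfigurationError("cell lengths must be positive")

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def orthogonalization_matrix(self) -> np.ndarray:
        """Standard crystallographic frame: a along x, b in the xy-plane."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in
                      (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v2 <= 1e-12:
            raise ConfigurationError("degenerate unit cell (zero volume)")
        v = math.sqrt(v2)
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix())

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.orthogonalization_matrix()))


@dataclass(frozen=True)
class SymOp:
    """Affine symmetry operator acting on fractional coordinates."""

    rot: tuple[tuple[float, float, float], ...]
    tran: tuple[float, float, float]

    @classmethod
    def from_arrays(cls, rot, tran) -> "SymOp":
        rot = np.asarray(rot, dtype=float)
        tran = np.asarray(tran, dtype=float)
        return cls(tuple(tuple(row) for row in rot), tuple(tran))

    @classmethod
    def identity(cls) -> "SymOp":
        return cls.from_arrays(np.eye(3), np.zeros(3))

    @property
    def rot_array(self) -> np.ndarray:
        return np.asarray(self.rot)

    @property
    def tran_array(self) -> np.ndarray:
        return np.asarray(self.tran)

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rot_array, np.eye(3)) and
                np.allclose(self.tran_array % 1.0, 0.0))

    def apply(self, frac: np.ndarray) -> np.ndarray:
        frac = np.asarray(frac, dtype=float)
        return frac @ self.rot_array.T + self.tran_array


@dataclass
class StructureModel:
    residues: list[Residue] = field(default_factory=list)
    cell: Optional[UnitCell] = None
    symmetry_ops: list[SymOp] = field(default_factory=lambda: [SymOp.identity()])
    resolution: Optional[float] = None
    id: str = ""
    spacegroup: str = "P 1"

    def __post_init__(self) -> None:
        if not any(op.is_identity for op in self.symmetry_ops):
            self.symmetry_ops.insert(0, SymOp.identity())

    def atoms(self) -> Iterator[Atom]:
        for residue in self.residues:
            yield from residue.atoms

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def atom_by_serial(self, serial: int) -> Atom:
        for atom in self.atoms():
            if atom.serial == serial:
                return atom
        raise KeyError(f"no atom with serial {serial}")

    def residue_of_serial(self, serial: int) -> Residue:
        for residue in self.residues:
            for atom in residue.atoms:
                if atom.serial == serial:
                    return residue
        raise KeyError(f"no atom with serial {serial}")

    def find_residues(self, chain_id: Optional[str] = None,
                      comp_id: Optional[str] = None,
                      seq_id: Optional[int] = None) -> list[Residue]:
        out = []
        for r in self.residues:
            if chain_id is not None and r.chain_id != chain_id:
                continue
            if comp_id is not None and r.comp_id != comp_id:
                continue
            if seq_id is not None and r.seq_id != seq_id:
                continue
            out.append(r)
        return out

    def renumber_serials(self) -> None:
        for i, atom in enumerate(self.atoms(), start=1):
            atom.serial = i

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms()], dtype=float)

    def copy(self) -> "StructureModel":
        return StructureModel([r.copy() for r in self.residues], self.cell,
                              list(self.symmetry_ops), self.resolution,
                              self.id, self.spacegroup)

    def molecular_weight(self) -> float:
        from .elements import atomic_weight
        return sum(atomic_weight(a.element) for a in self.atoms())


def classify_residue(comp_id: str, atoms: Sequence[Atom]) -> ResidueKind:
    """Classify by the standard component table (via gemmi), with waters and
    carbon-containing heteroatoms handled explicitly."""
    import gemmi

    if comp_id.upper() in WATER_SYNONYMS:
        return ResidueKind.water
    info = gemmi.find_tabulated_residue(comp_id)
    if info is not None:
        if info.is_amino_acid():
            return ResidueKind.amino_acid
        if info.is_nucleic_acid():
            return ResidueKind.nucleotide
        if info.is_water():
            return ResidueKind.water
    if any(a.element.upper() == "C" for a in atoms):
        return ResidueKind.ligand
    return ResidueKind.other
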