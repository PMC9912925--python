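"""Ligand-cluster construction, validation, capping and water protonation.

The ligand cluster is the ligand plus every whole residue — native or
crystallographic symmetry image — with at least one atom within the cutoff
radius (default 3.5 Å) of any ligand atom. Extracting it from the polymer
cuts covalent bonds; those are terminated with hydrogen link atoms (neutral
mode) or charged termini (zwitterion mode) before all-electron optimization.
Crystallographic waters arrive as bare O atoms and are protonated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import networkx as nx
import numpy as np

from .elements import is_metal
from .errors import (InternalConsistencyError, SelectionError,
                     ValidationError)
from .model import Atom, Residue, ResidueKind, StructureModel
from .model_io import infer_connectivity
from .symcell import apply_image, symmetry_images_within

DEFAULT_RADIUS = 3.5          # Å, cluster selection
VALIDATION_RADIUS = 5.5       # Å, other-ligand / metal / altloc screen
MISSING_ATOM_RADIUS = 3.5     # Å, completeness screen

# capping hydrogen bond lengths by the element of the kept (inside) atom
CAP_H_DISTANCE = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}
WATER_OH = 0.96               # Å
WATER_HOH = 104.5             # deg
ACCEPTOR_RADIUS = 3.5         # Å, search for water H-bond acceptors

# heavy-atom rosters of the 20 standard amino acids (OXT treated as optional)
_BACKBONE = ("N", "CA", "C", "O")
AMINO_ACID_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "GLY": _BACKBONE,
    "ALA": _BACKBONE + ("CB",),
    "SER": _BACKBONE + ("CB", "OG"),
    "CYS": _BACKBONE + ("CB", "SG"),
    "THR": _BACKBONE + ("CB", "OG1", "CG2"),
    "VAL": _BACKBONE + ("CB", "CG1", "CG2"),
    "LEU": _BACKBONE + ("CB", "CG", "CD1", "CD2"),
    "ILE": _BACKBONE + ("CB", "CG1", "CG2", "CD1"),
    "MET": _BACKBONE + ("CB", "CG", "SD", "CE"),
    "PRO": _BACKBONE + ("CB", "CG", "CD"),
    "PHE": _BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": _BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": _BACKBONE + ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3",
                        "CZ2", "CZ3", "CH2"),
    "ASP": _BACKBONE + ("CB", "CG", "OD1", "OD2"),
    "GLU": _BACKBONE + ("CB", "CG", "CD", "OE1", "OE2"),
    "ASN": _BACKBONE + ("CB", "CG", "OD1", "ND2"),
    "GLN": _BACKBONE + ("CB", "CG", "CD", "OE1", "NE2"),
    "HIS": _BACKBONE + ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "LYS": _BACKBONE + ("CB", "CG", "CD", "CE", "NZ"),
    "ARG": _BACKBONE + ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
}


@dataclass
class CutBond:
    inside_serial: int          # cluster serial of the kept atom
    outside_serial: int         # model serial of the removed atom
    inside_name: str
    outside_name: str
    inside_position: np.ndarray
    outside_position: np.ndarray


@dataclass
class CapRecord:
    atom: Atom
    inside_serial: int
    outside_serial: int


@dataclass
class ProtonRecord:
    atom: Atom
    parent_serial: int


@dataclass
class LigandCluster:
    ligand: Residue
    environment: list[Residue]
    radius: float
    cut_bonds: list[CutBond] = field(default_factory=list)
    added_caps: list[CapRecord] = field(default_factory=list)
    added_protons: list[ProtonRecord] = field(default_factory=list)
    model: Optional[StructureModel] = None   # source, for cell/provenance

    def residues(self) -> list[Residue]:
        return [self.ligand, *self.environment]

    def atoms(self) -> Iterator[Atom]:
        for residue in self.residues():
            yield from residue.atoms

    def atom_by_serial(self, serial: int) -> Atom:
        for atom in self.atoms():
            if atom.serial == serial:
                return atom
        raise KeyError(f"no cluster atom with serial {serial}")

    def residue_of_serial(self, serial: int) -> Residue:
        for residue in self.residues():
            if any(a.serial == serial for a in residue.atoms):
                return residue
        raise KeyError(f"no cluster atom with serial {serial}")

    def renumber(self) -> None:
        for i, atom in enumerate(self.atoms(), start=1):
            atom.serial = i

    def next_serial(self) -> int:
        return max((a.serial for a in self.atoms()), default=0) + 1

    @property
    def cap_serials(self) -> set[int]:
        return {c.atom.serial for c in self.added_caps}

    @property
    def proton_serials(self) -> set[int]:
        return {p.atom.serial for p in self.added_protons}


# ------------------------------------------------------------- construction

def _find_ligand(model: StructureModel, selector) -> Residue:
    chain_id, comp_id, seq_id = selector
    matches = model.find_residues(chain_id, comp_id, seq_id)
    if len(matches) != 1:
        raise SelectionError(
            f"selector {selector} matched {len(matches)} residues")
    return matches[0]


def _min_distance(residue: Residue, points: np.ndarray) -> float:
    pos = np.array([a.position for a in residue.atoms])
    diff = pos[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def build_ligand_cluster(model: StructureModel, ligand_selector,
                         radius: float = DEFAULT_RADIUS,
                         connectivity: Optional[nx.Graph] = None,
                         dictionaries: Optional[dict] = None,
                         include_symmetry: bool = True) -> LigandCluster:
    """Select the ligand cluster: whole residues within *radius* of the ligand.

    Symmetry-image residues are included whole whenever any image atom falls
    within the radius; each copy carries (operator index, lattice shift)
    provenance and fresh serials, so it never aliases a model atom. Cut bonds
    record every covalent edge from a cluster atom to an atom left outside.
    """
    ligand_src = _find_ligand(model, ligand_selector)
    ligand_points = np.array([a.position for a in ligand_src.atoms])

    native_env = [
        r for r in model.residues
        if r is not ligand_src and _min_distance(r, ligand_points) <= radius
    ]

    sym_groups: dict[tuple, Residue] = {}
    if include_symmetry and model.cell is not None:
        images = symmetry_images_within(
            model, [a.serial for a in ligand_src.atoms], radius)
        cell = model.cell
        for img in images:
            src_res = model.residue_of_serial(img.source_serial)
            key = (src_res.key, img.operator_index, img.lattice_shift)
            if key in sym_groups:
                continue
            copy = src_res.copy()
            op = model.symmetry_ops[img.operator_index]
            for atom in copy.atoms:
                atom.position = apply_image(atom.position, cell, op,
                                            img.lattice_shift)
            copy.provenance = ("sym", img.operator_index, img.lattice_shift)
            sym_groups[key] = copy

    ligand = ligand_src.copy()
    environment = [r.copy() for r in native_env] + list(sym_groups.values())

    cluster = LigandCluster(ligand, environment, radius, model=model)

    # map source serial -> cluster atom per provenance context
    source_serials: dict[object, dict[int, Atom]] = {}
    src_residues = [ligand_src, *native_env]
    dst_residues = [ligand, *environment[:len(native_env)]]
    ctx = source_serials.setdefault("model", {})
    for src, dst in zip(src_residues, dst_residues):
        for s_atom, d_atom in zip(src.atoms, dst.atoms):
            ctx[s_atom.serial] = d_atom
    for key, copy in sym_groups.items():
        src_res = next(r for r in model.residues if r.key == key[0])
        ctx = source_serials.setdefault(copy.provenance, {})
        for s_atom, d_atom in zip(src_res.atoms, copy.atoms):
            ctx[s_atom.serial] = d_atom

    cluster.renumber()

    if connectivity is None:
        connectivity = infer_connectivity(model, dictionaries)

    for provenance, mapping in source_serials.items():
        for src_serial, cluster_atom in mapping.items():
            for neighbor in connectivity.neighbors(src_serial):
                if neighbor in mapping:
                    continue  # partner kept within the same image context
                outside = model.atom_by_serial(neighbor)
                outside_pos = outside.position
                if provenance != "model":
                    _, op_index, shift = provenance
                    outside_pos = apply_image(
                        outside_pos, model.cell,
                        model.symmetry_ops[op_index], shift)
                cluster.cut_bonds.append(CutBond(
                    cluster_atom.serial, neighbor, cluster_atom.name,
                    outside.name, cluster_atom.position.copy(),
                    np.asarray(outside_pos, dtype=float)))

    cluster.cut_bonds.sort(key=lambda cb: (cb.inside_serial, cb.outside_serial))
    return cluster


# --------------------------------------------------------------- validation

@dataclass
class EnvironmentReport:
    other_ligand_within_5p5: bool
    other_ligand_offenders: list[Residue]
    metal_within_5p5: bool
    metal_offenders: list[Residue]
    altloc_within_5p5: bool
    altloc_offenders: list[Residue]
    missing_atoms_within_3p5: bool
    missing_atom_offenders: list[tuple[Residue, list[str]]]
    unknown_components: list[Residue] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.other_ligand_within_5p5 or self.metal_within_5p5
                    or self.altloc_within_5p5 or self.missing_atoms_within_3p5)

    def summary(self) -> str:
        def fmt(flag, offenders):
            return ("FAIL " + ", ".join(repr(o) if isinstance(o, Residue)
                                        else repr(o[0]) for o in offenders)
                    if flag else "ok")
        return (
            f"other ligands ≤{VALIDATION_RADIUS} Å: "
            f"{fmt(self.other_ligand_within_5p5, self.other_ligand_offenders)}\n"
            f"metals ≤{VALIDATION_RADIUS} Å: "
            f"{fmt(self.metal_within_5p5, self.metal_offenders)}\n"
            f"altlocs ≤{VALIDATION_RADIUS} Å: "
            f"{fmt(self.altloc_within_5p5, self.altloc_offenders)}\n"
            f"missing atoms ≤{MISSING_ATOM_RADIUS} Å: "
            f"{fmt(self.missing_atoms_within_3p5, self.missing_atom_offenders)}\n"
            f"clean: {self.clean}\n"
        )


def _residue_roster(residue: Residue, dictionaries: Optional[dict]):
    """Heavy-atom names the residue is expected to contain, or None."""
    if dictionaries and residue.comp_id in dictionaries:
        d = dictionaries[residue.comp_id]
        return [a.name for a in d.atoms if a.element.upper() not in ("H", "D")]
    if residue.kind is ResidueKind.water:
        return ["O"]
    if residue.comp_id in AMINO_ACID_HEAVY_ATOMS:
        return list(AMINO_ACID_HEAVY_ATOMS[residue.comp_id])
    return None


def validate_environment(model: StructureModel, ligand_selector,
                         connectivity: Optional[nx.Graph] = None,
                         dictionaries: Optional[dict] = None) -> EnvironmentReport:
    """Screen the ligand environment per the selection criteria.

    Within 5.5 Å of the ligand (measured on the input model, before any
    H-atom addition): no other ligand-kind residues, no metal atoms, no
    alternate conformations (the ligand's own altlocs count). Within 3.5 Å:
    no residues missing expected heavy atoms. Residues with no known roster
    are reported separately as unknown components, not as failures.
    """
    ligand = _find_ligand(model, ligand_selector)
    points = np.array([a.position for a in ligand.atoms])

    other_ligands, metals, altlocs = [], [], []
    missing, unknown = [], []

    for residue in model.residues:
        dist = _min_distance(residue, points)
        if residue is not ligand and dist <= VALIDATION_RADIUS:
            if residue.kind is ResidueKind.ligand:
                other_ligands.append(residue)
            if any(is_metal(a.element) for a in residue.atoms):
                metals.append(residue)
        if dist <= VALIDATION_RADIUS:
            if any(a.altloc for a in residue.atoms):
                altlocs.append(residue)
        if dist <= MISSING_ATOM_RADIUS:
            roster = _residue_roster(residue, dictionaries)
            if roster is None:
                unknown.append(residue)
                continue
            present = {a.name for a in residue.atoms}
            absent = [n for n in roster if n not in present]
            if absent:
                missing.append((residue, absent))

    return EnvironmentReport(
        bool(other_ligands), other_ligands,
        bool(metals), metals,
        bool(altlocs), altlocs,
        bool(missing), missing,
        unknown)


# ------------------------------------------------------------------ capping

def _unique_atom_name(residue: Residue, stem: str) -> str:
    existing = {a.name for a in residue.atoms}
    for i in range(1, 100):
        name = f"{stem}{i}"
        if name not in existing:
            return name
    raise ValidationError(f"cannot find a free atom name with stem {stem!r}")


def cap_dangling_bonds(cluster: LigandCluster,
                       mode: str = "neutral") -> LigandCluster:
    """Terminate every cut bond.

    neutral: a hydrogen link atom replaces the removed partner, placed along
    the former bond vector at the standard element–H distance (C–H 1.09 Å,
    N–H 1.01 Å, O–H 0.96 Å). zwitterion: backbone cuts become charged
    termini — a cut N(…)–C gains protons to an NH3+ and a cut C(=O)–N gains a
    second carboxylate O at 1.25 Å; non-backbone cuts fall back to hydrogen
    link atoms. Heavy-atom content of the input is never modified.
    """
    if mode not in ("neutral", "zwitterion"):
        raise ValueError(f"unknown capping mode {mode!r}")

    cap_serials = cluster.cap_serials
    for cut in cluster.cut_bonds:
        if cut.inside_serial in cap_serials:
            raise InternalConsistencyError(
                f"cut bond {cut.inside_name}-{cut.outside_name}: inside atom "
                f"is itself a cap")
        inside = cluster.atom_by_serial(cut.inside_serial)
        residue = cluster.residue_of_serial(cut.inside_serial)
        vector = cut.outside_position - inside.position
        norm = np.linalg.norm(vector)
        if norm < 1e-6:
            raise ValidationError(
                f"degenerate cut bond at {cut.inside_name}")
        direction = vector / norm

        if (mode == "zwitterion" and inside.element.upper() == "C"
                and cut.outside_name.startswith("N")):
            new = Atom(_unique_atom_name(residue, "OX"), "O",
                       inside.position + direction * 1.25,
                       serial=cluster.next_serial())
        elif (mode == "zwitterion" and inside.element.upper() == "N"
                and cut.outside_name.startswith("C")):
            _cap_ammonium(cluster, residue, inside)
            continue
        else:
            d = CAP_H_DISTANCE.get(inside.element.upper(), 1.09)
            new = Atom(_unique_atom_name(residue, "HX"), "H",
                       inside.position + direction * d,
                       serial=cluster.next_serial())
        residue.atoms.append(new)
        cluster.added_caps.append(CapRecord(new, cut.inside_serial,
                                            cut.outside_serial))
    return cluster


def _cap_ammonium(cluster: LigandCluster, residue: Residue,
                  nitrogen: Atom) -> None:
    """Complete a cut backbone nitrogen to NH3+ with tetrahedral geometry."""
    neighbors = [a for a in residue.atoms
                 if a is not nitrogen
                 and np.linalg.norm(a.position - nitrogen.position) < 1.7]
    existing_h = [a for a in neighbors if a.is_hydrogen]
    heavy = [a for a in neighbors if not a.is_hydrogen]
    needed = 3 - len(existing_h)
    taken = [(a.position - nitrogen.position) /
             np.linalg.norm(a.position - nitrogen.position)
             for a in heavy + existing_h]
    for direction in _tetrahedral_directions(taken, needed):
        new = Atom(_unique_atom_name(residue, "HX"), "H",
                   nitrogen.position + direction * CAP_H_DISTANCE["N"],
                   serial=cluster.next_serial())
        residue.atoms.append(new)
        cluster.added_caps.append(CapRecord(new, nitrogen.serial, -1))


def _perpendicular(u: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to u."""
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(u)))] = 1.0
    p = np.cross(u, axis)
    return p / np.linalg.norm(p)


def _tetrahedral_directions(taken: list[np.ndarray], n_new: int) -> list[np.ndarray]:
    """Unit vectors completing an approximate tetrahedron around a center."""
    tet = math.radians(109.47)
    if not taken:
        taken = [np.array([0.0, 0.0, 1.0])]
        n_new -= 0  # canonical frame seeds the first direction below
    u = taken[0]
    p = _perpendicular(u)
    q = np.cross(u, p)
    # candidate propeller at 109.47° from the first taken direction
    candidates = []
    for k in range(3):
        phi = 2.0 * math.pi * k / 3.0
        candidates.append(math.cos(tet) * u +
                          math.sin(tet) * (math.cos(phi) * p + math.sin(phi) * q))
    # drop candidates too close to other already-taken directions
    free = [c for c in candidates
            if all(np.dot(c, t) < math.cos(math.radians(30.0))
                   for t in taken[1:])]
    return free[:n_new]


# -------------------------------------------------------------- protonation

def protonate_waters(cluster: LigandCluster) -> LigandCluster:
    """Give every environment water two protons (O–H 0.96 Å, H–O–H 104.5°).

    Proton directions point towards the nearest two H-bond acceptor atoms
    (O/N within 3.5 Å elsewhere in the cluster); with one acceptor the second
    proton completes the angle in a deterministic plane, and with none a
    canonical frame is used. Idempotent: already-protonated waters are left
    untouched; more than two existing protons is a validation error.
    """
    acceptor_atoms = []
    for residue in cluster.residues():
        for atom in residue.atoms:
            if atom.element.upper() in ("O", "N"):
                acceptor_atoms.append((residue, atom))

    for water in cluster.environment:
        if water.kind is not ResidueKind.water:
            continue
        oxygens = [a for a in water.atoms if a.element.upper() == "O"]
        hydrogens = [a for a in water.atoms if a.is_hydrogen]
        if not oxygens:
            raise ValidationError(f"water {water!r} has no oxygen")
        if len(hydrogens) > 2:
            raise ValidationError(f"water {water!r} has {len(hydrogens)} protons")
        if len(hydrogens) == 2:
            continue
        oxygen = oxygens[0]

        acceptors = sorted(
            ((np.linalg.norm(atom.position - oxygen.position), atom.serial, atom)
             for residue, atom in acceptor_atoms
             if residue is not water
             and np.linalg.norm(atom.position - oxygen.position)
             <= ACCEPTOR_RADIUS),
            key=lambda t: (t[0], t[1]))
        directions = _water_proton_directions(
            oxygen, hydrogens, [a.position for _, _, a in acceptors[:2]])

        for direction in directions[:2 - len(hydrogens)]:
            new = Atom(_unique_atom_name(water, "H"), "H",
                       oxygen.position + direction * WATER_OH,
                       serial=cluster.next_serial())
            water.atoms.append(new)
            cluster.added_protons.append(ProtonRecord(new, oxygen.serial))
    return cluster


def _water_proton_directions(oxygen: Atom, existing_h: list[Atom],
                             acceptor_positions: list[np.ndarray]) -> list[np.ndarray]:
    theta = math.radians(WATER_HOH)

    if existing_h:
        u1 = existing_h[0].position - oxygen.position
        u1 /= np.linalg.norm(u1)
    elif acceptor_positions:
        u1 = acceptor_positions[0] - oxygen.position
        u1 /= np.linalg.norm(u1)
    else:
        u1 = np.array([1.0, 0.0, 0.0])

    # in-plane second direction: towards the next acceptor when available
    reference = None
    remaining = acceptor_positions[1:] if not existing_h else acceptor_positions
    for pos in remaining:
        v = pos - oxygen.position
        v = v - np.dot(v, u1) * u1
        if np.linalg.norm(v) > 1e-6:
            reference = v / np.linalg.norm(v)
            break
    if reference is None:
        reference = _perpendicular(u1)

    u2 = math.cos(theta) * u1 + math.sin(theta) * reference
    # only directions for protons still to be added
    return [u2] if existing_h else [u1, u2]


# ------------------------------------------------------------------- export

def cluster_to_pdb(cluster: LigandCluster) -> str:
    """Standalone PDB of the cluster with a remark block for provenance.

    REMARK 350 lines list cut bonds, caps, added protons and the symmetry
    provenance of every image residue, so the cluster can be audited.
    """
    from .model import StructureModel
    from .model_io import write_structure

    model = StructureModel(
        [r.copy() for r in cluster.residues()],
        cluster.model.cell if cluster.model else None,
        list(cluster.model.symmetry_ops) if cluster.model else None
        or [],
        id="ligand_cluster",
        spacegroup=cluster.model.spacegroup if cluster.model else "P 1")

    remarks = ["REMARK 350 LIGAND CLUSTER "
               f"RADIUS {cluster.radius:.2f} A"]
    for residue in cluster.environment:
        if residue.provenance != "model":
            _, op, shift = residue.provenance
            remarks.append(
                f"REMARK 350 SYMMETRY COPY {residue!r} OP {op} "
                f"SHIFT {shift[0]} {shift[1]} {shift[2]}")
    for cut in cluster.cut_bonds:
        remarks.append(
            f"REMARK 350 CUT BOND {cut.inside_name}({cut.inside_serial}) -> "
            f"{cut.outside_name}({cut.outside_serial})")
    for cap in cluster.added_caps:
        remarks.append(
            f"REMARK 350 CAP {cap.atom.name}({cap.atom.serial}) "
            f"FOR CUT AT SERIAL {cap.inside_serial}")
    for proton in cluster.added_protons:
        remarks.append(
            f"REMARK 350 ADDED PROTON {proton.atom.name}"
            f"({proton.atom.serial}) ON SERIAL {proton.parent_serial}")

    pdb = write_structure(model, "pdb")
    return "\n".join(remarks) + "\n" + pdb
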