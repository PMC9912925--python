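"""Read/write macromolecular models (PDB and mmCIF) and infer connectivity.

gemmi does the heavy lifting for both fixed-column PDB and mmCIF syntax and
for the Hermann–Mauguin → operator table; this module maps gemmi's hierarchy
onto the package's own data model and back.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .elements import covalent_radius, element_from_atom_name
from .errors import ConfigurationError, FormatError, SerializationError
from .model import (Atom, Residue, ResidueKind, StructureModel, SymOp,
                    UnitCell, classify_residue)
from .symcell import spacegroup_operators

# distance-based bonding: bonded iff d < tolerance * (r_cov1 + r_cov2)
COVALENT_TOLERANCE = 1.3
PEPTIDE_BOND_MAX = 1.7  # Å, C–N between consecutive residues

PDB_MAX_ATOMS = 99999


def parse_structure(text: str, format: str = "pdb",
                    default_spacegroup: Optional[str] = None) -> StructureModel:
    """Parse PDB or mmCIF text into a StructureModel.

    Symmetry operators come from the space-group name (CRYST1 or the mmCIF
    symmetry category); mmCIF symmetry-operator loops, when present, are taken
    verbatim. A missing or unknown space group raises ConfigurationError
    unless ``default_spacegroup`` supplies a fallback (e.g. "P 1").
    """
    import gemmi

    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    try:
        if format == "pdb":
            structure = gemmi.read_pdb_string(text)
            explicit_ops = None
        else:
            doc = gemmi.cif.read_string(text)
            block = doc.sole_block()
            structure = gemmi.make_structure_from_block(block)
            explicit_ops = _mmcif_symop_loop(block)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"unparseable {format} input: {exc}") from exc

    cell = None
    g = structure.cell
    if g is not None and g.is_crystal():
        cell = UnitCell(g.a, g.b, g.c, g.alpha, g.beta, g.gamma)

    sg_name = (structure.spacegroup_hm or "").strip()
    if explicit_ops:
        ops = explicit_ops
    else:
        if not sg_name:
            sg_name = default_spacegroup or ""
        if not sg_name:
            raise ConfigurationError(
                "no space group in input and no fallback requested")
        try:
            ops = spacegroup_operators(sg_name)
        except ConfigurationError:
            if default_spacegroup:
                ops = spacegroup_operators(default_spacegroup)
                sg_name = default_spacegroup
            else:
                raise

    resolution = structure.resolution if structure.resolution > 0 else None

    residues: list[Residue] = []
    serial = 0
    if len(structure) == 0:
        model_residues = []
    else:
        model_residues = [
            (chain.name, res)
            for chain in structure[0] for res in chain
        ]
    for chain_name, res in model_residues:
        atoms = []
        comp_standard = gemmi.find_tabulated_residue(res.name) is not None
        for at in res:
            serial += 1
            element = at.element.name if at.element.name != "X" else ""
            if not element:
                element = element_from_atom_name(at.name, comp_standard)
            atoms.append(Atom(
                name=at.name, element=element,
                position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                occupancy=float(at.occ), b_iso=float(at.b_iso),
                altloc=at.altloc if at.altloc != "\x00" else "",
                serial=serial))
        seq = res.seqid.num if res.seqid.num is not None else 0
        icode = res.seqid.icode.strip()
        residue = Residue(res.name, chain_name, seq, icode, atoms)
        residue.kind = classify_residue(res.name, atoms)
        residues.append(residue)

    return StructureModel(residues, cell,
                          ops, resolution, structure.name or "",
                          sg_name or "P 1")


def _mmcif_symop_loop(block) -> Optional[list[SymOp]]:
    import gemmi

    for tag in ("_symmetry_equiv.pos_as_xyz", "_symmetry_equiv_pos_as_xyz",
                "_space_group_symop.operation_xyz",
                "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        triplets = [gemmi.cif.as_string(v) for v in col]
        if triplets:
            ops = []
            for trip in triplets:
                op = gemmi.Op(trip)
                ops.append(SymOp.from_arrays(
                    np.array(op.rot, dtype=float) / op.DEN,
                    np.array(op.tran, dtype=float) / op.DEN))
            return ops
    return None


def write_structure(model: StructureModel, format: str = "pdb") -> str:
    """Serialize a StructureModel; output re-parses to an equivalent model."""
    import gemmi

    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    n_atoms = model.atom_count
    if format == "pdb" and n_atoms > PDB_MAX_ATOMS:
        raise SerializationError(
            f"{n_atoms} atoms exceed the PDB serial field limit "
            f"({PDB_MAX_ATOMS})")
    if format == "pdb":
        for atom in model.atoms():
            if len(atom.name) > 4:
                raise SerializationError(
                    f"atom name {atom.name!r} exceeds the 4-character "
                    f"PDB field")

    structure = gemmi.Structure()
    structure.name = model.id or "model"
    if model.cell is not None:
        structure.cell = gemmi.UnitCell(*model.cell.parameters)
    structure.spacegroup_hm = model.spacegroup
    if model.resolution:
        structure.resolution = model.resolution

    gmodel = gemmi.Model("1")
    chains: dict[str, "gemmi.Chain"] = {}
    for residue in model.residues:
        chain = chains.get(residue.chain_id)
        if chain is None:
            chain = gemmi.Chain(residue.chain_id)
            chains[residue.chain_id] = chain
            gmodel.add_chain(chain)
            chain = gmodel[-1]
            chains[residue.chain_id] = chain
        gres = gemmi.Residue()
        gres.name = residue.comp_id
        gres.seqid = gemmi.SeqId(residue.seq_id, residue.icode or " ")
        if residue.kind in (ResidueKind.water, ResidueKind.ligand,
                            ResidueKind.other):
            gres.het_flag = "H"
        else:
            gres.het_flag = "A"
        for atom in residue.atoms:
            gat = gemmi.Atom()
            gat.name = atom.name
            gat.element = gemmi.Element(atom.element)
            gat.pos = gemmi.Position(*atom.position)
            gat.occ = atom.occupancy
            gat.b_iso = atom.b_iso
            gat.altloc = atom.altloc or "\x00"
            gres.add_atom(gat)
        chain.add_residue(gres)
    structure.add_model(gmodel)
    structure.setup_entities()

    if format == "pdb":
        return structure.make_pdb_string()
    return structure.make_mmcif_document().as_string()


def infer_connectivity(model: StructureModel,
                       dictionaries: Optional[dict] = None) -> nx.Graph:
    """Bond graph over atom serials.

    Intra-residue bonds come from a matching restraint dictionary when one is
    supplied; otherwise any heavy/H atom pair closer than
    ``COVALENT_TOLERANCE x (sum of covalent radii)`` is bonded. Inter-residue
    peptide bonds (C–N under 1.7 Å between consecutive amino-acid residues)
    are always added; dictionary bonds carry their bond-order annotation.
    """
    graph = nx.Graph()
    for atom in model.atoms():
        graph.add_node(atom.serial)

    dictionaries = dictionaries or {}
    for residue in model.residues:
        d = dictionaries.get(residue.comp_id)
        if d is not None:
            _dictionary_bonds(graph, residue, d)
        else:
            _distance_bonds(graph, residue)

    _peptide_bonds(graph, model)
    return graph


def _dictionary_bonds(graph: nx.Graph, residue: Residue, dictionary) -> None:
    by_name: dict[str, list[Atom]] = {}
    for atom in residue.atoms:
        by_name.setdefault(atom.name, []).append(atom)
    for bond in dictionary.bonds:
        for a1 in by_name.get(bond.atoms[0], []):
            for a2 in by_name.get(bond.atoms[1], []):
                # altlocs pair within their own conformation (blank matches all)
                if a1.altloc and a2.altloc and a1.altloc != a2.altloc:
                    continue
                graph.add_edge(a1.serial, a2.serial, order="single",
                               source="dictionary")


def _distance_bonds(graph: nx.Graph, residue: Residue) -> None:
    atoms = residue.atoms
    if len(atoms) < 2:
        return
    positions = np.array([a.position for a in atoms])
    tree = cKDTree(positions)
    max_reach = COVALENT_TOLERANCE * 2 * max(covalent_radius(a.element)
                                             for a in atoms)
    for i, j in tree.query_pairs(max_reach):
        a1, a2 = atoms[i], atoms[j]
        if a1.is_hydrogen and a2.is_hydrogen:
            continue
        if a1.altloc and a2.altloc and a1.altloc != a2.altloc:
            continue
        cutoff = COVALENT_TOLERANCE * (covalent_radius(a1.element) +
                                       covalent_radius(a2.element))
        if np.linalg.norm(a1.position - a2.position) < cutoff:
            graph.add_edge(a1.serial, a2.serial, order="unknown",
                           source="distance")


def _peptide_bonds(graph: nx.Graph, model: StructureModel) -> None:
    previous: Optional[Residue] = None
    for residue in model.residues:
        if residue.kind is not ResidueKind.amino_acid:
            previous = None
            continue
        if previous is not None and previous.chain_id == residue.chain_id:
            c = previous.get_atom("C")
            n = residue.get_atom("N")
            if c is not None and n is not None:
                if np.linalg.norm(c.position - n.position) < PEPTIDE_BOND_MAX:
                    graph.add_edge(c.serial, n.serial, order="single",
                                   source="peptide")
        previous = residue
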