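"""Synthetic fixtures: a toy pocket, ligand and matching restraint dictionary.

The generator emulates the inputs of an in-situ restraint-generation run
without any deposited structure: a small branched ligand with one rotatable
torsion, one torsion carrying an aperiodic alternative target (the
ring-pucker mechanism) and one period-3 propeller torsion; a shell of
glycine fragments forming a rigid pocket; and bare-oxygen waters. The
ligand's restraint dictionary is measured from the constructed ground-truth
geometry, so an unperturbed fixture has identically zero deviations.

Perturbations are applied in internal coordinates during construction: the
torsion magnitude is added to every restrained non-hydrogen torsion (each
lives on its own rotatable bond, so the torsion r.m.s.d. of the perturbed
ligand equals the magnitude exactly), the angle magnitude to the O1–C1–C2
probe angle and the bond magnitude to the C1–O1 probe bond (terminal-atom
moves, so the categories stay decoupled).

All randomness derives from the seed; identical specs give byte-identical
PDB and CIF output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import bond_length, torsion_angle, valence_angle
from .model import (Atom, Residue, ResidueKind, StructureModel, UnitCell)
from .restraints import (AngleRestraint, AtomSpec, BondRestraint,
                         ChiralRestraint, RestraintDictionary,
                         TorsionRestraint)
from .symcell import spacegroup_operators

LIGAND_COMP = "LIG"
ROTATABLE_TORSION = ("O1", "C1", "C2", "C3")
PUCKER_TORSION = ("C1", "C2", "C3", "C4")
PROPELLER_TORSION = ("HN1", "N1", "C4", "C3")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    ligand_size: int = 8                 # heavy atoms (>= 8)
    pocket_residues: int = 4
    n_waters: int = 2
    perturbation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # Å, deg, deg
    cell: tuple[float, ...] = (30.0, 32.0, 34.0, 90.0, 90.0, 90.0)
    space_group: str = "P 21 21 21"
    steric_block: bool = False           # pocket O clashing with the
    block_distance: float = 1.3          # rotatable-target position of O1

    def __post_init__(self):
        if self.ligand_size < 8:
            raise ValueError("ligand_size must be at least 8 heavy atoms")
        if any(p < 0 for p in self.perturbation):
            raise ValueError("perturbation magnitudes must be >= 0")


def place_atom(a, b, c, r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Position d with |d-c| = r, angle(d,c,b) = theta, torsion(d,c,b,a) = phi."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta, phi = math.radians(theta_deg), math.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-r * math.cos(theta),
                        r * math.sin(theta) * math.cos(phi),
                        r * math.sin(theta) * math.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ------------------------------------------------------------- ligand builder

_CC, _CO, _CN, _NH = 1.53, 1.43, 1.47, 1.01
_TET = 109.5


def _build_ligand_coords(spec: FixtureSpec,
                         perturb: bool) -> dict[str, np.ndarray]:
    db, da, dt = spec.perturbation if perturb else (0.0, 0.0, 0.0)
    pos: dict[str, np.ndarray] = {}
    pos["C1"] = np.zeros(3)
    pos["C2"] = np.array([_CC, 0.0, 0.0])
    pos["C3"] = place_atom([0, 0, 1.0], pos["C1"], pos["C2"], _CC, _TET, 147.0)
    pos["O1"] = place_atom(pos["C3"], pos["C2"], pos["C1"],
                           _CO + db, _TET + da, 60.0 + dt)
    pos["C4"] = place_atom(pos["C1"], pos["C2"], pos["C3"],
                           _CC, _TET, 180.0 + dt)
    pos["C5"] = place_atom(pos["C3"], pos["C1"], pos["C2"], _CC, _TET, 121.0)
    pos["C6"] = place_atom(pos["C4"], pos["C2"], pos["C3"], _CC, _TET, -121.0)
    pos["N1"] = place_atom(pos["C2"], pos["C3"], pos["C4"],
                           _CN, _TET, 180.0 + dt)
    for i, phi in enumerate((60.0, 180.0, 300.0), start=1):
        pos[f"HN{i}"] = place_atom(pos["C3"], pos["C4"], pos["N1"],
                                   _NH, _TET, phi + dt)
    # optional trans chain extension on the C5 branch
    a, b, c = "C1", "C2", "C5"
    for name in _extension_names(spec):
        pos[name] = place_atom(pos[a], pos[b], pos[c], _CC, _TET, 180.0)
        a, b, c = b, c, name
    return pos


def _extension_names(spec: FixtureSpec) -> list[str]:
    return [f"C{7 + k}" for k in range(spec.ligand_size - 8)]


def _ligand_topology(spec: FixtureSpec):
    atoms = [
        AtomSpec("C1", "C"), AtomSpec("C2", "C"), AtomSpec("C3", "C"),
        AtomSpec("C4", "C"), AtomSpec("C5", "C"), AtomSpec("C6", "C"),
        AtomSpec("O1", "O"), AtomSpec("N1", "N"),
        AtomSpec("HN1", "H"), AtomSpec("HN2", "H"), AtomSpec("HN3", "H"),
    ]
    bonds = [("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C1", "O1"),
             ("C2", "C5"), ("C3", "C6"), ("C4", "N1"),
             ("N1", "HN1"), ("N1", "HN2"), ("N1", "HN3")]
    angles = [("O1", "C1", "C2"), ("C1", "C2", "C3"), ("C1", "C2", "C5"),
              ("C3", "C2", "C5"), ("C2", "C3", "C4"), ("C2", "C3", "C6"),
              ("C4", "C3", "C6"), ("C3", "C4", "N1"),
              ("C4", "N1", "HN1"), ("C4", "N1", "HN2"), ("C4", "N1", "HN3"),
              ("HN1", "N1", "HN2"), ("HN1", "N1", "HN3"), ("HN2", "N1", "HN3")]
    prev = "C2"
    chain_parent = "C5"
    for name in _extension_names(spec):
        atoms.append(AtomSpec(name, "C"))
        bonds.append((chain_parent, name))
        angles.append((prev, chain_parent, name))
        prev, chain_parent = chain_parent, name
    return atoms, bonds, angles


def _ligand_torsion_specs(spec: FixtureSpec):
    """(atoms, esd, periodicity, alternatives, involves_h)."""
    torsions = [
        (ROTATABLE_TORSION, 30.0, 1, None),
        (PUCKER_TORSION, 30.0, 1, (65.0,)),
        (("C2", "C3", "C4", "N1"), 30.0, 1, None),
        (PROPELLER_TORSION, 30.0, 3, None),
    ]
    a, b, c = "C1", "C2", "C5"
    for name in _extension_names(spec):
        torsions.append(((a, b, c, name), 30.0, 1, None))
        a, b, c = b, c, name
    return torsions


def build_ligand_dictionary(spec: FixtureSpec) -> RestraintDictionary:
    """Dictionary whose targets are measured from the ground-truth geometry."""
    truth = _build_ligand_coords(spec, perturb=False)
    atoms, bond_pairs, angle_triples = _ligand_topology(spec)

    h_names = {a.name for a in atoms if a.element == "H"}
    bonds = [BondRestraint(p, round(bond_length(truth[p[0]], truth[p[1]]), 4),
                           0.02) for p in bond_pairs]
    angles = [AngleRestraint(
        t, round(valence_angle(truth[t[0]], truth[t[1]], truth[t[2]]), 3),
        3.0 if set(t) & h_names else 2.0) for t in angle_triples]
    torsions = []
    for quad, esd, period, alts in _ligand_torsion_specs(spec):
        measured = round(torsion_angle(*(truth[n] for n in quad)), 3)
        torsions.append(TorsionRestraint(quad, measured, esd, period, alts))

    center = "C2"
    v = [truth[n] - truth[center] for n in ("C1", "C3", "C5")]
    volume = float(np.dot(v[0], np.cross(v[1], v[2])))
    chirals = [ChiralRestraint("chir_1", center, ("C1", "C3", "C5"),
                               "positive" if volume > 0 else "negative")]

    return RestraintDictionary(LIGAND_COMP, atoms, bonds, angles, torsions,
                               [], chirals, formal_charge=0)


# ------------------------------------------------------------ model assembly

def _gly_fragment(anchor: np.ndarray, outward: np.ndarray,
                  o_distance_from: np.ndarray) -> Residue:
    """Glycine-like fragment with its carbonyl O at *anchor*, growing outward."""
    outward = np.asarray(outward, float)
    outward = outward / np.linalg.norm(outward)
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(outward)))] = 1.0
    perp = np.cross(outward, axis)
    perp /= np.linalg.norm(perp)

    o = np.asarray(anchor, float)
    c = o + 1.23 * outward
    # sp2 carbonyl carbon: CA at 120° from O, then a zigzag N
    ca = c + 1.52 * (math.cos(math.radians(60.0)) * outward +
                     math.sin(math.radians(60.0)) * perp)
    v = (ca - c) / np.linalg.norm(ca - c)
    w = np.cross(np.cross(v, outward), v)
    w /= np.linalg.norm(w)
    n = ca + 1.45 * (math.cos(math.radians(70.0)) * v +
                     math.sin(math.radians(70.0)) * w)
    atoms = [
        Atom("N", "N", n), Atom("CA", "C", ca),
        Atom("C", "C", c), Atom("O", "O", o),
    ]
    residue = Residue("GLY", "P", 0, atoms=atoms)
    residue.kind = ResidueKind.amino_acid
    return residue


def generate_fixture(spec: FixtureSpec):
    """Build (StructureModel, RestraintDictionary, ground_truth).

    ground_truth maps ligand atom names to their unperturbed positions and
    records the designated probe internal coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    dictionary = build_ligand_dictionary(spec)
    truth = _build_ligand_coords(spec, perturb=False)
    perturbed = _build_ligand_coords(spec, perturb=True)

    # translate everything to sit well inside the cell
    cell = UnitCell(*spec.cell)
    origin = np.array([cell.a, cell.b, cell.c]) * 0.25
    centroid = np.mean(list(perturbed.values()), axis=0)
    offset = origin - centroid
    truth = {n: p + offset for n, p in truth.items()}
    perturbed = {n: p + offset for n, p in perturbed.items()}

    ligand = Residue(LIGAND_COMP, "A", 1, atoms=[
        Atom(a.name, a.element, perturbed[a.name])
        for a in dictionary.atoms
    ])
    ligand.kind = ResidueKind.ligand
    heavy_positions = np.array([a.position for a in ligand.heavy_atoms()])
    lig_centroid = heavy_positions.mean(axis=0)

    residues: list[Residue] = []

    def min_dist(point) -> float:
        return float(np.linalg.norm(heavy_positions - point, axis=1).min())

    placed_points: list[np.ndarray] = []

    def too_close(point, limit=3.0) -> bool:
        return any(np.linalg.norm(point - q) < limit for q in placed_points)

    n_pocket = spec.pocket_residues
    if spec.steric_block:
        # carbonyl O placed near where O1 sits at the unperturbed torsion
        # target, so repulsion forces the in-situ torsion off that target ...
        target_o1 = truth["O1"]
        outward = target_o1 - truth["C1"]
        outward /= np.linalg.norm(outward)
        anchor = target_o1 + spec.block_distance * outward
        residues.append(_gly_fragment(anchor, outward, truth["C1"]))
        placed_points.append(anchor)
        # ... while a snug pre-loaded cage of carbonyl contacts around the
        # rest of the ligand blocks the rigid-body escape route: opposing
        # pre-stressed contacts leave no net force but penalize any
        # translation or rotation of the cluster quadratically
        from .elements import vdw_radius
        n_cage, prestress = 26, 0.15
        golden = math.pi * (1.0 + math.sqrt(5.0))
        cage_dirs = []
        for i in range(n_cage):
            z = 1.0 - 2.0 * (i + 0.5) / n_cage
            rho = math.sqrt(1.0 - z * z)
            theta = golden * (i + 0.5)
            cage_dirs.append(np.array([rho * math.cos(theta),
                                       rho * math.sin(theta), z]))
        heavies = [a for a in ligand.heavy_atoms() if a.name != "O1"]
        all_pos = np.array([a.position for a in heavies])
        all_r0 = np.array([0.75 * (vdw_radius("O") + vdw_radius(a.element))
                           for a in heavies])
        for u in cage_dirs:
            extreme = max(heavies,
                          key=lambda a: float(np.dot(a.position - lig_centroid, u)))
            # slide outward to the touching distance, then preload slightly
            t = 0.0
            for _ in range(200):
                q = extreme.position + u * (1.0 + t)
                clearance = float(np.min(
                    np.linalg.norm(all_pos - q, axis=1) - all_r0))
                if clearance >= 0.0:
                    t -= clearance  # exact touch
                    break
                t += max(-clearance, 0.01)
            point = extreme.position + u * (1.0 + t - prestress)
            residues.append(_gly_fragment(point, u, lig_centroid))
            placed_points.append(point)

    attempts = 0
    while n_pocket > 0 and attempts < 500:
        attempts += 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        anchor = lig_centroid + direction * (
            np.max(np.linalg.norm(heavy_positions - lig_centroid, axis=1))
            + 3.2)
        if min_dist(anchor) < 3.0 or min_dist(anchor) > 3.45 or \
                too_close(anchor):
            # pull the anchor to 3.2 Å from the nearest ligand atom
            dists = np.linalg.norm(heavy_positions - anchor, axis=1)
            nearest = heavy_positions[int(np.argmin(dists))]
            pull = anchor - nearest
            anchor = nearest + pull / np.linalg.norm(pull) * 3.2
            if too_close(anchor):
                continue
        residues.append(_gly_fragment(anchor, direction, lig_centroid))
        placed_points.append(anchor)
        n_pocket -= 1

    polar = [ligand.get_atom("O1"), ligand.get_atom("N1")]
    for w in range(spec.n_waters):
        parent = polar[w % len(polar)]
        direction = parent.position - lig_centroid
        direction /= np.linalg.norm(direction)
        jitter = rng.normal(scale=0.1, size=3)
        point = parent.position + direction * 2.9 + jitter
        if too_close(point, 2.4):
            point = point + direction * 1.0
        water = Residue("HOH", "W", w + 1,
                        atoms=[Atom("O", "O", point)])
        water.kind = ResidueKind.water
        residues.append(water)
        placed_points.append(point)

    for i, residue in enumerate(r for r in residues if r.chain_id == "P"):
        residue.seq_id = i + 1

    model = StructureModel(residues + [ligand], cell,
                           spacegroup_operators(spec.space_group),
                           resolution=1.8, id=f"fixture-{spec.seed}",
                           spacegroup=spec.space_group)
    model.renumber_serials()

    ground_truth = {
        "positions": truth,
        "rotatable_torsion": ROTATABLE_TORSION,
        "pucker_torsion": PUCKER_TORSION,
        "propeller_torsion": PROPELLER_TORSION,
        "probe_angle": ("O1", "C1", "C2"),
        "probe_bond": ("C1", "O1"),
    }
    return model, dictionary, ground_truth
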