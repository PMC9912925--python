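"""Ligand restraint dictionaries in monomer-library-style CIF.

A dictionary holds the typed bond/angle/torsion/plane/chirality restraints of
one chemical component together with its atom roster. The defining operation
is :func:`generate_qmr_restraints`: measure every bond, angle and torsion
from an in-situ optimized geometry and use those values as the new targets,
keeping the estimated standard deviations of the base dictionary. Torsions in
the generated dictionary become unimodal (period 1, no alternative targets):
once the in-situ minimum is known there is no rotational ambiguity left to
encode.

Aperiodic alternative torsion targets (the ring-pucker mechanism) have no
column in the standard monomer-library format; they are serialized under the
namespaced extension loop ``_qmr_tor_alt`` and recovered on parse.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import FormatError, GenerationError, ValidationError
from .geometry import bond_length, torsion_angle, valence_angle, wrap_angle

DEFAULT_BOND_ESD = 0.02    # Å, conventional bond-length sigma
DEFAULT_ANGLE_ESD = 2.0    # deg, typical valence-angle sigma
DEFAULT_TORSION_ESD = 30.0  # deg, torsions are weakly restrained


@dataclass(frozen=True)
class AtomSpec:
    name: str
    element: str
    charge: float = 0.0


@dataclass(frozen=True)
class BondRestraint:
    atoms: tuple[str, str]
    target: float
    esd: float

    def __post_init__(self):
        if self.target <= 0 or self.esd <= 0:
            raise ValidationError(f"bond {self.atoms}: target/esd must be > 0")


@dataclass(frozen=True)
class AngleRestraint:
    atoms: tuple[str, str, str]
    target: float
    esd: float

    def __post_init__(self):
        if not 0.0 < self.target < 180.0:
            raise ValidationError(f"angle {self.atoms}: target outside (0,180)")
        if self.esd <= 0:
            raise ValidationError(f"angle {self.atoms}: esd must be > 0")


@dataclass(frozen=True)
class TorsionRestraint:
    atoms: tuple[str, str, str, str]
    target: float
    esd: float
    periodicity: int = 1
    alternatives: Optional[tuple[float, ...]] = None
    label: str = ""

    def __post_init__(self):
        if self.periodicity < 1:
            raise ValidationError(f"torsion {self.atoms}: periodicity < 1")
        if self.esd <= 0:
            raise ValidationError(f"torsion {self.atoms}: esd must be > 0")
        object.__setattr__(self, "target", wrap_angle(self.target))
        if self.alternatives is not None:
            object.__setattr__(
                self, "alternatives",
                tuple(wrap_angle(a) for a in self.alternatives))


@dataclass(frozen=True)
class PlaneRestraint:
    label: str
    atoms: tuple[str, ...]
    esd: float

    def __post_init__(self):
        if len(self.atoms) < 4:
            raise ValidationError(f"plane {self.label}: needs >= 4 atoms")


@dataclass(frozen=True)
class ChiralRestraint:
    label: str
    center: str
    atoms: tuple[str, str, str]
    sign: str  # "positive" | "negative" | "both"

    def __post_init__(self):
        if self.sign not in ("positive", "negative", "both"):
            raise ValidationError(f"chiral {self.label}: bad sign {self.sign!r}")


@dataclass
class RestraintDictionary:
    comp_id: str
    atoms: list[AtomSpec] = field(default_factory=list)
    bonds: list[BondRestraint] = field(default_factory=list)
    angles: list[AngleRestraint] = field(default_factory=list)
    torsions: list[TorsionRestraint] = field(default_factory=list)
    planes: list[PlaneRestraint] = field(default_factory=list)
    chirals: list[ChiralRestraint] = field(default_factory=list)
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValidationError(f"{self.comp_id}: duplicate roster atom names")
        roster = set(names)
        offenders = []
        for group in (self.bonds, self.angles, self.torsions):
            for r in group:
                offenders.extend(n for n in r.atoms if n not in roster)
        for p in self.planes:
            offenders.extend(n for n in p.atoms if n not in roster)
        for c in self.chirals:
            for n in (c.center, *c.atoms):
                if n not in roster:
                    offenders.append(n)
        if offenders:
            raise ValidationError(
                f"{self.comp_id}: restraints reference unknown atoms "
                f"{sorted(set(offenders))}")

    # roster helpers -------------------------------------------------------
    def atom_names(self, heavy_only: bool = False) -> list[str]:
        return [a.name for a in self.atoms
                if not (heavy_only and a.element.upper() in ("H", "D"))]

    def element_of(self, name: str) -> str:
        for a in self.atoms:
            if a.name == name:
                return a.element
        raise KeyError(name)

    def copy(self) -> "RestraintDictionary":
        return copy.deepcopy(self)


DictionarySet = Mapping[str, RestraintDictionary]


# ------------------------------------------------------------------ CIF I/O

_ALT_TAG = "_qmr_tor_alt"


def parse_dictionary(cif_text: str) -> RestraintDictionary:
    """Parse one component from monomer-library-style CIF text."""
    import gemmi.cif

    try:
        doc = gemmi.cif.read_string(cif_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"unparseable restraint CIF: {exc}") from exc

    block = None
    for b in doc:
        if b.find_loop("_chem_comp_atom.atom_id"):
            block = b
            break
    if block is None:
        raise FormatError("no _chem_comp_atom loop found in restraint CIF")

    def rows(prefix: str, tags: Sequence[str]) -> list[list[str]]:
        table = block.find(prefix, list(tags))
        out = []
        for row in table:
            out.append([row.str(i) if row.has(i) else None
                        for i in range(len(tags))])
        return out

    atoms = []
    comp_id = ""
    for row in rows("_chem_comp_atom.", ["comp_id", "atom_id", "type_symbol",
                                         "?charge"]):
        comp_id = row[0]
        charge = float(row[3]) if row[3] not in (None, "", ".", "?") else 0.0
        atoms.append(AtomSpec(row[1], row[2], charge))
    if not atoms:
        raise FormatError("empty _chem_comp_atom loop in restraint CIF")

    def num(value: str, what: str) -> float:
        try:
            return float(value)
        except (TypeError, ValueError):
            raise FormatError(f"bad numeric field in {what}: {value!r}")

    bonds = [
        BondRestraint((r[0], r[1]), num(r[2], "_chem_comp_bond"),
                      num(r[3], "_chem_comp_bond"))
        for r in rows("_chem_comp_bond.",
                      ["atom_id_1", "atom_id_2", "value_dist", "value_dist_esd"])
    ]
    angles = [
        AngleRestraint((r[0], r[1], r[2]), num(r[3], "_chem_comp_angle"),
                       num(r[4], "_chem_comp_angle"))
        for r in rows("_chem_comp_angle.",
                      ["atom_id_1", "atom_id_2", "atom_id_3",
                       "value_angle", "value_angle_esd"])
    ]

    alternatives: dict[str, list[float]] = {}
    for r in rows(_ALT_TAG + ".", ["tor_id", "value"]):
        alternatives.setdefault(r[0], []).append(float(r[1]))

    torsions = []
    for r in rows("_chem_comp_tor.",
                  ["id", "atom_id_1", "atom_id_2", "atom_id_3", "atom_id_4",
                   "value_angle", "value_angle_esd", "?period"]):
        period = 1
        if r[7] not in (None, "", ".", "?"):
            period = int(float(r[7]))
        alts = alternatives.get(r[0])
        torsions.append(TorsionRestraint(
            (r[1], r[2], r[3], r[4]), num(r[5], "_chem_comp_tor"),
            num(r[6], "_chem_comp_tor"), period,
            tuple(alts) if alts else None, label=r[0]))

    planes: dict[str, dict] = {}
    for r in rows("_chem_comp_plane_atom.", ["plane_id", "atom_id", "dist_esd"]):
        entry = planes.setdefault(r[0], {"atoms": [], "esd": float(r[2])})
        entry["atoms"].append(r[1])
    plane_list = [PlaneRestraint(pid, tuple(e["atoms"]), e["esd"])
                  for pid, e in planes.items()]

    chirals = [
        ChiralRestraint(r[0], r[1], (r[2], r[3], r[4]), _sign_from_cif(r[5]))
        for r in rows("_chem_comp_chir.",
                      ["id", "atom_id_centre", "atom_id_1", "atom_id_2",
                       "atom_id_3", "volume_sign"])
    ]

    charge = 0
    comp_row = block.find_value("_chem_comp.pdbx_formal_charge") or \
        block.find_value("_qmr_comp.formal_charge")
    if comp_row not in (None, "", ".", "?"):
        charge = int(float(comp_row))

    try:
        return RestraintDictionary(comp_id, atoms, bonds, angles, torsions,
                                   plane_list, chirals, charge)
    except ValidationError:
        raise


def _sign_from_cif(token: str) -> str:
    token = token.strip().lower()
    return {"positiv": "positive", "positive": "positive", "+": "positive",
            "negativ": "negative", "negative": "negative", "-": "negative",
            "both": "both", ".": "both"}.get(token, "both")


def _sign_to_cif(sign: str) -> str:
    return {"positive": "positiv", "negative": "negativ", "both": "both"}[sign]


def write_dictionary(d: RestraintDictionary) -> str:
    """Emit monomer-library-style CIF (round-trips through parse_dictionary).

    Bonds are printed with 3 decimals (Å); angles and torsions with 2 (deg).
    """
    import gemmi.cif

    doc = gemmi.cif.Document()
    block = doc.add_new_block(f"comp_{d.comp_id}")

    def loop(prefix: str, tags: list[str], rows: list[list[str]]) -> None:
        lp = block.init_loop(prefix, tags)
        for row in rows:
            lp.add_row(row)

    block.set_pair("_chem_comp.id", d.comp_id)
    block.set_pair("_chem_comp.pdbx_formal_charge", str(d.formal_charge))

    loop("_chem_comp_atom.", ["comp_id", "atom_id", "type_symbol", "charge"],
         [[d.comp_id, a.name, a.element, f"{a.charge:g}"] for a in d.atoms])
    loop("_chem_comp_bond.",
         ["comp_id", "atom_id_1", "atom_id_2", "value_dist", "value_dist_esd"],
         [[d.comp_id, b.atoms[0], b.atoms[1], f"{b.target:.3f}", f"{b.esd:.3f}"]
          for b in d.bonds])
    loop("_chem_comp_angle.",
         ["comp_id", "atom_id_1", "atom_id_2", "atom_id_3",
          "value_angle", "value_angle_esd"],
         [[d.comp_id, *a.atoms, f"{a.target:.2f}", f"{a.esd:.2f}"]
          for a in d.angles])
    tor_rows, alt_rows = [], []
    for i, t in enumerate(d.torsions, start=1):
        label = t.label or f"tor_{i}"
        tor_rows.append([d.comp_id, label, *t.atoms, f"{t.target:.2f}",
                         f"{t.esd:.2f}", str(t.periodicity)])
        for alt in (t.alternatives or ()):
            alt_rows.append([d.comp_id, label, f"{alt:.2f}"])
    loop("_chem_comp_tor.",
         ["comp_id", "id", "atom_id_1", "atom_id_2", "atom_id_3", "atom_id_4",
          "value_angle", "value_angle_esd", "period"], tor_rows)
    if alt_rows:
        loop(_ALT_TAG + ".", ["comp_id", "tor_id", "value"], alt_rows)
    loop("_chem_comp_chir.",
         ["comp_id", "id", "atom_id_centre", "atom_id_1", "atom_id_2",
          "atom_id_3", "volume_sign"],
         [[d.comp_id, c.label, c.center, *c.atoms, _sign_to_cif(c.sign)]
          for c in d.chirals])
    plane_rows = []
    for p in d.planes:
        plane_rows.extend([[d.comp_id, p.label, name, f"{p.esd:.3f}"]
                           for name in p.atoms])
    loop("_chem_comp_plane_atom.",
         ["comp_id", "plane_id", "atom_id", "dist_esd"], plane_rows)

    return doc.as_string()


# --------------------------------------------------------- target generation

def generate_qmr_restraints(optimized, base: RestraintDictionary,
                            require_h: bool = False) -> RestraintDictionary:
    """Replace bond/angle/torsion targets with values measured in-situ.

    ``optimized`` is a Residue or a name → position mapping covering the base
    roster (hydrogens may be absent unless ``require_h``). E.s.d.s are carried
    over from the base dictionary; torsions become period-1 with no
    alternative targets; planes, chirality and formal charge are copied
    unchanged. Restraints with hydrogen atoms missing from the coordinates
    are copied unchanged rather than re-measured.
    """
    from .model import Residue

    if isinstance(optimized, Residue):
        coords = {a.name: a.position for a in optimized.atoms}
    else:
        coords = dict(optimized)

    hydrogens = {a.name for a in base.atoms if a.element.upper() in ("H", "D")}
    missing_heavy = [a.name for a in base.atoms
                     if a.name not in coords and a.name not in hydrogens]
    missing_h = [a.name for a in base.atoms
                 if a.name not in coords and a.name in hydrogens]
    if missing_heavy or (require_h and missing_h):
        raise GenerationError(
            f"{base.comp_id}: optimized geometry lacks roster atoms "
            f"{sorted(missing_heavy + (missing_h if require_h else []))}")

    def have(names) -> bool:
        return all(n in coords for n in names)

    bonds = [
        replace(b, target=round(bond_length(coords[b.atoms[0]],
                                            coords[b.atoms[1]]), 4))
        if have(b.atoms) else b
        for b in base.bonds
    ]
    angles = [
        replace(a, target=round(valence_angle(*(coords[n] for n in a.atoms)), 3))
        if have(a.atoms) else a
        for a in base.angles
    ]
    torsions = []
    for t in base.torsions:
        if have(t.atoms):
            measured = round(torsion_angle(*(coords[n] for n in t.atoms)), 3)
            torsions.append(TorsionRestraint(t.atoms, measured, t.esd,
                                             periodicity=1, alternatives=None,
                                             label=t.label))
        else:
            torsions.append(t)

    return RestraintDictionary(
        base.comp_id, list(base.atoms), bonds, angles, torsions,
        copy.deepcopy(base.planes), copy.deepcopy(base.chirals),
        base.formal_charge)
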