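"""Per-element constants and atom-name → element inference.

Covalent radii follow Cordero et al.'s consensus single-bond values; van der
Waals radii are Bondi's. Both tables cover the elements that occur in
protein–ligand models; anything else falls back to generic defaults.
"""

from __future__ import annotations

# single-bond covalent radii, Å
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "D": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "B": 0.84,
    "SE": 1.20, "SI": 1.11,
    "NA": 1.66, "MG": 1.41, "K": 2.03, "CA": 1.76, "MN": 1.39, "FE": 1.32,
    "CO": 1.26, "NI": 1.24, "CU": 1.32, "ZN": 1.22, "CD": 1.44, "HG": 1.32,
}

# Bondi van der Waals radii, Å (used for soft-repulsion reference distances)
VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "B": 1.92,
    "SE": 1.90, "SI": 2.10,
}

ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "B": 10.81, "SE": 78.971, "SI": 28.085,
    "NA": 22.990, "MG": 24.305, "K": 39.098, "CA": 40.078, "MN": 54.938,
    "FE": 55.845, "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38,
    "CD": 112.414, "HG": 200.592,
}

# elements treated as metals for environment validation
METALS: frozenset[str] = frozenset({
    "LI", "NA", "K", "RB", "CS", "BE", "MG", "CA", "SR", "BA",
    "MN", "FE", "CO", "NI", "CU", "ZN", "CD", "HG", "AL", "GA",
    "V", "CR", "MO", "W", "PT", "PD", "AU", "AG", "PB", "SN",
})

_TWO_LETTER = frozenset(
    e for e in set(COVALENT_RADII) | METALS if len(e) == 2
)

DEFAULT_COVALENT_RADIUS = 1.5
DEFAULT_VDW_RADIUS = 2.0
DEFAULT_ATOMIC_WEIGHT = 30.0


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element.upper(), DEFAULT_COVALENT_RADIUS)


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def atomic_weight(element: str) -> float:
    return ATOMIC_WEIGHTS.get(element.upper(), DEFAULT_ATOMIC_WEIGHT)


def is_metal(element: str) -> bool:
    return element.upper() in METALS


def element_from_atom_name(name: str, comp_is_standard: bool = True) -> str:
    """Infer the element from a PDB-style atom name.

    Follows the fixed-column convention: in standard residues the element is
    the first non-digit character run ("CA" in an amino acid is carbon); a
    two-letter symbol is assumed only when the name itself starts with a
    known two-letter element and the residue is not a standard polymer
    component (so "CA" in residue CA is calcium, "CL" is chlorine).
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if not comp_is_standard:
        two = stripped[:2].upper()
        if two in _TWO_LETTER and two not in {"CD"}:  # CD is a common Cδ name
            return two.capitalize()
        if two in {"CD"} and stripped.upper() == "CD":
            return "Cd"
    first = stripped[0].upper()
    if first == "D":  # deuterium names
        return "D"
    return first
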