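"""Test-case selection rules for ligand instances.

A ligand instance qualifies when its entry resolution is at most 3.0 Å, its
cluster environment is clean, the map–model correlation is at least 0.7, it
has 8–40 non-hydrogen atoms (inclusive), a formal charge in {-1, 0, +1}, its
component is not a common crystallization-solution ingredient, and at least
one geometry category shows substantial strain under the baseline restraints
(mean r.m.s.d. ≥ 0.2 Å for bonds OR ≥ 5° for angles OR ≥ 30° for torsions —
any single trigger suffices). Every criterion is logged with its observed
value so the verdict is a full audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .cluster import EnvironmentReport
from .model import ResidueKind, StructureModel

RESOLUTION_MAX = 3.0
MAP_CC_MIN = 0.7
NON_H_MIN, NON_H_MAX = 8, 40
ALLOWED_CHARGES = (-1, 0, 1)
RMSD_TRIGGERS = {"bonds": 0.2, "angles": 5.0, "torsions": 30.0}
MOLECULAR_WEIGHT_MAX_KDA = 2000.0

# user-extensible default exclusion list of crystallization-solution components
COMMON_SOLVENT_COMPONENTS: set[str] = {
    "MES", "PEG", "PGE", "PG4", "EDO", "GOL", "DMS", "ACT", "FMT",
    "SO4", "PO4", "EPE", "TRS", "MPD",
}


def is_common_solvent(comp_id: str,
                      extra: Optional[set[str]] = None) -> bool:
    comp = comp_id.strip().upper()
    return comp in COMMON_SOLVENT_COMPONENTS or \
        (extra is not None and comp in {e.upper() for e in extra})


@dataclass
class LigandInstanceMeta:
    entry_id: str
    comp_id: str
    ligand_selector: tuple
    resolution: Optional[float] = None
    map_cc: Optional[float] = None
    non_h_atoms: Optional[int] = None
    formal_charge: Optional[int] = None
    mean_rmsd_bonds: Optional[float] = None
    mean_rmsd_angles: Optional[float] = None
    mean_rmsd_torsions: Optional[float] = None

    def __post_init__(self):
        if self.map_cc is not None and not 0.0 <= self.map_cc <= 1.0:
            raise ValueError(f"map_cc {self.map_cc} outside [0, 1]")
        if self.non_h_atoms is not None and self.non_h_atoms < 0:
            raise ValueError("non_h_atoms must be non-negative")


@dataclass
class CriterionResult:
    criterion: str
    passed: Optional[bool]   # None = indeterminate (missing metadata)
    observed: object
    threshold: str


@dataclass
class ScreeningVerdict:
    reasons: list[CriterionResult] = field(default_factory=list)

    @property
    def passed(self) -> Optional[bool]:
        if any(r.passed is None for r in self.reasons):
            return None
        return all(r.passed for r in self.reasons)

    @property
    def indeterminate_fields(self) -> list[str]:
        return [r.criterion for r in self.reasons if r.passed is None]

    def to_rows(self) -> list[dict]:
        return [
            {"criterion": r.criterion, "passed": r.passed,
             "observed": r.observed, "threshold": r.threshold}
            for r in self.reasons
        ]


def screen_ligand(meta: LigandInstanceMeta,
                  env: EnvironmentReport,
                  solvent_extra: Optional[set[str]] = None) -> ScreeningVerdict:
    """Evaluate every selection criterion; never silently passes on gaps."""
    verdict = ScreeningVerdict()

    def check(name, value, predicate, threshold):
        passed = None if value is None else bool(predicate(value))
        verdict.reasons.append(CriterionResult(name, passed, value, threshold))

    check("resolution", meta.resolution,
          lambda v: v <= RESOLUTION_MAX, f"<= {RESOLUTION_MAX} Å")
    check("environment_clean", env.clean, lambda v: v, "clean cluster")
    check("map_cc", meta.map_cc, lambda v: v >= MAP_CC_MIN, f">= {MAP_CC_MIN}")
    check("non_h_atoms", meta.non_h_atoms,
          lambda v: NON_H_MIN <= v <= NON_H_MAX,
          f"{NON_H_MIN}–{NON_H_MAX} inclusive")
    check("formal_charge", meta.formal_charge,
          lambda v: v in ALLOWED_CHARGES, "in {-1, 0, +1}")

    rmsd = (meta.mean_rmsd_bonds, meta.mean_rmsd_angles,
            meta.mean_rmsd_torsions)
    if any(v is None for v in rmsd):
        trigger = None
    else:
        trigger = (rmsd[0] >= RMSD_TRIGGERS["bonds"]
                   or rmsd[1] >= RMSD_TRIGGERS["angles"]
                   or rmsd[2] >= RMSD_TRIGGERS["torsions"])
    verdict.reasons.append(CriterionResult(
        "rmsd_trigger", trigger, rmsd,
        ">= 0.2 Å bonds OR >= 5° angles OR >= 30° torsions"))

    check("not_common_solvent", meta.comp_id,
          lambda v: not is_common_solvent(v, solvent_extra),
          "not a common crystallization-solution component")
    return verdict


# ------------------------------------------------------ entry-level prefilters

def entry_prefilter(model: StructureModel) -> dict[str, bool]:
    """Model-level predicates applied before per-ligand screening:
    molecular weight below 2000 kDa and no RNA/DNA residues."""
    weight_kda = model.molecular_weight() / 1000.0
    has_nucleic = any(r.kind is ResidueKind.nucleotide for r in model.residues)
    has_ligand = any(r.kind is ResidueKind.ligand for r in model.residues)
    return {
        "weight_ok": weight_kda < MOLECULAR_WEIGHT_MAX_KDA,
        "no_nucleic_acid": not has_nucleic,
        "has_ligand": has_ligand,
    }
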