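"""Symmetry-image search and test-case screening.

A single atom in a 5 Å cubic P 1 cell has six lattice neighbors within
5.1 Å; the screening rules then decide whether a hypothetical ligand
instance qualifies as a test case.
"""

import numpy as np

from qmrestraints import (Atom, Residue, ResidueKind, StructureModel,
                          UnitCell, symmetry_images_within)
from qmrestraints.cluster import EnvironmentReport
from qmrestraints.screening import LigandInstanceMeta, screen_ligand
from qmrestraints.symcell import spacegroup_operators

residue = Residue("LIG", "A", 1, atoms=[Atom("C1", "C", np.zeros(3), serial=1)])
residue.kind = ResidueKind.ligand
model = StructureModel([residue], UnitCell(5, 5, 5),
                       spacegroup_operators("P 1"), spacegroup="P 1")
images = symmetry_images_within(model, [1], 5.1)
print(f"lattice images within 5.1 A of the atom: {len(images)}")
for img in images[:3]:
    print("  shift", img.lattice_shift, "at", np.round(img.position, 2))

meta = LigandInstanceMeta(
    entry_id="demo", comp_id="BER", ligand_selector=("D", "BER", 1),
    resolution=2.34, map_cc=0.76, non_h_atoms=27, formal_charge=1,
    mean_rmsd_bonds=0.007, mean_rmsd_angles=2.4, mean_rmsd_torsions=48.2)
clean = EnvironmentReport(False, [], False, [], False, [], False, [])
verdict = screen_ligand(meta, clean)
print("screening verdict:", verdict.passed)
for reason in verdict.reasons:
    print(f"  {reason.criterion:20s} {str(reason.passed):5s} "
          f"observed={reason.observed} ({reason.threshold})")
# The torsion r.m.s.d. of 48.2° alone satisfies the strain trigger (OR
# semantics); all other criteria pass, so the instance qualifies.
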