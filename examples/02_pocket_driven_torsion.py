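"""A snug pocket that forces a torsion away from its generic target.

The fixture places a carbonyl oxygen where the ligand's rotatable torsion
would put its O1 atom at the generic target (60°), inside a tight contact
cage. The in-situ optimum therefore sits in a different torsion basin, and
the generated restraint records that pocket-compatible value while the base
dictionary keeps its generic one.
"""

from qmrestraints import FixtureSpec, generate_fixture, run_pipeline

spec = FixtureSpec(seed=3, steric_block=True, pocket_residues=0, n_waters=0)
model, base_dictionary, truth = generate_fixture(spec)

result = run_pipeline(model, ("A", "LIG", 1), base_dictionary, max_steps=6000)

names = truth["rotatable_torsion"]
base = next(t for t in base_dictionary.torsions if t.atoms == names)
qmr = next(t for t in result.qmr_dictionary.torsions if t.atoms == names)

print("rotatable torsion", "-".join(names))
print(f"  generic target   : {base.target:8.1f} deg")
print(f"  in-situ target   : {qmr.target:8.1f} deg  (period {qmr.periodicity})")
print(f"  shift            : {qmr.target - base.target:8.1f} deg")
# The shift shows the environment dictating the conformation: restraints
# generated in vacuo cannot know about the clash, in-situ ones can.
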