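"""Generate in-situ restraints for a perturbed ligand in a toy pocket.

Builds a synthetic fixture whose rotatable torsions are displaced 40° from
the dictionary targets, runs the full workflow (cluster → cap → protonate →
optimize → generate), and prints the torsion r.m.s.d. before and after.
"""

from qmrestraints import FixtureSpec, generate_fixture, run_pipeline

spec = FixtureSpec(seed=1, perturbation=(0.0, 0.0, 40.0))
model, base_dictionary, _ = generate_fixture(spec)

result = run_pipeline(model, ("A", "LIG", 1), base_dictionary, max_steps=4000)

print("environment clean:", result.environment.clean)
print("optimizer converged:", result.optimization.converged,
      f"in {result.optimization.n_steps} iterations")
print(f"torsion rmsd vs base set, input coords : "
      f"{result.report_base_before.rmsd_torsions:8.3f} deg")
print(f"torsion rmsd vs base set, optimized    : "
      f"{result.report_base_after.rmsd_torsions:8.3f} deg")
print(f"torsion rmsd vs generated set          : "
      f"{result.report_qmr_after.rmsd_torsions:8.5f} deg")
# The first number is the built-in strain of the input model (the 40°
# displacement); the optimizer relaxes it inside the rigid pocket, and the
# generated dictionary matches the optimized geometry essentially exactly.
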