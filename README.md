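# qmrestraints

Ligand restraint dictionaries for macromolecular crystallographic refinement
are usually generated in vacuo or in solvent, so their torsion targets — and
ring-pucker conformations — can disagree with the conformation a ligand
actually adopts in its binding pocket. `qmrestraints` implements the
*in-situ* alternative: extract the ligand together with its whole-residue
environment (including crystallographic symmetry images) from the model,
chemically complete that **ligand cluster** (hydrogen link atoms on cut
bonds, protons on bare-oxygen waters), optimize its geometry with a
pluggable backend, and measure the optimized ligand's internal coordinates
to produce a new restraint dictionary whose targets fit the pocket. It is
written for structural biologists refining protein–ligand complexes and for
methods developers who need an auditable, scriptable implementation of each
stage.

## The core quantities

A restraint is an ideal value with an estimated standard deviation (e.s.d.
σ): bonds (σ ≈ 0.02 Å), valence angles (σ ≈ 2°) and torsions (σ ≈ 30°,
because the in-pocket minimum is generally unknown). Torsion restraints may
be **periodic** — a period *n* target θ₀ has equivalent minima at
θ₀ + k·360°/n — or carry **aperiodic alternative targets** (the ring-pucker
mechanism). For a measured value θ the signed deviation is

    Δ = θ* − θ,   θ* = argmin over {θ₀ + k·360°/n} ∪ alternatives of |wrap(θc − θ)|

wrapped to (−180°, 180°], and per-category quality is the r.m.s.d.
√(mean Δ²) over all non-hydrogen restraints. Restraints generated in situ
(`generate_qmr_restraints`) replace every bond/angle/torsion target with the
value measured from the optimized geometry, keep the base e.s.d.s, and make
torsions unimodal (period 1, no alternatives) — once the in-situ minimum is
known, the rotational ambiguity is gone.

## Worked example

`examples/01_generate_restraints.py` builds a synthetic pocket whose ligand
has every restrained rotatable torsion displaced 40° from its dictionary
target, then runs the full workflow:

```
environment clean: True
optimizer converged: True in 235 iterations
torsion rmsd vs base set, input coords :   40.000 deg
torsion rmsd vs base set, optimized    :    0.000 deg
torsion rmsd vs generated set          :  0.00013 deg
```

The input model is 40° of torsion strain away from the generic targets; the
restrained optimization relaxes it inside the rigid pocket, and the
generated dictionary matches the optimized geometry essentially exactly.
`examples/02_pocket_driven_torsion.py` shows the opposite case — a pocket
clash that *forces* the torsion 117.6° away from the generic target, which
only the in-situ dictionary records:

```
rotatable torsion O1-C1-C2-C3
  generic target   :     60.0 deg
  in-situ target   :    -57.6 deg  (period 1)
  shift            :   -117.6 deg
```

The remaining examples demonstrate deviation arithmetic with wrapping and
periodicity (`03_deviation_tables.py`) and symmetry-image search plus
test-case screening (`04_symmetry_and_screening.py`).

## Command line

A thin CLI wraps the library:

```sh
qmr fixture --seed 2 --perturb 0,0,30 -o fx          # synthetic input
qmr run fx/model.pdb --ligand A/LIG/1 --dict fx/ligand.cif -o out
qmr report fx/model.pdb --ligand A/LIG/1 --dict fx/ligand.cif
qmr validate fx/model.pdb --ligand A/LIG/1 --dict fx/ligand.cif
```

`qmr run` persists the capped/protonated cluster PDB (with a remark block
listing cut bonds, caps and symmetry provenance), the generated restraint
CIF and before/after deviation reports.

## What the builtin optimizer is (and is not)

The `builtin` backend minimizes the dictionary-restraint objective
(σ-weighted bonds/angles, periodic cosine torsion wells, soft nonbonded
repulsion) with a deterministic quasi-Newton driver. It is **not** a quantum
mechanical method; it exists so the full pipeline runs and is testable at
desk scale. Production restraints should come from a semi-empirical engine
through the file-level adapter (`write_external_input` /
`parse_external_output`, MOPAC-style Cartesian decks with per-atom
fixed-coordinate flags). See `docs/methods.md` for the model, parameters and
limitations.
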