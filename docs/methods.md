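# Methods

This note records the models, conventions, parameters and deliberate design
choices behind `qmrestraints`, and what the synthetic fixtures do and do not
demonstrate.

## The ligand cluster

The cluster is the ligand plus every residue — model-native or
crystallographic symmetry image — that has at least one atom within a cutoff
radius (default **3.5 Å**, `--radius`) of any ligand atom, always copied
whole: partial residues would leave unphysical fragments for an all-electron
(or restraint-field) optimization. Symmetry images are found by enumerating
every (operator, lattice shift) pair over an integer shift box derived from
the radius and the per-axis lattice-plane spacings (`ceil(radius/height)+1`
in each direction), which is correct for arbitrarily oblique cells without
unbounded search. Images within 0.1 Å of their source atom sit on special
positions and are dropped as duplicates. Every image residue carries
(operator index, lattice shift) provenance, gets fresh atom serials, and is
exported into the cluster PDB remark block for auditability.

Coordinates are Cartesian Å everywhere; fractional coordinates exist only
inside the symmetry module. Orthogonalization uses the standard
crystallographic frame (a along x, b in the xy-plane); the in-package
implementation is cross-checked against gemmi's in the tests.

## Chemical completion

Cutting the cluster out of the polymer leaves dangling bonds. Default
(neutral) termination replaces the removed partner with a hydrogen link atom
on the former bond vector at the standard element–H distance (C–H 1.09 Å,
N–H 1.01 Å, O–H 0.96 Å) — the smallest perturbation and common QM/MM
practice. Zwitterion mode instead completes backbone cuts to charged
termini: a cut carbonyl carbon gains a second carboxylate oxygen at 1.25 Å
along the former C→N vector, a cut backbone nitrogen is filled to NH₃⁺ with
approximately tetrahedral geometry. The exact zwitterion construction is not
standardized anywhere authoritative; this is the package's documented
choice, and non-backbone cuts always fall back to hydrogen caps.

Crystallographic waters arrive as bare O atoms and are protonated with O–H
0.96 Å and H–O–H 104.5°. Orientation is a documented heuristic: protons
point toward the nearest two hydrogen-bond acceptors (O/N within 3.5 Å,
ties broken by distance then serial), one acceptor fixes the first proton
and the second completes the angle in a deterministic plane, and an isolated
water uses a canonical frame. Protonation is idempotent and bit-reproducible;
a water with more than two protons is rejected. Ligand protonation is never
invented — the input model is taken as given.

Validation follows the selection rules used for screening: no other ligands,
metals or alternate conformations within **5.5 Å** of the ligand (measured
on the input model, before hydrogen addition; the ligand's own altlocs
count), and no missing expected heavy atoms within **3.5 Å**. Expected
rosters come from supplied dictionaries, a built-in table for the 20
standard amino acids (OXT optional), or {O} for waters; residues with no
roster are reported as unknown components rather than failures. Native
residues only are screened; a symmetry-related offender is not detected,
a known limitation.

## The optimization backend

`OptimizationJob.method = "builtin"` minimizes a restraint-field objective
over the mobile atoms (default: ligand + caps + water protons; optionally
protein side chains; symmetry-image atoms are always immobile because moving
them would desynchronize them from their sources):

- bonds and angles: ((target − value)/σ)², values in Å and degrees;
- torsions: a periodic cosine well A·(1 − cos n(θ − θ₀)) with
  A = 2(180/π)²/(n²σ²), which matches the harmonic curvature (Δ/σ)² at the
  minimum; a torsion with aperiodic alternatives uses the well centered on
  the nearest candidate target;
- nonbonded soft repulsion ((r₀ − r)/0.2 Å)² for r < r₀ with
  r₀ = 0.75·(vdW_i + vdW_j), over pairs more than three bonds apart
  (1-2/1-3/1-4 excluded so bonded terms alone govern local geometry).

Gradients are analytic (verified against finite differences in the tests).
The driver is scipy's L-BFGS-B: the objective mixes very stiff bond terms
(1/0.02² Å⁻²) with very soft torsion wells (≈1/30² deg⁻²), a conditioning
regime where first-order descent crawls while a quasi-Newton method
converges in a few hundred iterations. The driver is deterministic, accepted
iterates are monotonically decreasing (the recorded trace is non-increasing),
immobile atoms are exactly fixed, convergence is max |gradient| < 1e-4
(objective units/Å) or `max_steps` (default 2000), non-convergence returns
`converged=False` rather than raising, and a gradient above 1e6 aborts with
diagnostics.

This backend is explicitly **not** a quantum-mechanical method: its physics
is the base dictionary plus excluded-volume repulsion, so it can never
discover chemistry the dictionary does not encode (no polarization, no
hydrogen-bond directionality, no charge transfer). It exists to make the
pipeline testable end to end. External engines plug in at file level: a
MOPAC-style Cartesian deck (`method keyword + CHARGE=n`, one
`element x flag y flag z flag` row per atom, flag 0 = fixed) and a parser
for the final coordinate block and heat-of-formation scalar. Results are
cached in a JSON sidecar keyed by a SHA-256 content hash of the job
(method, charge, mobile set, coordinates rounded to 1e-6 Å), so repeated
runs re-use the optimization.

## Restraint generation semantics

`generate_qmr_restraints` replaces every bond, angle and torsion target with
the value measured from the optimized geometry and copies the e.s.d.s from
the base dictionary. Torsions become period 1 with no alternative targets:
the defining semantic of in-situ restraints is that the pocket has already
chosen the minimum. Planes and chirality are copied unchanged — re-deriving
planes from a slightly puckered optimized geometry would wrongly
de-planarize aromatics, and chirality cannot change during a continuous
optimization. Restraints involving hydrogens are re-measured when the
hydrogens have coordinates and copied unchanged otherwise. A base restraint
with a malformed (missing/zero) e.s.d. receives the conventional defaults
0.02 Å / 2° / 30°.

Dictionaries are read and written in monomer-library-style CIF
(`_chem_comp_atom/_bond/_angle/_tor/_chir/_plane_atom`; torsion period from
the `period` column, defaulting to 1). Aperiodic alternative targets have no
standard column and are serialized under the namespaced extension loop
`_qmr_tor_alt.(comp_id, tor_id, value)`, recovered on parse. Numeric
formatting is 3 decimals for Å and 2 for degrees; round trips are lossless
to that precision.

## Deviation analysis

Δ = target − actual (this sign convention makes the published outlier tables
reproducible digit for digit), torsions wrapped to (−180°, 180°] after
choosing the nearest candidate among the periodicity-expanded targets plus
alternatives, ties broken toward the base target. Inputs outside the range
(e.g. a printed 210.9°) are normalized on ingest; the wrapped deviation is
unchanged. Per-category r.m.s.d. is computed over non-hydrogen restraints by
default (`include_h` flips this), matching how such statistics are
conventionally quoted; an empty category reports an undefined marker, never
zero. Periodicity-aware deviations are applied to every restraint set,
including generic ones. Outlier cutoffs default to 0.02 Å / 5° / 30°.

Resolution-binned summaries use one wide high-resolution bin (0.8–1.4 Å)
followed by 0.2 Å bins to 3.0 Å, assignment (low, high]; per bin they report
n, mean, s.e.m. = sd/√n (undefined for n < 2) and, for exactly two
conditions, a Welch two-sample t-test p-value.

## Screening rules

A ligand instance qualifies as a test case when: resolution ≤ 3.0 Å; clean
environment; map–model correlation ≥ 0.7 (supplied as metadata — computing
it needs structure factors, out of scope); 8–40 non-H atoms inclusive;
formal charge in {−1, 0, +1}; not a common crystallization-solution
component (default exclusion list MES, PEG, PGE, PG4, EDO, GOL, DMS, ACT,
FMT, SO4, PO4, EPE, TRS, MPD — user-extensible, since any fixed list is a
pragmatic default); and baseline strain in at least one category (mean
r.m.s.d. ≥ 0.2 Å bonds OR ≥ 5° angles OR ≥ 30° torsions). All bounds are
inclusive. Missing metadata yields an indeterminate verdict naming the
field, never a silent pass. Entry-level prefilters (molecular weight
< 2000 kDa, no nucleic-acid residues) are separate model predicates.

## The synthetic fixtures

The generator emulates the inputs of a restraint-generation run without any
deposited structure: a branched sp³ toy ligand (8 heavy atoms by default,
extendable) whose dictionary contains one rotatable torsion (target 60°,
σ 30°), one torsion with an aperiodic alternative target (the ring-pucker
mechanism), one period-3 propeller torsion on an NH₃ group, and a chirality
record; a shell of glycine fragments as the pocket; bare-oxygen waters near
the ligand's polar atoms; cell 30×32×34 Å, space group P 2₁2₁2₁. Dictionary
targets are *measured from the constructed ground-truth geometry*, so the
unperturbed fixture has identically zero deviations by construction.

Perturbations are applied in internal coordinates during construction: the
torsion magnitude is added to every restrained non-hydrogen torsion (each
lives on its own rotatable bond, so the perturbed torsion r.m.s.d. equals
the magnitude exactly), the angle magnitude to the O1–C1–C2 probe angle and
the bond magnitude to the C1–O1 probe bond (terminal-atom moves, so the
categories stay decoupled). All randomness (pocket directions, water jitter)
comes from the seed; equal seeds give byte-identical PDB/CIF output.

The steric-block variant places a carbonyl oxygen at 1.3 Å outside the
position O1 would occupy at the generic torsion target, inside a snug
26-direction pre-loaded contact cage (carbonyl oxygens touching the ligand
at the nonbonded reference distance minus 0.15 Å, directions from a
Fibonacci sphere). The cage is needed because a repulsion-only objective
cannot otherwise confine the cluster: with a single clash partner the ligand
simply drifts away as a rigid body. Opposing pre-loaded contacts exert no
net force but penalize any rigid motion quadratically, so the cheapest
escape from the blocker is the torsion rotation — the scenario the fixture
exists to produce. The pocket-compatible torsion is defined independently in
the tests by a 1-D scan of the objective over the torsion in the relaxed
cluster.

What passing fixture tests do **not** show about real data: the toy ligand
has idealized sp³ geometry and no aromatic systems; pockets are rigid
glycine fragments, not polarizable protein; the builtin objective is the
base dictionary itself, so recovery tests demonstrate the *plumbing*
(selection, capping, protonation, optimization, target generation, reporting)
and the *semantics* (periodicity, wrapping, self-consistency), not the
chemical accuracy of any quantum method.

## Numerical choices and degenerate inputs

- Distance-based bonding: d < 1.3 × (sum of covalent radii), dictionary
  bonds take precedence; peptide C–N bonds added below 1.7 Å between
  consecutive amino acids. H–H pairs are never bonded.
- Element inference for legacy PDB files without an element column follows
  the atom-name convention, with two-letter symbols honored only in
  non-standard components ("CA" is carbon in an amino acid, calcium in
  residue CA).
- Water synonyms: HOH, WAT, H2O, DOD.
- Torsions over collinear atoms raise an undefined-torsion error; degenerate
  cells (zero volume, angles outside (0°, 180°)) are configuration errors;
  a PDB write with > 99 999 atoms or 5+ character atom names is a
  serialization error.
- Ties in nearest-candidate selection go to the base target's candidate;
  wrapping maps −180° to +180°.
- The fixture problem sizes used by the test suite and the acceptance script
  (tens of atoms, ≤ 6000 optimizer iterations, 50-cell brute-force symmetry
  sweeps, 10⁴ randomized deviation triples) keep the whole suite under a
  minute on one CPU while still exercising every stage end to end.

## Known limitations

- No pKa prediction, histidine flip enumeration, or metal coordination
  chemistry; inputs are taken as protonated.
- Environment validation ignores symmetry-related offenders.
- Anisotropic displacement records, NMR ensembles and entity bookkeeping are
  out of scope for model I/O.
- Map–model correlation is consumed as metadata, never computed.
- The external-engine adapter covers the file contract only; no engine is
  bundled or invoked.
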