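"""Deviation arithmetic with torsion wrapping and periodicity.

Recomputes the signed deviations of published outlier rows for the berberine
ligand (target / actual value pairs) and shows the periodicity rule on the
methyl-propeller example.
"""

import math

from qmrestraints import signed_deviation, wrap_angle

rows = [
    ("bond", "C20-O4", 1.419, 1.394),
    ("angle", "C10-C7-N1", 109.7, 117.3),
    ("torsion", "C4-C10-C7-N1", 58.0, -18.7),
    ("torsion", "C1-C7-N1-C10", 43.0, -13.1),
    ("torsion", "C2-C10-C4-C7", 35.8, -12.4),
]

print(f"{'kind':8s} {'atoms':16s} {'target':>8s} {'actual':>8s} {'delta':>8s}")
deltas = []
for kind, atoms, target, actual in rows:
    if kind == "torsion":
        target = wrap_angle(target)
    delta = signed_deviation(kind, target, actual)
    deltas.append((kind, delta))
    print(f"{kind:8s} {atoms:16s} {target:8.3f} {actual:8.3f} {delta:8.3f}")

torsions = [d for k, d in deltas if k == "torsion"]
print(f"\ntorsion outlier rmsd: "
      f"{math.sqrt(sum(d * d for d in torsions) / len(torsions)):.1f} deg")

# a torsion with periodicity 3 has minima every 120°: an actual of 175° is
# only 5° from the 180° minimum even though the printed target is 60°
print("period-3 deviation of 175 deg from target 60 deg:",
      signed_deviation("torsion", 60.0, 175.0, periodicity=3), "deg")
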