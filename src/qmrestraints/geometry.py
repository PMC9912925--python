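"""Internal-coordinate measurement and restraint-deviation analysis.

Sign convention: delta = target - actual, so a bond modelled shorter than its
ideal value gives a positive delta. Torsions live in (-180, 180]; deviations
are computed against the nearest of the periodicity-expanded targets plus any
aperiodic alternative targets, and are wrapped back into (-180, 180].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedTorsionError, ValidationError

DEFAULT_CUTOFFS = (0.02, 5.0, 30.0)  # Å, deg, deg outlier thresholds


# ---------------------------------------------------------------- primitives

def bond_length(p1, p2) -> float:
    return float(np.linalg.norm(np.asarray(p2, float) - np.asarray(p1, float)))


def valence_angle(p1, p2, p3) -> float:
    """Angle at p2 in degrees, in [0, 180]."""
    u = np.asarray(p1, float) - np.asarray(p2, float)
    v = np.asarray(p3, float) - np.asarray(p2, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("zero-length bond vector in angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


def torsion_angle(p1, p2, p3, p4) -> float:
    """Dihedral 1-2-3-4 in degrees, in (-180, 180].

    IUPAC sign convention: looking from atom 2 towards atom 3, a clockwise
    rotation of the far bond relative to the near bond is positive; cis = 0.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise UndefinedTorsionError("collinear atoms: torsion undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = math.degrees(math.atan2(y, x))
    return wrap_angle(ang)


def wrap_angle(angle: float) -> float:
    """Wrap to (-180, 180]."""
    wrapped = ((angle + 180.0) % 360.0) - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return float(wrapped)


def signed_deviation(kind: str, target: float, actual: float,
                     periodicity: int = 1,
                     alternatives: Optional[Sequence[float]] = None) -> float:
    """delta = target - actual; torsions pick the nearest candidate target.

    Candidates are target + k*360/periodicity (k = 0..periodicity-1) plus the
    aperiodic alternatives; ties break towards the base target's candidate
    (candidates are considered in that order with a strict improvement rule).
    """
    if kind in ("bond", "angle"):
        return float(target - actual)
    if kind != "torsion":
        raise ValueError(f"unknown restraint kind {kind!r}")
    if periodicity < 1:
        raise ValidationError(f"torsion periodicity {periodicity} < 1")
    candidates = [target + k * 360.0 / periodicity for k in range(periodicity)]
    if alternatives:
        candidates.extend(alternatives)
    best = None
    for cand in candidates:
        delta = wrap_angle(cand - actual)
        if best is None or abs(delta) < abs(best) - 1e-12:
            best = delta
    return float(best)


# -------------------------------------------------------------------- report

@dataclass
class DeviationRecord:
    kind: str                       # bond | angle | torsion
    atoms: tuple[str, ...]
    target: float
    actual: float
    delta: float
    is_outlier: bool
    involves_h: bool = False

    @property
    def abs_delta(self) -> float:
        return abs(self.delta)


def _rmsd(deltas: Sequence[float]) -> Optional[float]:
    if not deltas:
        return None
    return float(math.sqrt(sum(d * d for d in deltas) / len(deltas)))


@dataclass
class GeometryReport:
    records: list[DeviationRecord]
    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS
    includes_h: bool = False

    def _category(self, kind: str) -> list[DeviationRecord]:
        return [r for r in self.records if r.kind == kind]

    @property
    def rmsd_bonds(self) -> Optional[float]:
        return _rmsd([r.delta for r in self._category("bond")])

    @property
    def rmsd_angles(self) -> Optional[float]:
        return _rmsd([r.delta for r in self._category("angle")])

    @property
    def rmsd_torsions(self) -> Optional[float]:
        return _rmsd([r.delta for r in self._category("torsion")])

    def outliers(self, kind: Optional[str] = None) -> list[DeviationRecord]:
        return [r for r in self.records if r.is_outlier
                and (kind is None or r.kind == kind)]

    def to_rows(self) -> list[dict]:
        return [
            {
                "kind": r.kind,
                "atoms": "—".join(r.atoms),
                "target": r.target,
                "actual": r.actual,
                "delta": r.delta,
                "outlier": r.is_outlier,
            }
            for r in self.records
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "rmsd": {"bonds": self.rmsd_bonds, "angles": self.rmsd_angles,
                         "torsions": self.rmsd_torsions},
                "cutoffs": list(self.cutoffs),
                "includes_h": self.includes_h,
                "records": self.to_rows(),
            },
            indent=1,
        )

    def to_tsv(self) -> str:
        lines = ["kind\tatoms\ttarget\tactual\tdelta\toutlier"]
        for row in self.to_rows():
            lines.append(
                f"{row['kind']}\t{row['atoms']}\t{row['target']:.4f}\t"
                f"{row['actual']:.4f}\t{row['delta']:.4f}\t{row['outlier']}"
            )
        return "\n".join(lines) + "\n"

    def outlier_table(self) -> str:
        """Formatted outlier listing (Target / Actual / Δ per restraint)."""
        lines = [f"{'Kind':8s} {'Atoms':24s} {'Target':>9s} {'Actual':>9s} {'Δ':>8s}"]
        for r in self.outliers():
            fmt = ".3f" if r.kind == "bond" else ".1f"
            lines.append(
                f"{r.kind:8s} {'—'.join(r.atoms):24s} "
                f"{r.target:>9{fmt}} {r.actual:>9{fmt}} {r.delta:>8{fmt}}"
            )
        return "\n".join(lines) + "\n"


def geometry_report(coords: Mapping[str, np.ndarray], dictionary,
                    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS,
                    include_h: bool = False) -> GeometryReport:
    """Measure every applicable restraint of *dictionary* against *coords*.

    ``coords`` maps atom names to Cartesian positions (a Residue may be passed
    instead). Restraints involving hydrogen atoms are skipped unless
    ``include_h``; restraints whose atoms lack coordinates are skipped.
    """
    from .model import Residue

    if isinstance(coords, Residue):
        coords = {a.name: a.position for a in coords.atoms}

    hydrogens = {a.name for a in dictionary.atoms if a.element.upper() in ("H", "D")}
    records: list[DeviationRecord] = []

    def add(kind, names, target, measure, cutoff, periodicity=1, alternatives=None):
        involves_h = any(n in hydrogens for n in names)
        if involves_h and not include_h:
            return
        if any(n not in coords for n in names):
            return
        actual = measure(*(coords[n] for n in names))
        delta = signed_deviation(kind, target, actual, periodicity, alternatives)
        records.append(DeviationRecord(kind, tuple(names), target, actual,
                                       delta, abs(delta) > cutoff, involves_h))

    for b in dictionary.bonds:
        add("bond", b.atoms, b.target, bond_length, cutoffs[0])
    for a in dictionary.angles:
        add("angle", a.atoms, a.target, valence_angle, cutoffs[1])
    for t in dictionary.torsions:
        add("torsion", t.atoms, t.target, torsion_angle, cutoffs[2],
            t.periodicity, t.alternatives)

    return GeometryReport(records, cutoffs, include_h)


# -------------------------------------------------------- resolution binning

def resolution_bin_edges(low: float = 0.8, first_break: float = 1.4,
                         high: float = 3.0, width: float = 0.2) -> list[float]:
    """Default bins: one wide high-resolution bin, then uniform-width bins."""
    edges = [low, first_break]
    e = first_break
    while e < high - 1e-9:
        e = round(e + width, 10)
        edges.append(min(e, high))
    return edges


@dataclass
class BinnedSummary:
    edges: list[float]
    conditions: list[str]
    n: dict[str, list[int]]
    mean: dict[str, list[Optional[float]]]
    sem: dict[str, list[Optional[float]]]
    p_values: list[Optional[float]] = field(default_factory=list)

    def bin_label(self, i: int) -> str:
        return f"{self.edges[i]:.1f}–{self.edges[i + 1]:.1f}"

    def to_frame(self):
        import pandas as pd

        rows = []
        for i in range(len(self.edges) - 1):
            row = {"bin": self.bin_label(i)}
            for c in self.conditions:
                row[f"n_{c}"] = self.n[c][i]
                row[f"mean_{c}"] = self.mean[c][i]
                row[f"sem_{c}"] = self.sem[c][i]
            if self.p_values:
                row["p"] = self.p_values[i]
            rows.append(row)
        return pd.DataFrame(rows)


def assign_bin(resolution: float, edges: Sequence[float]) -> int:
    """Half-open assignment (low, high]; the first bin absorbs its lower edge."""
    if not edges[0] <= resolution <= edges[-1]:
        raise ValueError(f"resolution {resolution} outside ({edges[0]}, {edges[-1]}]")
    for i in range(len(edges) - 1):
        if resolution <= edges[i + 1] + 1e-12:
            return i
    return len(edges) - 2


def binned_summary(entries: Mapping[str, Iterable[tuple[float, float]]],
                   edges: Optional[Sequence[float]] = None) -> BinnedSummary:
    """Per-bin mean and s.e.m. of r.m.s.d. values, by condition.

    ``entries`` maps a condition label to (resolution, rmsd) pairs. With
    exactly two conditions a Welch two-sample t-test p-value is computed per
    bin (undefined when either side has n < 2).
    """
    edges = list(edges) if edges is not None else resolution_bin_edges()
    conditions = list(entries)
    nbins = len(edges) - 1
    binned: dict[str, list[list[float]]] = {
        c: [[] for _ in range(nbins)] for c in conditions
    }
    for c in conditions:
        for resolution, value in entries[c]:
            binned[c][assign_bin(resolution, edges)].append(value)

    n = {c: [len(v) for v in binned[c]] for c in conditions}
    mean = {c: [float(np.mean(v)) if v else None for v in binned[c]]
            for c in conditions}
    sem = {}
    for c in conditions:
        sem[c] = [
            float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) >= 2 else None
            for v in binned[c]
        ]

    p_values: list[Optional[float]] = []
    if len(conditions) == 2:
        c1, c2 = conditions
        for i in range(nbins):
            if len(binned[c1][i]) >= 2 and len(binned[c2][i]) >= 2:
                p = stats.ttest_ind(binned[c1][i], binned[c2][i],
                                    equal_var=False).pvalue
                p_values.append(float(p))
            else:
                p_values.append(None)

    return BinnedSummary(edges, conditions, n, mean, sem, p_values)
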