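"""File-level adapter for MOPAC-style semi-empirical engines.

Only the text contract is implemented here: a Cartesian input deck
(keyword line; ``element x flag y flag z flag`` rows with flag 1 = optimize,
0 = fixed) and a parser for the final geometry and heat-of-formation scalar
of the engine's log. The electronic-structure calculation itself is external.
"""

from __future__ import annotations

import re
from typing import TYPE_CHECKING

import numpy as np

from .errors import FormatError

if TYPE_CHECKING:
    from .optimize import OptimizationJob, OptimizationResult

_METHOD_KEYWORDS = {
    "external:PM7": "PM7",
    "external:PM6-D3H4": "PM6-D3H4",
    "external:other": "PM7",
}


def write_external_input(job: "OptimizationJob") -> str:
    """Emit the engine input deck for the cluster in the job.

    Atom order follows cluster serial order; immobile atoms carry
    optimization flag 0 on all three coordinates.
    """
    method = _METHOD_KEYWORDS.get(job.method, job.method.split(":", 1)[-1])
    lines = [
        f"{method} XYZ CHARGE={job.total_charge} PRECISE",
        "ligand cluster generated by qmrestraints",
        "",
    ]
    mobile = set(job.mobile_selection)
    for atom in sorted(job.cluster.atoms(), key=lambda a: a.serial):
        flag = 1 if atom.serial in mobile else 0
        x, y, z = atom.position
        lines.append(
            f"{atom.element:<2s} {x:14.8f} {flag:d} {y:14.8f} {flag:d} "
            f"{z:14.8f} {flag:d}")
    return "\n".join(lines) + "\n"


_COORD_ROW = re.compile(
    r"^\s*\d+\s+([A-Za-z]{1,2})\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s*$")
_HOF = re.compile(r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+\.\d+)")


def parse_external_output(text: str, job: "OptimizationJob") -> "OptimizationResult":
    """Extract the final Cartesian geometry and energy scalar from engine output.

    The last ``CARTESIAN COORDINATES`` block wins; coordinate order must
    match the serial order of the job's cluster atoms.
    """
    from .optimize import OptimizationResult

    blocks = []
    lines = text.splitlines()
    for i, line in enumerate(lines):
        if "CARTESIAN COORDINATES" in line.upper():
            rows = []
            for later in lines[i + 1:]:
                m = _COORD_ROW.match(later)
                if m:
                    rows.append([float(m.group(k)) for k in (2, 3, 4)])
                elif rows:
                    break
            if rows:
                blocks.append(rows)
    if not blocks:
        excerpt = "\n".join(lines[-10:])
        raise FormatError(
            "engine output lacks a final CARTESIAN COORDINATES block; "
            f"log tail:\n{excerpt}")
    coords = np.array(blocks[-1])

    serials = [a.serial for a in sorted(job.cluster.atoms(),
                                        key=lambda a: a.serial)]
    if len(coords) != len(serials):
        raise FormatError(
            f"engine returned {len(coords)} atoms, job has {len(serials)}")

    m = _HOF.search(text)
    energy = float(m.group(1)) if m else float("nan")

    positions = {s: coords[i] for i, s in enumerate(serials)}
    return OptimizationResult(positions, energy, n_steps=1,
                              converged=m is not None, trace=[energy])
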