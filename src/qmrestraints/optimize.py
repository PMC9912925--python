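"""Geometry-optimization backends for the ligand cluster.

The builtin backend is NOT a quantum-mechanical method. It minimizes the
dictionary-restraint objective — sigma-weighted harmonic bond and angle terms,
periodic cosine torsion wells and a soft nonbonded repulsion — by
deterministic limited-memory quasi-Newton descent with a monotone
(non-increasing) objective trace. It exists so the
full pipeline, including pocket-driven torsion shifts, runs at desk scale;
production restraint generation is expected to go through an external
semi-empirical engine via the file-level adapter in
:mod:`qmrestraints.mopac`.

Results are cached in a JSON sidecar keyed by a content hash of the job, so
repeated runs of the same optimization are read from file.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .cluster import LigandCluster
from .elements import covalent_radius, vdw_radius
from .errors import BackendUnavailableError, OptimizationError
from .model import ResidueKind

DEG = 180.0 / math.pi

DEFAULT_MAX_STEPS = 2000
DEFAULT_GRAD_TOL = 1e-4        # objective units / Å, max |component|
GRADIENT_EXPLOSION = 1e6

NONBONDED_FACTOR = 0.75        # reference = factor * (vdw_i + vdw_j)
NONBONDED_SIGMA = 0.2          # Å, stiffness of the soft repulsion
WATER_OH_TARGET = 0.96
WATER_OH_SIGMA = 0.02
WATER_HOH_TARGET = 104.5
WATER_HOH_SIGMA = 3.0
CAP_BOND_SIGMA = 0.02


# ------------------------------------------------------------------ job/result

@dataclass
class OptimizationJob:
    cluster: LigandCluster
    dictionaries: dict
    mobile_selection: Optional[set[int]] = None   # cluster serials
    method: str = "builtin"                       # builtin | external:PM7 | ...
    max_steps: int = DEFAULT_MAX_STEPS
    convergence_grad: float = DEFAULT_GRAD_TOL
    total_charge: int = 0
    optimize_side_chains: bool = False

    def __post_init__(self):
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        if self.mobile_selection is None:
            self.mobile_selection = default_mobile_selection(
                self.cluster, self.optimize_side_chains)
        all_serials = {a.serial for a in self.cluster.atoms()}
        if not set(self.mobile_selection) <= all_serials:
            raise ValueError("mobile_selection contains non-cluster serials")

    def content_hash(self) -> str:
        payload = {
            "method": self.method,
            "charge": self.total_charge,
            "mobile": sorted(self.mobile_selection),
            "max_steps": self.max_steps,
            "gtol": self.convergence_grad,
            "atoms": [
                [a.serial, a.element,
                 [round(float(x), 6) for x in a.position]]
                for a in self.cluster.atoms()
            ],
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class OptimizationResult:
    positions: dict[int, np.ndarray]     # cluster serial -> Cartesian Å
    final_objective: float
    n_steps: int
    converged: bool
    trace: list[float] = field(default_factory=list)
    from_cache: bool = False


def default_mobile_selection(cluster: LigandCluster,
                             side_chains: bool = False) -> set[int]:
    """Ligand + caps + water protons; optionally protein side-chain atoms.

    Symmetry-image residues stay immobile always — moving them would
    desynchronize them from their source atoms.
    """
    mobile = {a.serial for a in cluster.ligand.atoms}
    mobile |= cluster.cap_serials
    mobile |= cluster.proton_serials
    for residue in cluster.environment:
        if residue.kind is ResidueKind.water:
            mobile |= {a.serial for a in residue.atoms if a.is_hydrogen}
        if (side_chains and residue.kind is ResidueKind.amino_acid
                and residue.provenance == "model"):
            backbone = {"N", "CA", "C", "O", "OXT"}
            mobile |= {a.serial for a in residue.atoms
                       if a.name not in backbone}
    return mobile


# ------------------------------------------------------------ restraint field

class RestraintField:
    """Vectorized objective and analytic gradient over cluster coordinates."""

    def __init__(self, cluster: LigandCluster, dictionaries: dict):
        atoms = list(cluster.atoms())
        self.serials = np.array([a.serial for a in atoms])
        self.index = {s: i for i, s in enumerate(self.serials)}
        self.elements = [a.element for a in atoms]
        self.x0 = np.array([a.position for a in atoms], dtype=float)

        bonds, angles, torsions = [], [], []
        graph = nx.Graph()
        graph.add_nodes_from(self.serials)

        for residue in cluster.residues():
            d = dictionaries.get(residue.comp_id)
            if d is not None:
                by_name = {a.name: a for a in residue.atoms}
                for b in d.bonds:
                    if all(n in by_name for n in b.atoms):
                        ij = [by_name[n].serial for n in b.atoms]
                        bonds.append((ij, b.target, b.esd))
                        graph.add_edge(*ij)
                for a in d.angles:
                    if all(n in by_name for n in a.atoms):
                        angles.append(([by_name[n].serial for n in a.atoms],
                                       a.target, a.esd))
                for t in d.torsions:
                    if all(n in by_name for n in t.atoms):
                        torsions.append(([by_name[n].serial for n in t.atoms],
                                         t.target, t.esd, t.periodicity,
                                         t.alternatives or ()))
            elif residue.kind is ResidueKind.water:
                oxygen = next((a for a in residue.atoms
                               if a.element.upper() == "O"), None)
                hs = [a for a in residue.atoms if a.is_hydrogen]
                for h in hs:
                    bonds.append(([oxygen.serial, h.serial],
                                  WATER_OH_TARGET, WATER_OH_SIGMA))
                    graph.add_edge(oxygen.serial, h.serial)
                if len(hs) == 2:
                    angles.append(([hs[0].serial, oxygen.serial, hs[1].serial],
                                   WATER_HOH_TARGET, WATER_HOH_SIGMA))
            else:
                # un-dictionaried residue: rigid in practice (immobile), but
                # keep its atoms bonded for nonbonded exclusions
                self._distance_edges(residue, graph)

        for cap in cluster.added_caps:
            inside = cluster.atom_by_serial(cap.inside_serial)
            target = float(np.linalg.norm(cap.atom.position - inside.position))
            bonds.append(([cap.inside_serial, cap.atom.serial],
                          target, CAP_BOND_SIGMA))
            graph.add_edge(cap.inside_serial, cap.atom.serial)
        for proton in cluster.added_protons:
            graph.add_edge(proton.parent_serial, proton.atom.serial)

        self.bond_idx = np.array([[self.index[s] for s in b[0]]
                                  for b in bonds], int).reshape(-1, 2)
        self.bond_target = np.array([b[1] for b in bonds])
        self.bond_w = np.array([1.0 / b[2] ** 2 for b in bonds])

        self.angle_idx = np.array([[self.index[s] for s in a[0]]
                                   for a in angles], int).reshape(-1, 3)
        self.angle_target = np.array([a[1] for a in angles])
        self.angle_w = np.array([1.0 / a[2] ** 2 for a in angles])

        self.tor_idx = np.array([[self.index[s] for s in t[0]]
                                 for t in torsions], int).reshape(-1, 4)
        self.tor_target = np.array([t[1] for t in torsions])
        self.tor_sigma = np.array([t[2] for t in torsions])
        self.tor_n = np.array([max(1, t[3]) for t in torsions], int)
        self.tor_alts = [tuple(t[4]) for t in torsions]

        self._build_nonbonded(graph)

    def _distance_edges(self, residue, graph) -> None:
        atoms = residue.atoms
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                cutoff = 1.3 * (covalent_radius(atoms[i].element) +
                                covalent_radius(atoms[j].element))
                if np.linalg.norm(atoms[i].position - atoms[j].position) < cutoff:
                    graph.add_edge(atoms[i].serial, atoms[j].serial)

    def _build_nonbonded(self, graph: nx.Graph) -> None:
        """Pairs separated by more than three bonds (1-5 and further, plus
        all inter-residue pairs), with reference distances from vdW radii."""
        n = len(self.serials)
        excluded: set[tuple[int, int]] = set()
        lengths = dict(nx.all_pairs_shortest_path_length(graph, cutoff=3))
        for s1, dists in lengths.items():
            for s2 in dists:
                if s1 < s2:
                    excluded.add((self.index[s1], self.index[s2]))
        pairs, r0 = [], []
        radii = [vdw_radius(e) for e in self.elements]
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excluded:
                    continue
                pairs.append((i, j))
                r0.append(NONBONDED_FACTOR * (radii[i] + radii[j]))
        self.nb_idx = np.array(pairs, int).reshape(-1, 2)
        self.nb_r0 = np.array(r0)
        self.nb_w = 1.0 / NONBONDED_SIGMA ** 2

    # ------------------------------------------------------------- evaluation
    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        e = 0.0
        g = np.zeros_like(x)

        if len(self.bond_idx):
            vec = x[self.bond_idx[:, 1]] - x[self.bond_idx[:, 0]]
            d = np.linalg.norm(vec, axis=1)
            delta = self.bond_target - d
            e += float(np.sum(self.bond_w * delta ** 2))
            coeff = (-2.0 * self.bond_w * delta / np.maximum(d, 1e-9))[:, None]
            np.add.at(g, self.bond_idx[:, 1], coeff * vec)
            np.add.at(g, self.bond_idx[:, 0], -coeff * vec)

        if len(self.angle_idx):
            p1 = x[self.angle_idx[:, 0]]
            p2 = x[self.angle_idx[:, 1]]
            p3 = x[self.angle_idx[:, 2]]
            u, v = p1 - p2, p3 - p2
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh, vh = u / nu[:, None], v / nv[:, None]
            cos = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
            theta = np.degrees(np.arccos(cos))
            sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-12))
            delta = self.angle_target - theta
            e += float(np.sum(self.angle_w * delta ** 2))
            dE_dtheta_rad = -2.0 * self.angle_w * delta * DEG
            g1 = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
            g3 = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
            np.add.at(g, self.angle_idx[:, 0], dE_dtheta_rad[:, None] * g1)
            np.add.at(g, self.angle_idx[:, 2], dE_dtheta_rad[:, None] * g3)
            np.add.at(g, self.angle_idx[:, 1],
                      dE_dtheta_rad[:, None] * (-g1 - g3))

        if len(self.tor_idx):
            e += self._torsion_terms(x, g)

        if len(self.nb_idx):
            vec = x[self.nb_idx[:, 1]] - x[self.nb_idx[:, 0]]
            d = np.linalg.norm(vec, axis=1)
            overlap = self.nb_r0 - d
            active = overlap > 0.0
            if np.any(active):
                ov = overlap[active]
                e += float(np.sum(self.nb_w * ov ** 2))
                coeff = (2.0 * self.nb_w * ov /
                         np.maximum(d[active], 1e-9))[:, None]
                np.add.at(g, self.nb_idx[active, 1], -coeff * vec[active])
                np.add.at(g, self.nb_idx[active, 0], coeff * vec[active])
        return e, g

    def _torsion_terms(self, x: np.ndarray, g: np.ndarray) -> float:
        idx = self.tor_idx
        p1, p2, p3, p4 = (x[idx[:, k]] for k in range(4))
        b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        xc = np.sum(n1 * n2, axis=1)
        yc = np.sum(np.cross(n1, n2) * b2, axis=1) / np.maximum(nb2, 1e-9)
        theta = np.degrees(np.arctan2(yc, xc))

        # center of the nearest well: base target for the periodic family
        # (the cosine handles the periodicity), or the closest alternative
        center = self.tor_target.copy()
        n_eff = self.tor_n.astype(float).copy()
        for i, alts in enumerate(self.tor_alts):
            if not alts:
                continue
            per_delta = _wrap(theta[i] - self.tor_target[i])
            half = 180.0 / self.tor_n[i]
            per_delta = _wrap((per_delta + half) % (2 * half) - half)
            best = abs(per_delta)
            for alt in alts:
                d = abs(_wrap(theta[i] - alt))
                if d < best - 1e-12:
                    best, center[i], n_eff[i] = d, alt, 1.0

        amp = 2.0 * DEG ** 2 / (n_eff ** 2 * self.tor_sigma ** 2)
        phase = np.radians(n_eff * (theta - center))
        e = float(np.sum(amp * (1.0 - np.cos(phase))))
        dE_dtheta_rad = amp * n_eff * np.sin(phase)

        sq1 = np.maximum(np.sum(n1 * n1, axis=1), 1e-12)
        sq2 = np.maximum(np.sum(n2 * n2, axis=1), 1e-12)
        g1 = (-nb2 / sq1)[:, None] * n1
        g4 = (nb2 / sq2)[:, None] * n2
        f12 = np.sum(b1 * b2, axis=1) / np.maximum(nb2 ** 2, 1e-12)
        f32 = np.sum(b3 * b2, axis=1) / np.maximum(nb2 ** 2, 1e-12)
        g2 = -(1.0 + f12)[:, None] * g1 + f32[:, None] * g4
        g3 = f12[:, None] * g1 - (1.0 + f32)[:, None] * g4
        for k, gk in enumerate((g1, g2, g3, g4)):
            np.add.at(g, idx[:, k], dE_dtheta_rad[:, None] * gk)
        return e


def _wrap(a):
    w = ((a + 180.0) % 360.0) - 180.0
    return w if not isinstance(w, float) or w != -180.0 else 180.0


# ---------------------------------------------------------------- minimizer

def builtin_minimize(cluster: LigandCluster, mobile_selection: Iterable[int],
                     dictionaries: dict,
                     max_steps: int = DEFAULT_MAX_STEPS,
                     convergence_grad: float = DEFAULT_GRAD_TOL) -> OptimizationResult:
    """Deterministic restrained minimization of the mobile cluster atoms.

    Quasi-Newton descent (limited-memory BFGS with a sufficient-decrease line
    search, via scipy); every accepted iterate lowers the objective, so the
    recorded trace is non-increasing. The restraint objective mixes very
    stiff bond terms with very soft torsion wells, which makes curvature
    information essential — plain gradient descent crawls on it. Immobile
    atoms are exactly fixed. No randomness anywhere.
    """
    from scipy.optimize import minimize as _minimize

    field_ = RestraintField(cluster, dictionaries)
    x0 = field_.x0.copy()
    mobile_mask = np.array([s in set(mobile_selection) for s in field_.serials])

    e0, g0 = field_.energy_gradient(x0)
    trace = [float(e0)]

    if not mobile_mask.any():
        positions = {int(s): x0[i].copy() for i, s in enumerate(field_.serials)}
        return OptimizationResult(positions, float(e0), 0, True, trace)

    def objective(z):
        x = x0.copy()
        x[mobile_mask] = z.reshape(-1, 3)
        e, g = field_.energy_gradient(x)
        gm = g[mobile_mask]
        gmax = float(np.abs(gm).max()) if gm.size else 0.0
        if gmax > GRADIENT_EXPLOSION:
            raise OptimizationError(
                f"exploding gradient ({gmax:.3g}); objective {e:.3g}")
        return e, gm.ravel()

    def record(zk):
        x = x0.copy()
        x[mobile_mask] = zk.reshape(-1, 3)
        e, _ = field_.energy_gradient(x)
        trace.append(float(e))

    result = _minimize(objective, x0[mobile_mask].ravel(), jac=True,
                       method="L-BFGS-B", callback=record,
                       options={"maxiter": max_steps, "ftol": 1e-14,
                                "gtol": convergence_grad, "maxcor": 20})

    x = x0.copy()
    x[mobile_mask] = result.x.reshape(-1, 3)
    e, g = field_.energy_gradient(x)
    gmax = float(np.abs(g[mobile_mask]).max())
    converged = bool(gmax < convergence_grad or result.success)

    positions = {int(s): x[i].copy() for i, s in enumerate(field_.serials)}
    return OptimizationResult(positions, float(e), int(result.nit),
                              converged, trace)


# ------------------------------------------------------------------ dispatch

def optimize(job: OptimizationJob,
             cache_dir: Optional[str] = None,
             engine_runner=None) -> OptimizationResult:
    """Run (or reload) the optimization named by the job.

    Results are cached in ``cache_dir`` keyed by a content hash of the job;
    a second call with an identical job reads the sidecar and performs no
    optimization. External methods require ``engine_runner``, a callable
    mapping the engine input deck to the engine output text.
    """
    cache_path = None
    if cache_dir is not None:
        os.makedirs(cache_dir, exist_ok=True)
        cache_path = os.path.join(cache_dir, f"qmr_{job.content_hash()}.json")
        if os.path.exists(cache_path):
            return _load_sidecar(cache_path)

    if job.method == "builtin":
        result = builtin_minimize(job.cluster, job.mobile_selection,
                                  job.dictionaries, job.max_steps,
                                  job.convergence_grad)
    elif job.method.startswith("external:"):
        from .mopac import parse_external_output, write_external_input
        if engine_runner is None:
            raise BackendUnavailableError(
                f"no engine runner configured for adapter {job.method!r}; "
                f"supply engine_runner=callable(deck_text) -> output_text")
        deck = write_external_input(job)
        output = engine_runner(deck)
        result = parse_external_output(output, job)
    else:
        raise ValueError(f"unknown optimization method {job.method!r}")

    if cache_path is not None:
        _write_sidecar(cache_path, job, result)
    return result


def apply_result(cluster: LigandCluster, result: OptimizationResult) -> None:
    """Copy optimized positions back onto the cluster atoms."""
    for atom in cluster.atoms():
        atom.position = np.asarray(result.positions[atom.serial], float)


def _write_sidecar(path: str, job: OptimizationJob,
                   result: OptimizationResult) -> None:
    payload = {
        "hash": job.content_hash(),
        "method": job.method,
        "final_objective": result.final_objective,
        "n_steps": result.n_steps,
        "converged": result.converged,
        "trace": result.trace,
        "positions": {str(s): [float(v) for v in p]
                      for s, p in result.positions.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _load_sidecar(path: str) -> OptimizationResult:
    with open(path) as fh:
        payload = json.load(fh)
    positions = {int(s): np.array(p) for s, p in payload["positions"].items()}
    return OptimizationResult(positions, payload["final_objective"],
                              payload["n_steps"], payload["converged"],
                              payload["trace"], from_cache=True)
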