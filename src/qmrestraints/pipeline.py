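"""End-to-end restraint generation: select → validate → cap → protonate →
optimize → generate targets → report."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

from .cluster import (EnvironmentReport, LigandCluster, build_ligand_cluster,
                      cap_dangling_bonds, cluster_to_pdb, protonate_waters)
from .errors import QmrError
from .geometry import DEFAULT_CUTOFFS, GeometryReport, geometry_report
from .model import StructureModel
from .model_io import infer_connectivity
from .optimize import (OptimizationJob, OptimizationResult, apply_result,
                       optimize)
from .restraints import (RestraintDictionary, generate_qmr_restraints,
                         write_dictionary)

log = logging.getLogger("qmrestraints.pipeline")


@dataclass
class PipelineResult:
    qmr_dictionary: RestraintDictionary
    report_base_before: GeometryReport   # input coords vs base restraints
    report_base_after: GeometryReport    # optimized coords vs base restraints
    report_qmr_after: GeometryReport     # optimized coords vs generated set
    environment: EnvironmentReport
    cluster: LigandCluster
    optimization: OptimizationResult
    timings: dict[str, float] = field(default_factory=dict)


def run_pipeline(model: StructureModel, ligand_selector,
                 base_dictionary: RestraintDictionary,
                 dictionaries: Optional[dict] = None,
                 radius: float = 3.5,
                 mode: str = "neutral",
                 backend: str = "builtin",
                 cache_dir: Optional[str] = None,
                 outdir: Optional[str] = None,
                 include_h: bool = False,
                 cutoffs=DEFAULT_CUTOFFS,
                 max_steps: int = 2000,
                 optimize_side_chains: bool = False,
                 engine_runner=None) -> PipelineResult:
    """Run the full restraint-generation workflow for one ligand instance.

    Any stage failure is re-raised annotated with the stage name; when an
    output directory is given, intermediates (cluster PDB, generated
    restraint CIF, before/after reports, optimization sidecar) are persisted
    there for post-mortem inspection.
    """
    dictionaries = dict(dictionaries or {})
    dictionaries.setdefault(base_dictionary.comp_id, base_dictionary)
    timings: dict[str, float] = {}
    stage = "setup"

    def tick(name):
        nonlocal stage
        timings[stage] = time.perf_counter() - tick.t0
        log.info("stage %-12s %.3f s", stage, timings[stage])
        stage = name
        tick.t0 = time.perf_counter()
    tick.t0 = time.perf_counter()

    try:
        stage = "connectivity"
        connectivity = infer_connectivity(model, dictionaries)

        tick("validate")
        from .cluster import validate_environment
        environment = validate_environment(model, ligand_selector,
                                           connectivity, dictionaries)

        tick("cluster")
        cluster = build_ligand_cluster(model, ligand_selector, radius,
                                       connectivity, dictionaries)
        report_before = geometry_report(cluster.ligand, base_dictionary,
                                        cutoffs, include_h)

        tick("cap")
        cap_dangling_bonds(cluster, mode)

        tick("protonate")
        protonate_waters(cluster)

        tick("optimize")
        job = OptimizationJob(cluster, dictionaries, method=backend,
                              total_charge=base_dictionary.formal_charge,
                              max_steps=max_steps,
                              optimize_side_chains=optimize_side_chains)
        result = optimize(job, cache_dir=cache_dir,
                          engine_runner=engine_runner)
        apply_result(cluster, result)

        tick("generate")
        qmr = generate_qmr_restraints(cluster.ligand, base_dictionary)

        tick("report")
        report_base_after = geometry_report(cluster.ligand, base_dictionary,
                                            cutoffs, include_h)
        report_qmr_after = geometry_report(cluster.ligand, qmr,
                                           cutoffs, include_h)
        tick("done")
    except QmrError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    out = PipelineResult(qmr, report_before, report_base_after,
                         report_qmr_after, environment, cluster, result,
                         timings)
    if outdir is not None:
        _persist(outdir, out)
    return out


def _persist(outdir: str, result: PipelineResult) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "cluster.pdb"), "w") as fh:
        fh.write(cluster_to_pdb(result.cluster))
    with open(os.path.join(outdir, "qmr_restraints.cif"), "w") as fh:
        fh.write(write_dictionary(result.qmr_dictionary))
    for name, report in (("report_base_before", result.report_base_before),
                         ("report_base_after", result.report_base_after),
                         ("report_qmr_after", result.report_qmr_after)):
        with open(os.path.join(outdir, name + ".tsv"), "w") as fh:
            fh.write(report.to_tsv())
        with open(os.path.join(outdir, name + ".json"), "w") as fh:
            fh.write(report.to_json())
    with open(os.path.join(outdir, "environment.txt"), "w") as fh:
        fh.write(result.environment.summary())
    with open(os.path.join(outdir, "timings.json"), "w") as fh:
        json.dump(result.timings, fh, indent=1)
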