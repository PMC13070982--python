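"""End-to-end assignment pipeline: three replicas, confidence, safeguards, reports."""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import yaml

from .config import RunConfig
from .noe import NOEGraph, read_noe_peaklist
from .reports import (
    read_preassignments,
    read_theoretical_restraints,
    write_assignment_table,
    write_correlation_csv,
    write_walk_trace,
)
from .scoring import RestraintSets
from .structure import (
    MethylSet,
    assemble_structure_graph,
    parse_structure,
    write_structure_graph,
)
from .walker import (
    apply_restraint_safeguard,
    classify_confidence,
    run_cpmw,
)


def nonstereo_types_of(scheme) -> frozenset[str]:
    return frozenset(t for t in ("L", "V") if scheme.is_nonstereo(t))


def build_restraint_sets(noe: NOEGraph, theo: dict[str, dict[int, float]] | None) -> RestraintSets | None:
    """Pair experimental (peak-list) and theoretical (table) restraints."""
    exp = {r: dict(noe.restraints(r)) for r in noe.resonances if noe.restraints(r)}
    if not exp and not theo:
        return None
    if bool(exp) != bool(theo):
        warnings.warn(
            "restraints present on only one side (experimental peak-list "
            "columns vs theoretical table); ignoring them",
            stacklevel=2,
        )
        return None
    return RestraintSets(exp=exp, theo=theo or {})


def run_assignment(cfg: RunConfig, check_paths: bool = True) -> dict:
    """Run the full three-replica assignment and write all artifacts.

    Returns a dict with the confidence report, the three CPMWs and the
    paths of the written files.
    """
    cfg.validate(check_paths=check_paths)
    scheme = cfg.scheme
    methyls = parse_structure(
        cfg.structure_files, scheme, collapse_symmetry=cfg.collapse_symmetry
    )
    mset = MethylSet(methyls, mode=cfg.ensemble_mode)
    if cfg.peak_list is None:
        raise ValueError("assignment requires a peak list")
    noe = read_noe_peaklist(cfg.peak_list)
    theo = (
        read_theoretical_restraints(cfg.theoretical_restraints)
        if cfg.theoretical_restraints
        else None
    )
    rsets = build_restraint_sets(noe, theo)
    pre = read_preassignments(cfg.preassignments) if cfg.preassignments else None

    dump: list | None = [] if cfg.score_dump else None
    cpmws = [
        run_cpmw(
            noe,
            mset,
            cfg.walker_config(r),
            restraints=rsets,
            preassignments=pre,
            replica=r,
            dump=dump if r == 1 else None,  # dump the middle replica
        )
        for r in range(3)
    ]
    report = classify_confidence(cpmws, mset, nonstereo_types_of(scheme))
    safeguard = None
    if cfg.safeguard_enabled and rsets is not None:
        safeguard = apply_restraint_safeguard(report, rsets, cfg.safeguard_k_sigma)

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "assignments": out / "assignments.tsv",
        "walk_trace": out / "walk_trace.tsv",
        "noe_graph": out / "noe_graph.graphml",
        "structure_graph": out / "structure_graph.graphml",
        "structure_edges": out / "structure_graph_edges.tsv",
        "run_log": out / "run_log.yaml",
    }
    write_assignment_table(paths["assignments"], report, cpmws, fixed=set(pre or ()))
    write_walk_trace(paths["walk_trace"], cpmws)
    noe.to_graphml(paths["noe_graph"])
    # matched structure graph of the middle replica; methyls never assigned
    # keep the minimal cut-off (no evidence for a larger star)
    mid = cpmws[1]
    selected = {
        m: mid.selected_cutoffs.get(m, mid.grid.min) for m in mset.ids
    }
    sg = assemble_structure_graph(selected, mset)
    write_structure_graph(sg, graphml=paths["structure_graph"], tsv=paths["structure_edges"])
    if noe.resonances and len(noe.resonances) <= 150:
        paths["noe_dot"] = out / "noe_graph.dot"
        noe.to_dot(paths["noe_dot"])
    if safeguard is not None:
        paths["correlation"] = out / "restraint_correlation.csv"
        write_correlation_csv(paths["correlation"], safeguard)
    if dump is not None:
        paths["score_dump"] = out / "score_dump.tsv"
        pd.DataFrame(
            dump,
            columns=["resonance", "methyl", "cutoff", "score", "common_edges", "seminal"],
        ).to_csv(paths["score_dump"], sep="\t", index=False)
    log = {
        "parameters": cfg.effective_parameters(),
        "n_methyls": len(mset),
        "n_resonances": len(noe.resonances),
        "noe_metrics": noe.metrics() if noe.resonances else {},
        "replica_cluster_sizes": [c.cluster_sizes for c in cpmws],
        "safeguard_summary": safeguard.summary if safeguard else [],
    }
    with open(paths["run_log"], "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return {
        "report": report,
        "cpmws": cpmws,
        "safeguard": safeguard,
        "paths": paths,
        "methyls": mset,
        "noe": noe,
    }
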