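"""Report writers and readers: assignment tables, walk traces, correlations.

All tables are TSV with documented headers so the package's own readers can
re-parse them (round-trip); graphs are exported as GraphML.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pandas as pd

from .walker import CPMW, ConfidenceReport, SafeguardResult

ASSIGNMENT_COLUMNS = [
    "resonance",
    "methyl",
    "status",
    "score",
    "cutoff_A",
    "cluster",
    "replica_1",
    "replica_2",
    "replica_3",
    "flags",
]

TRACE_COLUMNS = [
    "replica",
    "cluster",
    "step_index",
    "seminal",
    "resonance",
    "methyl",
    "cutoff_A",
    "common_edges",
    "score",
]


def write_assignment_table(
    path: str | Path,
    report: ConfidenceReport,
    cpmws: Sequence[CPMW],
    fixed: set[str] | None = None,
) -> None:
    """Final per-resonance assignment table with replica answers."""
    mid = cpmws[1] if len(cpmws) > 1 else cpmws[0]
    step_info = {
        s.resonance: (s.score, s.cutoff, ci)
        for c_i, cluster in enumerate(mid.clusters, start=1)
        for s, ci in ((st, c_i) for st in cluster.walk.steps)
    }
    rows = []
    for res in sorted(report.verdicts):
        v = report.verdicts[res]
        score, cutoff, cluster = step_info.get(res, (float("nan"), float("nan"), 0))
        flags = list(v.flags)
        if fixed and res in fixed:
            flags.append("fixed")
        rows.append(
            {
                "resonance": res,
                "methyl": v.methyl or "",
                "status": v.status,
                "score": f"{score:.4f}" if score == score else "",
                "cutoff_A": f"{cutoff:.1f}" if cutoff == cutoff else "",
                "cluster": cluster or "",
                "replica_1": v.answers[0] or "",
                "replica_2": v.answers[1] if len(v.answers) > 1 else "",
                "replica_3": v.answers[2] if len(v.answers) > 2 else "",
                "flags": ";".join(flags),
            }
        )
    pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_assignment_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_walk_trace(path: str | Path, cpmws: Sequence[CPMW]) -> None:
    """Ordered, human-readable record of every step of every walk."""
    rows = []
    for cpmw in cpmws:
        for c_i, cluster in enumerate(cpmw.clusters, start=1):
            for step in cluster.walk.steps:
                rows.append(
                    {
                        "replica": cpmw.replica + 1,
                        "cluster": c_i,
                        "step_index": step.step_index,
                        "seminal": int(step.seminal),
                        "resonance": step.resonance,
                        "methyl": step.methyl,
                        "cutoff_A": f"{step.cutoff:.1f}",
                        "common_edges": step.common,
                        "score": f"{step.score:.4f}",
                    }
                )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_walk_trace(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def format_trace(df: pd.DataFrame, resonance: str) -> str:
    """Human-readable walk trace of the cluster(s) containing ``resonance``."""
    hits = df[df["resonance"] == resonance]
    if hits.empty:
        valid = sorted(df["resonance"].unique())
        raise KeyError(
            f"resonance {resonance!r} appears in no walk; known resonances: "
            f"{', '.join(valid[:10])}{' ...' if len(valid) > 10 else ''}"
        )
    lines = []
    for _, hit in hits.iterrows():
        sel = df[(df["replica"] == hit["replica"]) & (df["cluster"] == hit["cluster"])]
        lines.append(f"replica {hit['replica']}, cluster {hit['cluster']}:")
        for _, row in sel.iterrows():
            tag = "seminal" if row["seminal"] == "1" else f"step {row['step_index']}"
            mark = "  <-- queried" if row["resonance"] == resonance else ""
            lines.append(
                f"  [{tag}] {row['resonance']} -> {row['methyl']} "
                f"(cutoff {row['cutoff_A']} A, c={row['common_edges']}, "
                f"score {row['score']}){mark}"
            )
    return "\n".join(lines)


def write_correlation_csv(path: str | Path, safeguard: SafeguardResult) -> None:
    """Experimental-vs-theoretical restraint table per set (diagnostic)."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["set", "resonance", "methyl", "a_exp", "a_theo", "residual", "flagged"],
        )
        writer.writeheader()
        for row in safeguard.correlation:
            writer.writerow(row)


def write_evaluation_tsv(path: str | Path, result) -> None:
    pct = result.percentages()
    with open(path, "w") as fh:
        fh.write("category\tcount\tpercent\n")
        for cat in ("correct", "erroneous", "ambiguous", "unassigned"):
            fh.write(f"{cat}\t{getattr(result, cat)}\t{pct[cat]:.2f}\n")
        fh.write(f"total\t{result.denominator}\t100.00\n")


def read_preassignments(path: str | Path) -> dict[str, str]:
    """Two-column TSV: resonance id, methyl id (header optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed pre-assignment line: {line!r}")
            if parts[0].lower() in ("resonance", "res_id", "peak"):
                continue
            if parts[0] in out:
                raise ValueError(f"duplicate pre-assignment for {parts[0]!r}")
            out[parts[0]] = parts[1]
    return out


def read_theoretical_restraints(path: str | Path) -> dict[str, dict[int, float]]:
    """Per-methyl theoretical restraint table.

    TSV with a ``methyl`` column plus ``restraint_1`` .. ``restraint_4``
    (``pcs_i`` / ``pre_i`` accepted); blank cells mean unavailable.
    """
    import re

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    if "methyl" not in cols:
        raise ValueError(f"{path}: theoretical restraint table needs a 'methyl' column")
    rre = re.compile(r"^(?:restraint|pcs|pre)[_ ]?([1-4])$")
    rcols = {int(m.group(1)): cols[c] for c in cols if (m := rre.match(c))}
    out: dict[str, dict[int, float]] = {}
    for _, row in df.iterrows():
        vals = {
            i: float(str(row[col]).strip())
            for i, col in rcols.items()
            if str(row[col]).strip()
        }
        if vals:
            out[str(row[cols["methyl"]]).strip()] = vals
    return out
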