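"""Directed NOE graphs from methyl-TROSY / NOESY peak lists.

Nodes are methyl resonances (auto-peaks) carrying an amino-acid-type
classification (possibly a candidate set) and optional long-range restraint
values (e.g. PCS, up to four sets).  A directed edge ``u -> v`` records a
NOESY cross-peak observed in the plane of auto-peak ``u``; reciprocal
cross-peaks give edge pairs and carry more weight downstream.

The canonical peak-list format is a TSV/CSV with columns::

    auto_peak_id  auto_aa_type  cross_peak_id  cross_aa_type  [restraint_1..4]

``auto_aa_type`` may list several candidate letters (``"LV"``).  Restraint
columns attach to the auto-peak; blank means unavailable.  A row with an
empty ``cross_peak_id`` declares a resonance without asserting a contact.
Header names are matched tolerantly so CCPN-style exports load too.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

RECIPROCAL = "reciprocal"
OUT_ONLY = "out"
IN_ONLY = "in"


@dataclass(frozen=True)
class NGBBNeighbour:
    """One neighbour of an NGBB's active node."""

    res_id: str
    types: frozenset[str]
    cls: str  # RECIPROCAL / OUT_ONLY / IN_ONLY


@dataclass(frozen=True)
class NGBB:
    """NOE graph building block: the star around one auto-peak.

    ``k`` counts only out-neighbours (the cross-peaks of the active node's
    NOESY plane); in-only neighbours are retained for common-edge counting.
    """

    active: str
    active_types: frozenset[str]
    neighbours: tuple[NGBBNeighbour, ...]

    @property
    def out_neighbours(self) -> tuple[NGBBNeighbour, ...]:
        return tuple(n for n in self.neighbours if n.cls != IN_ONLY)

    @property
    def k(self) -> int:
        return len(self.out_neighbours)

    @property
    def n_edges(self) -> int:
        """Neighbour count used as E_NOE in the similarity score."""
        return len(self.neighbours)


class NOEGraph:
    """Directed, attributed NOE graph over methyl resonances."""

    def __init__(self) -> None:
        self.g = nx.DiGraph()

    # -- construction -----------------------------------------------------
    def add_resonance(
        self,
        res_id: str,
        types: Iterable[str] | str,
        restraints: dict[int, float] | None = None,
    ) -> None:
        tset = frozenset(types)
        if not tset:
            raise ValueError(f"resonance {res_id!r} has no amino-acid type")
        if res_id in self.g:
            old = self.g.nodes[res_id]["types"]
            if old != tset:
                raise ValueError(
                    f"conflicting amino-acid type for peak {res_id!r}: "
                    f"{''.join(sorted(old))} vs {''.join(sorted(tset))}"
                )
            if restraints:
                merged = dict(self.g.nodes[res_id]["restraints"])
                for i, v in restraints.items():
                    if i in merged and abs(merged[i] - v) > 1e-9:
                        raise ValueError(
                            f"conflicting restraint {i} for peak {res_id!r}"
                        )
                    merged[i] = v
                self.g.nodes[res_id]["restraints"] = merged
        else:
            self.g.add_node(res_id, types=tset, restraints=dict(restraints or {}))

    def add_contact(self, auto: str, cross: str) -> None:
        if auto not in self.g or cross not in self.g:
            raise KeyError("add resonances before contacts")
        if auto == cross:
            raise ValueError(f"self-NOE on peak {auto!r}")
        self.g.add_edge(auto, cross)

    # -- accessors --------------------------------------------------------
    @property
    def resonances(self) -> list[str]:
        return sorted(self.g.nodes)

    def types(self, res_id: str) -> frozenset[str]:
        return self.g.nodes[res_id]["types"]

    def restraints(self, res_id: str) -> dict[int, float]:
        return self.g.nodes[res_id]["restraints"]

    def reciprocal(self, u: str, v: str) -> bool:
        return self.g.has_edge(u, v) and self.g.has_edge(v, u)

    def neighbour_class(self, active: str, other: str) -> str:
        out = self.g.has_edge(active, other)
        inn = self.g.has_edge(other, active)
        if out and inn:
            return RECIPROCAL
        return OUT_ONLY if out else IN_ONLY

    def undirected_contacts(self) -> set[tuple[str, str]]:
        """Unordered contact pairs (a reciprocal edge pair counts once)."""
        return {tuple(sorted((u, v))) for u, v in self.g.edges}

    def extract_ngbb(self, res_id: str) -> NGBB:
        if res_id not in self.g:
            raise KeyError(f"unknown resonance {res_id!r}")
        nbr_ids = sorted(set(self.g.successors(res_id)) | set(self.g.predecessors(res_id)))
        nbrs = tuple(
            NGBBNeighbour(n, self.types(n), self.neighbour_class(res_id, n))
            for n in nbr_ids
        )
        return NGBB(active=res_id, active_types=self.types(res_id), neighbours=nbrs)

    def metrics(self) -> dict[str, float]:
        """NOE density (contacts per resonance) and degree connectivity."""
        n = self.g.number_of_nodes()
        if n == 0:
            raise ValueError("empty NOE graph")
        contacts = len(self.undirected_contacts())
        return {"density": contacts / n, "degree_connectivity": 2.0 * contacts / n}

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path: str | Path | None = None) -> str | None:
        rows = []
        listed_as_auto = set()
        for u in sorted(self.g.nodes):
            succ = sorted(self.g.successors(u))
            if succ:
                listed_as_auto.add(u)
            for v in succ:
                rows.append(self._row(u, v))
        for u in sorted(self.g.nodes):
            if u not in listed_as_auto:
                rows.append(self._row(u, None))
        cols = ["auto_peak_id", "auto_aa_type", "cross_peak_id", "cross_aa_type"]
        ridx = sorted({i for u in self.g.nodes for i in self.restraints(u)})
        cols += [f"restraint_{i}" for i in ridx]
        df = pd.DataFrame(rows, columns=cols)
        if path is None:
            buf = io.StringIO()
            df.to_csv(buf, sep="\t", index=False)
            return buf.getvalue()
        df.to_csv(path, sep="\t", index=False)
        return None

    def _row(self, u: str, v: str | None) -> dict:
        row = {
            "auto_peak_id": u,
            "auto_aa_type": "".join(sorted(self.types(u))),
            "cross_peak_id": v or "",
            "cross_aa_type": "".join(sorted(self.types(v))) if v else "",
        }
        for i, val in self.restraints(u).items():
            row[f"restraint_{i}"] = val
        return row

    def to_graphml(self, path: str | Path) -> None:
        g = nx.DiGraph()
        for u in self.g.nodes:
            g.add_node(u, aa_type="".join(sorted(self.types(u))))
        for u, v in self.g.edges:
            g.add_edge(u, v, reciprocal=self.reciprocal(u, v))
        nx.write_graphml(g, str(path))

    def to_dot(self, path: str | Path) -> None:
        """Plain Graphviz DOT export for visual inspection of small graphs."""
        lines = ["digraph noe {", "  node [shape=circle];"]
        for u in sorted(self.g.nodes):
            lines.append(f'  "{u}" [label="{u}\\n{"".join(sorted(self.types(u)))}"];')
        for u, v in sorted(self.g.edges):
            style = "" if self.reciprocal(u, v) else " [style=dashed]"
            lines.append(f'  "{u}" -> "{v}"{style};')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def copy(self) -> "NOEGraph":
        new = NOEGraph()
        new.g = self.g.copy()
        return new


# ---------------------------------------------------------------------------
# peak-list reading
# ---------------------------------------------------------------------------

_HEADER_SYNONYMS = {
    "auto_peak_id": {"auto_peak_id", "auto_peak", "auto_id", "auto", "peak_id", "assign_f1"},
    "auto_aa_type": {"auto_aa_type", "auto_type", "auto_aa", "aa_type", "residue_type"},
    "cross_peak_id": {"cross_peak_id", "cross_peak", "cross_id", "cross", "assign_f2"},
    "cross_aa_type": {"cross_aa_type", "cross_type", "cross_aa"},
}
_RESTRAINT_RE = re.compile(r"^(?:restraint|pcs|pre)[_ ]?([1-4])$")


def _normalise(col: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", col.strip().lower()).strip("_")


def read_noe_peaklist(path: str | Path) -> NOEGraph:
    """Read a peak-list TSV/CSV into an :class:`NOEGraph`.

    Duplicate rows collapse to a single edge; a cross-peak id that never
    appears as an auto-peak is kept as a node with a warning (its NOESY
    plane may simply be missing from the list).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    colmap: dict[str, str] = {}
    for col in df.columns:
        norm = _normalise(str(col))
        for canon, names in _HEADER_SYNONYMS.items():
            if norm in names:
                colmap[canon] = col
        m = _RESTRAINT_RE.match(norm)
        if m:
            colmap[f"restraint_{m.group(1)}"] = col
    missing = {"auto_peak_id", "auto_aa_type", "cross_peak_id", "cross_aa_type"} - set(colmap)
    if missing:
        raise ValueError(f"peak list {path} lacks columns: {sorted(missing)}")
    ridx = sorted(int(k.split("_")[1]) for k in colmap if k.startswith("restraint_"))

    graph = NOEGraph()
    for _, row in df.iterrows():
        auto = str(row[colmap["auto_peak_id"]]).strip()
        if not auto:
            continue
        restraints = {}
        for i in ridx:
            raw = str(row[colmap[f"restraint_{i}"]]).strip()
            if raw:
                restraints[i] = float(raw)
        graph.add_resonance(auto, str(row[colmap["auto_aa_type"]]).strip(), restraints)
        cross = str(row[colmap["cross_peak_id"]]).strip()
        if cross:
            graph.add_resonance(cross, str(row[colmap["cross_aa_type"]]).strip())
            graph.add_contact(auto, cross)
    dangling = [u for u in graph.g.nodes if graph.g.out_degree(u) == 0 and graph.g.in_degree(u) > 0]
    if dangling:
        warnings.warn(
            f"{len(dangling)} cross-peak id(s) never appear as auto-peaks: "
            f"{dangling[:5]}",
            stacklevel=2,
        )
    return graph


def read_noe_peaklist_str(text: str) -> NOEGraph:
    """Read a peak list from a string (same schema as :func:`read_noe_peaklist`)."""
    return read_noe_peaklist(io.StringIO(text))
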