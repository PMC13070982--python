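"""Structural models: methyl extraction, cut-off grids, SGBBs, structure graphs.

A structure graph has one node per labelled methyl group and a directed edge
``u -> v`` whenever ``v`` lies within the cut-off distance *selected for u*.
Because cut-offs are chosen per methyl, edges are generally asymmetric.  The
building block of such graphs is the SGBB: the star of one "active" methyl
at one specific cut-off.  For a grid of ``n`` cut-offs and ``m`` methyls
only ``n x m`` SGBBs exist, although they combine into ``n**m`` distinct
structure graphs.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .labelling import ATOM_POSITION, THREE_TO_ONE, LabellingScheme

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MethylGroup:
    """A labelled methyl site in the structural model.

    Coordinates are those of the methyl *carbon* atom: the NOESY dimensions
    are the methyl 13C/1H, and the carbon position is rotamer-invariant and
    always present in deposited models.  ``conformers`` maps a conformer key
    (``"<file>:<model>"``) to an ``(n_copies, 3)`` array; several copies per
    conformer arise when symmetry-equivalent chains of a homo-multimer are
    collapsed onto one node.
    """

    chain: str  # "*" for a symmetry-collapsed node
    resnum: int
    restype: str  # one-letter code
    atom: str  # methyl carbon atom name, e.g. "CD2"
    conformers: dict[str, np.ndarray]

    @property
    def methyl_id(self) -> str:
        base = f"{self.restype}{self.resnum}-{self.atom}"
        return base if self.chain == "*" else f"{self.chain}/{base}"

    @property
    def label(self) -> str:
        """Greek-position label, e.g. ``L128-d2``."""
        pos = ATOM_POSITION.get(self.atom, self.atom)
        return f"{self.restype}{self.resnum}-{pos}"

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.restype)

    @property
    def sort_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.atom)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MethylGroup({self.methyl_id}, {len(self.conformers)} conformer(s))"


@dataclass(frozen=True)
class CutoffGrid:
    """Cut-off distance grid (Å) used to build SGBBs.

    The default spans 3.0–9.0 Å in 0.2 Å steps (31 values).
    """

    min: float = 3.0
    max: float = 9.0
    step: float = 0.2

    def __post_init__(self) -> None:
        if not (self.min < self.max):
            raise ValueError("cutoff grid requires min < max")
        if self.step <= 0:
            raise ValueError("cutoff grid requires step > 0")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.max - self.min) / self.step))
        return np.round(self.min + self.step * np.arange(n + 1), 6)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[float]:
        return iter(float(v) for v in self.values)

    def __contains__(self, cutoff: float) -> bool:
        return bool(self.min - 1e-9 <= cutoff <= self.max + 1e-9)


@dataclass(frozen=True)
class SGBB:
    """Structure graph building block: star of one active methyl at one cut-off."""

    active: str  # methyl_id
    cutoff: float
    neighbours: tuple[str, ...]  # methyl_ids, sorted by increasing distance
    distances: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.neighbours)


@dataclass
class ParseReport:
    """Per-file account of skipped residues and other parse events."""

    skipped: list[str] = field(default_factory=list)
    n_files: int = 0
    n_models: int = 0


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _best_altloc(residue: gemmi.Residue, atom_name: str) -> gemmi.Atom | None:
    """Highest-occupancy copy of ``atom_name`` in ``residue`` (None if absent)."""
    best = None
    for atom in residue:
        if atom.name == atom_name:
            if best is None or atom.occ > best.occ:
                best = atom
    return best


def parse_structure(
    files: str | Path | Sequence[str | Path],
    scheme: LabellingScheme,
    *,
    collapse_symmetry: bool = True,
    report: ParseReport | None = None,
) -> list[MethylGroup]:
    """Extract labelled methyl groups from one or more PDB/mmCIF files.

    Every model of every file becomes one conformer, keyed
    ``"<file-index>:<model-number>"`` so that apo/holo or ensemble members
    of the same methyl line up.  With ``collapse_symmetry`` (default) the
    symmetry-equivalent copies of a residue across chains are merged into a
    single node — symmetric mates are NMR-indistinguishable — whose
    coordinate set is the union over chains.

    Residues with an unknown name raise :class:`ValueError`; a labelled
    residue missing its methyl carbon is skipped with a warning recorded in
    ``report``.
    """
    if isinstance(files, (str, Path)):
        files = [files]
    report = report if report is not None else ParseReport()
    # identity key -> {"restype":..., "atom":..., "chain":..., conf_key: [xyz...]}
    sites: dict[tuple, dict] = {}
    for file_idx, path in enumerate(files):
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        report.n_files += 1
        for model in st:
            conf_key = f"{file_idx}:{model.num}"
            report.n_models += 1
            for chain in model:
                for residue in chain:
                    name = residue.name.upper()
                    one = THREE_TO_ONE.get(name)
                    if one is None:
                        info = gemmi.find_tabulated_residue(name)
                        if info is None or not info.found():
                            raise ValueError(
                                f"unknown residue name {residue.name!r} at "
                                f"{chain.name} {residue.seqid.num}"
                            )
                        continue  # known residue without labelled methyls
                    for atom_name in scheme.atoms_for(one):
                        atom = _best_altloc(residue, atom_name)
                        if atom is None:
                            msg = (
                                f"{chain.name}/{name}{residue.seqid.num} lacks "
                                f"methyl carbon {atom_name}; skipped"
                            )
                            warnings.warn(msg, stacklevel=2)
                            report.skipped.append(msg)
                            continue
                        node_chain = "*" if collapse_symmetry else chain.name
                        key = (node_chain, residue.seqid.num, one, atom_name)
                        entry = sites.setdefault(key, {})
                        entry.setdefault(conf_key, []).append(
                            [atom.pos.x, atom.pos.y, atom.pos.z]
                        )
    methyls = [
        MethylGroup(
            chain=key[0],
            resnum=key[1],
            restype=key[2],
            atom=key[3],
            conformers={ck: np.asarray(v, dtype=float) for ck, v in entry.items()},
        )
        for key, entry in sites.items()
    ]
    methyls.sort(key=lambda m: m.sort_key)
    return methyls


def make_methyl(
    methyl_id_or_parts, xyz, conf_key: str = "0:1", chain: str = "*"
) -> MethylGroup:
    """Convenience constructor for in-memory methyls (tests, simulators).

    ``methyl_id_or_parts`` is either ``(restype, resnum, atom)`` or an id
    string like ``"L128-CD2"``.
    """
    if isinstance(methyl_id_or_parts, str):
        body = methyl_id_or_parts.split("/")[-1]
        restype = body[0]
        resnum_s, atom = body[1:].split("-")
        parts = (restype, int(resnum_s), atom)
    else:
        parts = methyl_id_or_parts
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    return MethylGroup(
        chain=chain,
        resnum=int(parts[1]),
        restype=parts[0],
        atom=parts[2],
        conformers={conf_key: xyz},
    )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def methyl_distance(a: MethylGroup, b: MethylGroup, mode: str = "min") -> float:
    """Carbon–carbon distance (Å) between two methyls under the ensemble rule.

    ``mode="min"`` takes the minimum over all shared conformers (and over
    chain copies within each conformer): a pair is "close" if it is close in
    at least one conformation.  ``mode="single"`` uses the first shared
    conformer only.
    """
    shared = sorted(set(a.conformers) & set(b.conformers))
    if not shared:
        raise ValueError(
            f"{a.methyl_id} and {b.methyl_id} share no conformer key"
        )
    if mode == "single":
        shared = shared[:1]
    elif mode != "min":
        raise ValueError(f"unknown ensemble mode {mode!r}")
    return min(float(cdist(a.conformers[k], b.conformers[k]).min()) for k in shared)


class MethylSet:
    """Indexed methyl collection with a precomputed distance matrix.

    Same-residue (geminal) methyl pairs — Leu delta1/delta2 and Val
    gamma1/gamma2 under non-stereospecific labelling — are excluded as
    neighbours of each other by default: their NOE is a trivially present
    geminal contact that carries no assignment information.
    """

    def __init__(
        self,
        methyls: Sequence[MethylGroup],
        mode: str = "min",
        exclude_geminal: bool = True,
    ):
        self.methyls = list(methyls)
        self.mode = mode
        self.exclude_geminal = exclude_geminal
        self.ids = [m.methyl_id for m in self.methyls]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate methyl ids")
        self.index = {mid: i for i, mid in enumerate(self.ids)}
        self.types = {m.methyl_id: m.restype for m in self.methyls}
        n = len(self.methyls)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = methyl_distance(
                    self.methyls[i], self.methyls[j], mode
                )
        self.dist = D
        # sorted neighbour lists (geminal pairs excluded if configured)
        self._sorted: list[tuple[np.ndarray, list[int]]] = []
        for i in range(n):
            others = [
                j
                for j in range(n)
                if j != i
                and not (
                    exclude_geminal
                    and self.methyls[j].residue_key == self.methyls[i].residue_key
                )
            ]
            order = sorted(others, key=lambda j: (D[i, j], self.ids[j]))
            self._sorted.append((np.array([D[i, j] for j in order]), order))

    def __len__(self) -> int:
        return len(self.methyls)

    def __getitem__(self, methyl_id: str) -> MethylGroup:
        return self.methyls[self.index[methyl_id]]

    def distance(self, a: str, b: str) -> float:
        return float(self.dist[self.index[a], self.index[b]])

    def neighbours_within(self, methyl_id: str, cutoff: float) -> tuple[list[str], list[float]]:
        """Neighbour ids and distances within ``cutoff`` Å, nearest first."""
        dists, order = self._sorted[self.index[methyl_id]]
        k = bisect_right(dists, cutoff + 1e-9)
        return [self.ids[j] for j in order[:k]], [float(d) for d in dists[:k]]

    def count_within(self, methyl_id: str, cutoff: float) -> int:
        dists, _ = self._sorted[self.index[methyl_id]]
        return int(bisect_right(dists, cutoff + 1e-9))

    def of_type(self, types: Iterable[str]) -> list[str]:
        tset = set(types)
        return [mid for mid in self.ids if self.types[mid] in tset]

    def geminal_partner(self, methyl_id: str) -> str | None:
        """The other prochiral methyl of the same residue, if present."""
        m = self[methyl_id]
        for other in self.methyls:
            if other.residue_key == m.residue_key and other.atom != m.atom:
                return other.methyl_id
        return None


# ---------------------------------------------------------------------------
# SGBBs and structure graphs
# ---------------------------------------------------------------------------


def build_sgbb(
    active: MethylGroup | str,
    cutoff: float,
    methyls: MethylSet | Sequence[MethylGroup],
    mode: str = "min",
) -> SGBB:
    """Star SGBB of ``active`` at ``cutoff``: all methyls within the cut-off."""
    if not isinstance(methyls, MethylSet):
        methyls = MethylSet(methyls, mode=mode)
    mid = active if isinstance(active, str) else active.methyl_id
    nbrs, dists = methyls.neighbours_within(mid, cutoff)
    return SGBB(active=mid, cutoff=float(cutoff), neighbours=tuple(nbrs), distances=tuple(dists))


class SGBBCollection:
    """All ``n_cutoffs x n_methyls`` SGBBs, keyed by ``(methyl_id, cutoff)``.

    Materialized lazily: the count contract holds without building every
    star up front.
    """

    def __init__(self, methyls: MethylSet | Sequence[MethylGroup], grid: CutoffGrid, mode: str = "min"):
        if not isinstance(methyls, MethylSet):
            methyls = MethylSet(methyls, mode=mode)
        if len(methyls) < 1:
            raise ValueError("need at least one methyl")
        self.methyls = methyls
        self.grid = grid
        self._cache: dict[tuple[str, float], SGBB] = {}

    def __len__(self) -> int:
        return len(self.grid) * len(self.methyls)

    def __getitem__(self, key: tuple[str, float]) -> SGBB:
        mid, cutoff = key
        cutoff = float(cutoff)
        if key not in self._cache:
            self._cache[(mid, cutoff)] = build_sgbb(mid, cutoff, self.methyls)
        return self._cache[(mid, cutoff)]

    def __iter__(self) -> Iterator[SGBB]:
        for mid in self.methyls.ids:
            for cutoff in self.grid:
                yield self[(mid, cutoff)]


def enumerate_sgbbs(
    methyls: MethylSet | Sequence[MethylGroup], grid: CutoffGrid, mode: str = "min"
) -> SGBBCollection:
    """Indexed SGBB collection over the cut-off grid (|collection| = n x m)."""
    return SGBBCollection(methyls, grid, mode=mode)


def count_structure_graphs(n_cutoffs: int, n_methyls: int) -> int:
    """Number of distinct structure graphs: ``n_cutoffs ** n_methyls`` (exact)."""
    if n_cutoffs < 1 or n_methyls < 1:
        raise ValueError("need n_cutoffs >= 1 and n_methyls >= 1")
    return int(n_cutoffs) ** int(n_methyls)


def assemble_structure_graph(
    selected: Mapping[str, float],
    methyls: MethylSet | Sequence[MethylGroup],
    mode: str = "min",
) -> nx.DiGraph:
    """Union of per-methyl SGBB stars for a cut-off selection.

    ``selected`` maps every methyl id to its cut-off.  Edges carry the
    distance and the producing cut-off; the graph is directed and generally
    asymmetric.
    """
    if not isinstance(methyls, MethylSet):
        methyls = MethylSet(methyls, mode=mode)
    missing = set(methyls.ids) - set(selected)
    if missing:
        raise ValueError(f"no cutoff selected for: {sorted(missing)[:5]} ...")
    g = nx.DiGraph()
    for m in methyls.methyls:
        g.add_node(
            m.methyl_id,
            restype=m.restype,
            resnum=m.resnum,
            chain=m.chain,
            atom=m.atom,
            cutoff=float(selected[m.methyl_id]),
        )
    for mid in methyls.ids:
        nbrs, dists = methyls.neighbours_within(mid, selected[mid])
        for nbr, d in zip(nbrs, dists):
            g.add_edge(mid, nbr, distance=round(d, 4), cutoff=float(selected[mid]))
    return g


def structure_contacts(methyls: MethylSet, cutoff: float) -> list[tuple[str, str, float]]:
    """Undirected contact list (a < b lexicographically) at a fixed cut-off."""
    out = []
    for i, mid in enumerate(methyls.ids):
        nbrs, dists = methyls.neighbours_within(mid, cutoff)
        for nbr, d in zip(nbrs, dists):
            if mid < nbr:
                out.append((mid, nbr, d))
    return out


def write_structure_graph(g: nx.DiGraph, graphml: str | Path | None = None, tsv: str | Path | None = None) -> None:
    """Export a structure graph as GraphML and/or a TSV edge list."""
    if graphml is not None:
        nx.write_graphml(g, str(graphml))
    if tsv is not None:
        with open(tsv, "w") as fh:
            fh.write("source_methyl\ttarget_methyl\tdistance_A\tcutoff_A\n")
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data['distance']:.3f}\t{data['cutoff']:.1f}\n")
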