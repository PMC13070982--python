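"""Scores driving the automated methyl walk.

Three scores are defined:

* **rarity score** of an NGBB within the pool ``G_NMR`` of NGBBs whose
  active nodes are still unassigned::

      rarity = - p_active**4 * prod_i p_neighbor_i          (in [-1, 0])

  with ``p_active`` the frequency of the active node's amino-acid type among
  active nodes of ``G_NMR`` and ``p_neighbor_i`` the frequency of the i-th
  out-neighbour's type among all out-neighbours in ``G_NMR``.  Scores closer
  to zero mark rarer local patterns — the best anchors for a walk.

* **similarity score** between an NGBB and a candidate SGBB whose active
  nodes share an amino-acid type::

      similarity = 2*c*W_NOE - |c - E_structure| - |c - E_NOE|  - penalty

  where ``c`` is the number of common edges (neighbour correspondences),
  ``E_*`` the neighbour counts of the two stars, and ``penalty`` the
  additional-restraints term: per configured restraint set,
  ``W_i * |a_exp - a_theo|`` at the two active nodes, or — if either value
  is unavailable — ``10 * W_i * |mu_exp - mu_theo|`` against the global
  set means of absolute values, so that missing data never favours an
  assignment.

* **total score** of a methyl walk: the sum of its step similarity scores.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .noe import IN_ONLY, OUT_ONLY, RECIPROCAL, NGBB, NGBBNeighbour

MISSING_RESTRAINT_MULTIPLIER = 10.0  # fixed fallback factor


# ---------------------------------------------------------------------------
# rarity
# ---------------------------------------------------------------------------


class RarityContext:
    """Type-frequency counts over the NGBBs with unassigned active nodes.

    A node carrying a candidate-type set contributes fractionally (1/|set|)
    to each of its candidate types; its own probability is then the total
    frequency mass of its candidate set.
    """

    def __init__(self, ngbbs: Sequence[NGBB]):
        self.n_total = len(ngbbs)
        self.n_total_neighbor = sum(b.k for b in ngbbs)
        self.active_ids = frozenset(b.active for b in ngbbs)
        self._active_w: dict[str, float] = defaultdict(float)
        self._neigh_w: dict[str, float] = defaultdict(float)
        for b in ngbbs:
            w = 1.0 / len(b.active_types)
            for t in b.active_types:
                self._active_w[t] += w
            for nb in b.out_neighbours:
                wn = 1.0 / len(nb.types)
                for t in nb.types:
                    self._neigh_w[t] += wn

    def p_active(self, types: frozenset[str]) -> float:
        if self.n_total == 0:
            return 0.0
        return sum(self._active_w.get(t, 0.0) for t in types) / self.n_total

    def p_neighbor(self, types: frozenset[str]) -> float:
        if self.n_total_neighbor == 0:
            return 0.0
        return sum(self._neigh_w.get(t, 0.0) for t in types) / self.n_total_neighbor


def rarity_score(ngbb: NGBB, ctx: RarityContext) -> float:
    """Rarity of an NGBB's active node within ``G_NMR`` (see module docs)."""
    p_act = ctx.p_active(ngbb.active_types)
    if p_act <= 0.0:
        raise ValueError(
            f"rarity context inconsistent: active type of {ngbb.active!r} "
            "has zero frequency in G_NMR"
        )
    score = -(p_act**4)
    for nb in ngbb.out_neighbours:
        score *= ctx.p_neighbor(nb.types)
    return score


# ---------------------------------------------------------------------------
# restraints and weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Weights:
    """Score weights: the NOE term weight and one weight per restraint set."""

    w_noe: float = 1.0
    w_restraints: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.w_noe < 0 or any(w < 0 for w in self.w_restraints):
            raise ValueError("weights must be non-negative")


@dataclass
class RestraintSets:
    """Paired experimental / theoretical long-range restraints (≤ 4 sets).

    ``exp`` maps resonance id -> {set index: value}; ``theo`` maps methyl id
    -> {set index: value}.  The global means of absolute values per set are
    computed once over available entries and back the missing-data fallback.
    """

    exp: dict[str, dict[int, float]] = field(default_factory=dict)
    theo: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = {i for d in self.exp.values() for i in d} | {
            i for d in self.theo.values() for i in d
        }
        if any(i < 1 or i > 4 for i in idx):
            raise ValueError("restraint set indices must be in 1..4")
        self.sets: tuple[int, ...] = tuple(sorted(idx))
        self.mu_exp: dict[int, float] = {}
        self.mu_theo: dict[int, float] = {}
        for i in self.sets:
            ev = [abs(d[i]) for d in self.exp.values() if i in d]
            tv = [abs(d[i]) for d in self.theo.values() if i in d]
            if not ev or not tv:
                raise ValueError(
                    f"restraint set {i} needs at least one experimental and "
                    "one theoretical value"
                )
            self.mu_exp[i] = sum(ev) / len(ev)
            self.mu_theo[i] = sum(tv) / len(tv)

    @property
    def configured(self) -> bool:
        return bool(self.sets)


def similarity_score_restraints(
    res_id: str,
    methyl_id: str,
    restraints: RestraintSets | None,
    weights: Weights = Weights(),
) -> float:
    """Additional-restraints penalty (≥ 0) at the two active nodes."""
    if restraints is None or not restraints.configured:
        return 0.0
    penalty = 0.0
    for i in restraints.sets:
        w_i = weights.w_restraints[i - 1]
        a_exp = restraints.exp.get(res_id, {}).get(i)
        a_theo = restraints.theo.get(methyl_id, {}).get(i)
        if a_exp is not None and a_theo is not None:
            penalty += w_i * abs(a_exp - a_theo)
        else:
            penalty += (
                MISSING_RESTRAINT_MULTIPLIER
                * w_i
                * abs(restraints.mu_exp[i] - restraints.mu_theo[i])
            )
    return penalty


# ---------------------------------------------------------------------------
# similarity (NOE term)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SGBBNeighbour:
    """One neighbour of a candidate SGBB, annotated for matching."""

    methyl_id: str
    restype: str
    cls: str  # RECIPROCAL / OUT_ONLY / IN_ONLY
    assigned_to: str | None = None  # resonance already holding this methyl


@dataclass(frozen=True)
class SGBBPattern:
    """A candidate SGBB prepared for similarity scoring."""

    active: str
    cutoff: float
    neighbours: tuple[SGBBNeighbour, ...]

    @property
    def n_edges(self) -> int:
        return len(self.neighbours)


_CLS_COMPAT = {
    RECIPROCAL: (RECIPROCAL,),
    OUT_ONLY: (OUT_ONLY, RECIPROCAL),
    IN_ONLY: (IN_ONLY, RECIPROCAL),
}


def _compatible(nb: NGBBNeighbour, sn: SGBBNeighbour) -> bool:
    # A one-directional NOE may simply miss the return peak, so it can match
    # a reciprocal structural edge; an observed reciprocal NOE demands one.
    return sn.restype in nb.types and sn.cls in _CLS_COMPAT[nb.cls]


def common_edges(
    ngbb: NGBB,
    sgbb: SGBBPattern,
    assigned: Mapping[str, str] | None = None,
) -> int:
    """Number of neighbour correspondences ``c`` between the two stars.

    Neighbours whose resonance is already assigned are matched by identity:
    they contribute iff their methyl is a neighbour of the candidate SGBB.
    The remaining neighbours are matched by maximum bipartite matching on
    (amino-acid type, edge-direction class) compatibility, which reduces to
    a per-category multiset intersection when types are unambiguous.
    """
    assigned = assigned or {}
    sgbb_ids = {sn.methyl_id for sn in sgbb.neighbours}
    c = 0
    free_noe: list[NGBBNeighbour] = []
    for nb in ngbb.neighbours:
        if nb.res_id in assigned:
            if assigned[nb.res_id] in sgbb_ids:
                c += 1
        else:
            free_noe.append(nb)
    pool = [sn for sn in sgbb.neighbours if sn.assigned_to is None]
    c += _max_bipartite(free_noe, pool)
    return c


def _max_bipartite(left: list[NGBBNeighbour], right: list[SGBBNeighbour]) -> int:
    """Kuhn's augmenting-path maximum matching (stars are small)."""
    adj = [
        [j for j, sn in enumerate(right) if _compatible(nb, sn)] for nb in left
    ]
    match_r = [-1] * len(right)

    def augment(i: int, seen: set[int]) -> bool:
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if match_r[j] == -1 or augment(match_r[j], seen):
                match_r[j] = i
                return True
        return False

    return sum(1 for i in range(len(left)) if augment(i, set()))


def similarity_score_noe(
    ngbb: NGBB,
    sgbb: SGBBPattern,
    w_noe: float = 1.0,
    assigned: Mapping[str, str] | None = None,
) -> float:
    """NOE term ``2*c*W_NOE - |c - E_structure| - |c - E_NOE|``."""
    score, _ = similarity_score_noe_with_c(ngbb, sgbb, w_noe, assigned)
    return score


def similarity_score_noe_with_c(
    ngbb: NGBB,
    sgbb: SGBBPattern,
    w_noe: float = 1.0,
    assigned: Mapping[str, str] | None = None,
) -> tuple[float, int]:
    if not (ngbb.active_types & _sgbb_active_types(sgbb, ngbb)):
        raise ValueError(
            f"active nodes of {ngbb.active!r} and {sgbb.active!r} share no "
            "amino-acid type"
        )
    c = common_edges(ngbb, sgbb, assigned)
    score = 2.0 * c * w_noe - abs(c - sgbb.n_edges) - abs(c - ngbb.n_edges)
    return score, c


def _sgbb_active_types(sgbb: SGBBPattern, ngbb: NGBB) -> frozenset[str]:
    # The SGBB active methyl's type is the first letter of its id body.
    body = sgbb.active.split("/")[-1]
    return frozenset(body[0])


def similarity_score(
    ngbb: NGBB,
    sgbb: SGBBPattern,
    restraints: RestraintSets | None = None,
    weights: Weights = Weights(),
    assigned: Mapping[str, str] | None = None,
) -> float:
    """Full similarity score: NOE term minus additional-restraints penalty."""
    noe_term = similarity_score_noe(ngbb, sgbb, weights.w_noe, assigned)
    penalty = similarity_score_restraints(
        ngbb.active, sgbb.active, restraints, weights
    )
    return noe_term - penalty


def total_score(
    pairs: Sequence[tuple[NGBB, SGBBPattern]],
    restraints: RestraintSets | None = None,
    weights: Weights = Weights(),
    assigned: Mapping[str, str] | None = None,
) -> float:
    """Total score of a methyl walk: sum of its pair similarity scores."""
    return sum(
        similarity_score(ngbb, sgbb, restraints, weights, assigned)
        for ngbb, sgbb in pairs
    )


def sgbb_pattern_static(sgbb, methyl_types: Mapping[str, str]) -> SGBBPattern:
    """Wrap a geometric :class:`~methylwalk.structure.SGBB` for scoring.

    All neighbours are treated as unassigned and reciprocal — the situation
    under a uniform cut-off, where distance symmetry makes every edge
    mutual.
    """
    return SGBBPattern(
        active=sgbb.active,
        cutoff=sgbb.cutoff,
        neighbours=tuple(
            SGBBNeighbour(mid, methyl_types[mid], RECIPROCAL) for mid in sgbb.neighbours
        ),
    )
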