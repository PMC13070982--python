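"""The automated methyl walk engine.

A walk starts from a *seminal* resonance — the rarest unassigned NGBB — and
matches it to the best methyl of the same amino-acid type by scanning every
candidate SGBB over the cut-off grid.  It then repeatedly picks the rarest
unassigned resonance NOE-adjacent to the assigned frontier, restricts the
candidate methyls to those structure-adjacent to the anchor's methyl, and
assigns the best-scoring (methyl, cut-off) pair, until no step passes the
acceptance floor.  One walk is tried from every eligible seminal; the walk
with the highest total score becomes a *cluster* and its members are fixed.
Iterating clusters to exhaustion yields the complete protein methyl walk
(CPMW).  Three CPMW replicas with increasing cut-off ranges classify each
resonance as safe (all replicas agree), ambiguous (they differ) or
unassigned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .noe import IN_ONLY, OUT_ONLY, RECIPROCAL, NGBB, NOEGraph
from .scoring import (
    RarityContext,
    RestraintSets,
    SGBBNeighbour,
    SGBBPattern,
    Weights,
    rarity_score,
    similarity_score_noe_with_c,
    similarity_score_restraints,
)
from .structure import CutoffGrid, MethylSet

_EPS = 1e-9


# ---------------------------------------------------------------------------
# configuration and records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WalkerConfig:
    """Tunables of the walk engine.

    The acceptance floor — a step needs a positive similarity score and at
    least ``min_common_edges`` matched neighbours (more for the riskier
    seminal step) — blocks zero-evidence assignments.  ``top_k_seminal``
    optionally restricts seminal enumeration to the K rarest resonances;
    ``None`` tries them all.
    """

    grid: CutoffGrid = CutoffGrid()
    weights: Weights = Weights()
    min_score: float = 0.0
    min_common_edges: int = 1
    min_common_edges_seminal: int = 2
    top_k_seminal: int | None = None


#: default replica cut-off ranges (Å) for the three confidence CPMWs
REPLICA_GRIDS: tuple[CutoffGrid, ...] = (
    CutoffGrid(3.0, 8.0, 0.2),
    CutoffGrid(3.0, 9.0, 0.2),
    CutoffGrid(3.0, 10.0, 0.2),
)

SAFE = "safe"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AssignmentStep:
    resonance: str
    methyl: str
    cutoff: float
    score: float
    common: int
    step_index: int
    seminal: bool


@dataclass
class MethylWalk:
    seminal: str
    steps: list[AssignmentStep] = field(default_factory=list)

    @property
    def total_score(self) -> float:
        return sum(s.score for s in self.steps)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class Cluster:
    walk: MethylWalk

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(s.resonance for s in self.walk.steps)


@dataclass
class CPMW:
    """One complete protein methyl walk (one replica)."""

    replica: int
    grid: CutoffGrid
    clusters: list[Cluster]
    assignment: dict[str, str]  # resonance -> methyl (incl. pre-assignments)
    selected_cutoffs: dict[str, float]  # methyl -> chosen cut-off
    eligible: tuple[str, ...]  # resonances with >= 1 NOE

    @property
    def cluster_sizes(self) -> list[int]:
        return [len(c.members) for c in self.clusters]


@dataclass
class ResonanceVerdict:
    status: str  # SAFE / AMBIGUOUS / UNASSIGNED
    methyl: str | None
    answers: tuple[str | None, ...]
    flags: list[str] = field(default_factory=list)


@dataclass
class ConfidenceReport:
    verdicts: dict[str, ResonanceVerdict]

    def assigned(self) -> dict[str, str]:
        return {
            r: v.methyl
            for r, v in self.verdicts.items()
            if v.status == SAFE and v.methyl is not None
        }


# ---------------------------------------------------------------------------
# assignment state
# ---------------------------------------------------------------------------


class AssignmentState:
    """Mutable assignment bookkeeping shared by walks of one CPMW."""

    def __init__(self, noe: NOEGraph, methyls: MethylSet, grid: CutoffGrid):
        self.noe = noe
        self.methyls = methyls
        self.grid = grid
        self.ngbbs: dict[str, NGBB] = {
            r: noe.extract_ngbb(r) for r in noe.resonances
        }
        self.res_to_methyl: dict[str, str] = {}
        self.methyl_to_res: dict[str, str] = {}
        self.selected_cutoff: dict[str, float] = {}
        self.fixed: set[str] = set()

    def copy(self) -> "AssignmentState":
        new = AssignmentState.__new__(AssignmentState)
        new.noe = self.noe
        new.methyls = self.methyls
        new.grid = self.grid
        new.ngbbs = self.ngbbs
        new.res_to_methyl = dict(self.res_to_methyl)
        new.methyl_to_res = dict(self.methyl_to_res)
        new.selected_cutoff = dict(self.selected_cutoff)
        new.fixed = set(self.fixed)
        return new

    def adopt(self, other: "AssignmentState") -> None:
        self.res_to_methyl = other.res_to_methyl
        self.methyl_to_res = other.methyl_to_res
        self.selected_cutoff = other.selected_cutoff
        self.fixed = other.fixed

    def assign(self, res: str, methyl: str, cutoff: float) -> None:
        if res in self.res_to_methyl or methyl in self.methyl_to_res:
            raise ValueError(f"injectivity violated at {res} -> {methyl}")
        self.res_to_methyl[res] = methyl
        self.methyl_to_res[methyl] = res
        self.selected_cutoff[methyl] = float(cutoff)

    def unassigned_resonances(self) -> list[str]:
        return [r for r in self.noe.resonances if r not in self.res_to_methyl]

    def unassigned_ngbbs(self) -> list[NGBB]:
        return [self.ngbbs[r] for r in self.unassigned_resonances()]

    def type_compatible_methyls(self, res: str) -> list[str]:
        types = self.noe.types(res)
        return [
            m
            for m in self.methyls.of_type(types)
            if m not in self.methyl_to_res
        ]


def sgbb_pattern(state: AssignmentState, methyl: str, cutoff: float) -> SGBBPattern:
    """Candidate SGBB of ``methyl`` at ``cutoff`` under the current state.

    Unassigned neighbours count as reciprocal (a uniform trial cut-off is
    distance-symmetric); assigned neighbours are reciprocal only if their
    selected cut-off reaches back to the active methyl.  Assigned methyls
    beyond the trial cut-off whose own cut-off covers the active methyl are
    included as incoming-only neighbours: the partially built structure
    graph predicts an NOE the candidate must account for.
    """
    ms = state.methyls
    nbr_ids, dists = ms.neighbours_within(methyl, cutoff)
    nbr_set = set(nbr_ids)
    entries = []
    for nbr, d in zip(nbr_ids, dists):
        res = state.methyl_to_res.get(nbr)
        if res is None:
            cls = RECIPROCAL
        else:
            cls = (
                RECIPROCAL
                if state.selected_cutoff.get(nbr, state.grid.max) >= d - _EPS
                else OUT_ONLY
            )
        entries.append(SGBBNeighbour(nbr, ms.types[nbr], cls, assigned_to=res))
    for other, cut in state.selected_cutoff.items():
        if other == methyl or other in nbr_set:
            continue
        if other not in ms.index:
            continue
        d = ms.distance(methyl, other)
        if cutoff + _EPS < d <= cut + _EPS:
            if ms.exclude_geminal and ms[other].residue_key == ms[methyl].residue_key:
                continue
            entries.append(
                SGBBNeighbour(
                    other, ms.types[other], IN_ONLY, assigned_to=state.methyl_to_res[other]
                )
            )
    return SGBBPattern(active=methyl, cutoff=float(cutoff), neighbours=tuple(entries))


# ---------------------------------------------------------------------------
# walk steps
# ---------------------------------------------------------------------------


def select_seminal(state: AssignmentState) -> NGBB | None:
    """Rarest unassigned NGBB with at least one neighbour (None = done)."""
    pool = [b for b in state.unassigned_ngbbs() if b.neighbours]
    if not pool:
        return None
    ctx = RarityContext(state.unassigned_ngbbs())
    return max(pool, key=lambda b: (rarity_score(b, ctx), _rev(b.active)))


def _rev(s: str):
    # max() tie-break helper: prefer lexicographically smaller id
    return tuple(-ord(ch) for ch in s)


def best_match(
    state: AssignmentState,
    ngbb: NGBB,
    candidates: Iterable[str],
    config: WalkerConfig,
    restraints: RestraintSets | None,
    *,
    seminal: bool,
    dump: list | None = None,
) -> tuple[str, float, float, int] | None:
    """Best (methyl, cutoff, score, c) over candidates x cut-off grid.

    Cut-offs producing the same neighbour set as a smaller one are skipped;
    ties resolve toward the smallest cut-off, then the lexicographically
    first methyl.  Returns ``None`` when the best step fails the acceptance
    floor.  ``dump`` collects one row per evaluated candidate (the
    score-dump debug output).
    """
    floor_c = config.min_common_edges_seminal if seminal else config.min_common_edges
    assigned = state.res_to_methyl
    best: tuple[str, float, float, int] | None = None
    best_key: tuple | None = None
    for methyl in sorted(set(candidates), key=lambda m: state.methyls[m].sort_key):
        if methyl in state.methyl_to_res:
            continue
        penalty = similarity_score_restraints(
            ngbb.active, methyl, restraints, config.weights
        )
        last_k = -1
        for cutoff in config.grid:
            k_within = state.methyls.count_within(methyl, cutoff)
            if k_within == last_k:
                continue
            last_k = k_within
            pat = sgbb_pattern(state, methyl, cutoff)
            noe_term, c = similarity_score_noe_with_c(
                ngbb, pat, config.weights.w_noe, assigned
            )
            score = noe_term - penalty
            if dump is not None:
                dump.append(
                    {
                        "resonance": ngbb.active,
                        "methyl": methyl,
                        "cutoff": float(cutoff),
                        "score": score,
                        "common_edges": c,
                        "seminal": seminal,
                    }
                )
            # ties resolve toward the smaller cut-off (NOEs fall off with
            # distance, so the tighter star is the more plausible match),
            # then the lexicographically first methyl
            key = (cutoff, state.methyls[methyl].sort_key)
            if (
                best is None
                or score > best[2] + _EPS
                or (score > best[2] - _EPS and key < best_key)
            ):
                best = (methyl, float(cutoff), score, c)
                best_key = key
    if best is None:
        return None
    if best[2] <= config.min_score + _EPS or best[3] < floor_c:
        return None
    return best


def run_walk(
    state: AssignmentState,
    seminal_res: str,
    config: WalkerConfig,
    restraints: RestraintSets | None = None,
    dump: list | None = None,
) -> MethylWalk:
    """Grow one methyl walk from ``seminal_res``, mutating ``state``.

    The frontier includes previously committed assignments (clusters and
    pre-assignments), so later walks may anchor on them; only the newly
    assigned resonances belong to the returned walk.
    """
    walk = MethylWalk(seminal=seminal_res)
    ngbb = state.ngbbs[seminal_res]
    bm = best_match(
        state,
        ngbb,
        state.type_compatible_methyls(seminal_res),
        config,
        restraints,
        seminal=True,
        dump=dump,
    )
    if bm is None:
        return walk
    methyl, cutoff, score, c = bm
    state.assign(seminal_res, methyl, cutoff)
    walk.steps.append(
        AssignmentStep(seminal_res, methyl, cutoff, score, c, 0, True)
    )
    grid_max = config.grid.max
    while True:
        frontier = set(state.res_to_methyl)
        adjacent = sorted(
            {
                r
                for f in frontier
                for r in _noe_neighbours(state.noe, f)
                if r not in state.res_to_methyl
            }
        )
        if not adjacent:
            break
        ctx = RarityContext(state.unassigned_ngbbs())
        order = sorted(
            adjacent,
            key=lambda r: (-rarity_score(state.ngbbs[r], ctx), r),
        )
        progressed = False
        for res in order:
            anchors = [
                state.res_to_methyl[f]
                for f in _noe_neighbours(state.noe, res)
                if f in state.res_to_methyl
            ]
            candidates = [
                m
                for m in state.type_compatible_methyls(res)
                if any(state.methyls.distance(m, a) <= grid_max + _EPS for a in anchors)
            ]
            bm = best_match(
                state, state.ngbbs[res], candidates, config, restraints,
                seminal=False, dump=dump,
            )
            if bm is None:
                continue
            methyl, cutoff, score, c = bm
            state.assign(res, methyl, cutoff)
            walk.steps.append(
                AssignmentStep(res, methyl, cutoff, score, c, len(walk.steps), False)
            )
            progressed = True
            break
        if not progressed:
            break
    return walk


def _noe_neighbours(noe: NOEGraph, res: str) -> set[str]:
    return set(noe.g.successors(res)) | set(noe.g.predecessors(res))


# ---------------------------------------------------------------------------
# clusters and CPMW
# ---------------------------------------------------------------------------


def run_cluster(
    state: AssignmentState,
    config: WalkerConfig,
    restraints: RestraintSets | None = None,
    dump: list | None = None,
) -> Cluster | None:
    """Try a walk from every eligible seminal; commit the best-scoring one.

    Returns ``None`` when every candidate walk is empty (CPMW finished).
    Ties resolve toward more steps, then the earlier seminal id.  When
    ``dump`` is given, the winning walk is replayed (walks are
    deterministic) to record all candidate scores per committed step.
    """
    eligible = [
        r
        for r in state.unassigned_resonances()
        if state.ngbbs[r].neighbours
    ]
    if not eligible:
        return None
    if config.top_k_seminal is not None and len(eligible) > config.top_k_seminal:
        ctx = RarityContext(state.unassigned_ngbbs())
        eligible = sorted(
            eligible, key=lambda r: (-rarity_score(state.ngbbs[r], ctx), r)
        )[: config.top_k_seminal]
    best_walk: MethylWalk | None = None
    best_state: AssignmentState | None = None
    for sem in sorted(eligible):
        trial = state.copy()
        walk = run_walk(trial, sem, config, restraints)
        if not walk.steps:
            continue
        if best_walk is None or (walk.total_score, len(walk), _rev(walk.seminal)) > (
            best_walk.total_score,
            len(best_walk),
            _rev(best_walk.seminal),
        ):
            best_walk, best_state = walk, trial
    if best_walk is None:
        return None
    assert best_state is not None
    if dump is not None:
        replay = state.copy()
        run_walk(replay, best_walk.seminal, config, restraints, dump=dump)
    state.adopt(best_state)
    return Cluster(best_walk)


def apply_preassignments(
    pairs: Mapping[str, str] | Sequence[tuple[str, str]],
    state: AssignmentState,
) -> AssignmentState:
    """Seed fixed resonance->methyl assignments before any walk.

    Fixed pairs must be type-consistent and injective; they are never
    reassigned and walks may anchor on them.  Their structural cut-off is
    taken as the grid maximum (most permissive anchoring).
    """
    items = list(pairs.items()) if isinstance(pairs, Mapping) else list(pairs)
    seen_r: set[str] = set()
    seen_m: set[str] = set()
    for res, methyl in items:
        if res in seen_r or methyl in seen_m:
            raise ValueError(f"duplicate or conflicting pre-assignment {res} -> {methyl}")
        seen_r.add(res)
        seen_m.add(methyl)
        if res not in state.noe.g:
            raise ValueError(f"pre-assigned resonance {res!r} not in the NOE graph")
        if methyl not in state.methyls.index:
            raise ValueError(f"pre-assigned methyl {methyl!r} not in the structure")
        if state.methyls.types[methyl] not in state.noe.types(res):
            raise ValueError(
                f"pre-assignment {res} -> {methyl} is type-inconsistent"
            )
    for res, methyl in items:
        state.assign(res, methyl, state.grid.max)
        state.fixed.add(res)
    return state


def run_cpmw(
    noe: NOEGraph,
    methyls: MethylSet,
    config: WalkerConfig,
    restraints: RestraintSets | None = None,
    preassignments: Mapping[str, str] | None = None,
    replica: int = 0,
    dump: list | None = None,
) -> CPMW:
    """Iterate clusters to exhaustion for one cut-off range."""
    state = AssignmentState(noe, methyls, config.grid)
    if preassignments:
        apply_preassignments(preassignments, state)
    eligible = tuple(
        r for r in noe.resonances if state.ngbbs[r].neighbours
    )
    clusters: list[Cluster] = []
    while True:
        cluster = run_cluster(state, config, restraints, dump=dump)
        if cluster is None:
            break
        clusters.append(cluster)
    return CPMW(
        replica=replica,
        grid=config.grid,
        clusters=clusters,
        assignment=dict(state.res_to_methyl),
        selected_cutoffs=dict(state.selected_cutoff),
        eligible=eligible,
    )


# ---------------------------------------------------------------------------
# confidence classification and safeguards
# ---------------------------------------------------------------------------


def classify_confidence(
    cpmws: Sequence[CPMW],
    methyls: MethylSet | None = None,
    nonstereo_types: frozenset[str] = frozenset(),
) -> ConfidenceReport:
    """Combine three CPMW replicas into per-resonance confidence verdicts.

    Safe: all replicas agree on one methyl.  Ambiguous: at least two
    distinct answers (a geminal delta1/delta2 or gamma1/gamma2 split under
    non-stereospecific labelling is flagged ``stereo_pair``).  Unassigned:
    no replica produced an answer.
    """
    if len(cpmws) != 3:
        raise ValueError(f"confidence classification needs 3 replicas, got {len(cpmws)}")
    resonances = sorted({r for c in cpmws for r in c.eligible})
    verdicts: dict[str, ResonanceVerdict] = {}
    for res in resonances:
        answers = tuple(c.assignment.get(res) for c in cpmws)
        given = [a for a in answers if a is not None]
        if not given:
            verdicts[res] = ResonanceVerdict(UNASSIGNED, None, answers)
        elif len(given) == 3 and len(set(given)) == 1:
            verdicts[res] = ResonanceVerdict(SAFE, given[0], answers)
        else:
            flags = []
            if (
                methyls is not None
                and len({_residue_of(methyls, a) for a in set(given)}) == 1
                and len(set(given)) > 1
                and methyls[given[0]].restype in nonstereo_types
            ):
                flags.append("stereo_pair")
            verdicts[res] = ResonanceVerdict(AMBIGUOUS, None, answers, flags)
    return ConfidenceReport(verdicts)


def _residue_of(methyls: MethylSet, methyl_id: str):
    return methyls[methyl_id].residue_key


def methyls_equivalent(
    a: str, b: str, methyls: MethylSet, nonstereo_types: frozenset[str]
) -> bool:
    """True if two methyl ids are the same, or a geminal pair whose residue
    type is non-stereospecifically labelled (proS/proR indistinguishable)."""
    if a == b:
        return True
    ma, mb = methyls[a], methyls[b]
    return ma.residue_key == mb.residue_key and ma.restype in nonstereo_types


@dataclass
class SafeguardResult:
    flagged: dict[str, list[str]]  # resonance -> flags
    summary: list[dict]  # per-set statistics
    correlation: list[dict]  # per-assignment residual rows


def apply_restraint_safeguard(
    report: ConfidenceReport,
    restraints: RestraintSets,
    k_sigma: float = 1.0,
) -> SafeguardResult:
    """Flag safe assignments whose restraint residual is an outlier.

    Per configured set, residuals ``r = a_exp - a_theo`` over safe
    assignments with both values are summarized; assignments with
    ``|r - mean| > k_sigma * std`` are demoted to unassigned (the structural
    model and the solution conformation disagree there, or the assignment is
    wrong).  A set with fewer than 3 residuals is skipped with a warning; a
    zero spread flags nothing.
    """
    flagged: dict[str, list[str]] = {}
    summary: list[dict] = []
    correlation: list[dict] = []
    assigned = report.assigned()
    for i in restraints.sets:
        rows = []
        for res, methyl in sorted(assigned.items()):
            a_exp = restraints.exp.get(res, {}).get(i)
            a_theo = restraints.theo.get(methyl, {}).get(i)
            if a_exp is None or a_theo is None:
                continue
            rows.append((res, methyl, a_exp, a_theo, a_exp - a_theo))
        if len(rows) < 3:
            warnings.warn(
                f"restraint set {i}: only {len(rows)} assigned pair(s) with "
                "values; safeguard skipped",
                stacklevel=2,
            )
            continue
        residuals = [r[4] for r in rows]
        mean = sum(residuals) / len(residuals)
        var = sum((x - mean) ** 2 for x in residuals) / len(residuals)
        std = math.sqrt(var)
        n_flagged = 0
        for res, methyl, a_exp, a_theo, resid in rows:
            outlier = std > 0 and abs(resid - mean) > k_sigma * std + _EPS
            correlation.append(
                {
                    "set": i,
                    "resonance": res,
                    "methyl": methyl,
                    "a_exp": a_exp,
                    "a_theo": a_theo,
                    "residual": resid,
                    "flagged": outlier,
                }
            )
            if outlier:
                flagged.setdefault(res, []).append(f"safeguard_set_{i}")
                n_flagged += 1
        summary.append(
            {"set": i, "n": len(rows), "mean": mean, "std": std, "flagged": n_flagged}
        )
    for res, flags in flagged.items():
        v = report.verdicts[res]
        report.verdicts[res] = ResonanceVerdict(
            UNASSIGNED, None, v.answers, v.flags + flags
        )
    return SafeguardResult(flagged=flagged, summary=summary, correlation=correlation)
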