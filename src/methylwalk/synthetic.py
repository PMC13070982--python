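"""Synthetic methyl coordinate sets and NOE networks with ground truth.

The benchmark protocol mirrors how sparse experimental NOE data relate to a
structure: starting from the fixed-cut-off structure graph of a methyl
coordinate set, undirected contacts are removed uniformly at random until
the NOE density (undirected contacts per methyl) falls inside a target
interval — 1.75–2.1 NOEs per methyl resonance by default, the range of
realistic methyl-TROSY datasets.  Each surviving contact becomes a
reciprocal edge pair, of which one direction is dropped with a configurable
probability (default 0.2) to emulate cross-peaks observed in only one NOESY
plane.  No spurious contacts are injected by default: an optional noise
parameter exists but the baseline protocol only removes edges.

Ground truth (the resonance -> methyl bijection) is retained, so predicted
assignments can be scored as correct / erroneous / ambiguous / unassigned
over the resonances that carry at least one NOE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .labelling import LabellingScheme
from .noe import NOEGraph
from .structure import MethylGroup, MethylSet, make_methyl, structure_contacts
from .walker import (
    AMBIGUOUS,
    SAFE,
    UNASSIGNED,
    ConfidenceReport,
    methyls_equivalent,
)

#: approximate relative abundances of the methyl-bearing amino acids in
#: globular proteins (Met is rare, Leu common) — used to draw residue types
_AA_ABUNDANCE = {"A": 8.3, "I": 5.9, "L": 9.7, "M": 2.4, "T": 5.5, "V": 6.9}

DEFAULT_DENSITY_INTERVAL = (1.75, 2.1)
DEFAULT_BASE_CUTOFF = 7.0
DEFAULT_UNIDIRECTIONAL_FRACTION = 0.2


@dataclass
class SyntheticNetwork:
    """A simulated NOE network plus its generating parameters and truth."""

    noe: NOEGraph
    truth: dict[str, str]  # resonance -> methyl
    base_cutoff: float
    target_density: tuple[float, float]
    seed: int
    unidirectional_fraction: float
    achieved_density: float  # undirected contacts / n_methyls
    n_methyls: int


@dataclass
class EvaluationResult:
    """Assignment statistics over resonances with at least one NOE."""

    correct: int
    erroneous: int
    ambiguous: int
    unassigned: int

    @property
    def denominator(self) -> int:
        return self.correct + self.erroneous + self.ambiguous + self.unassigned

    def percentages(self) -> dict[str, float]:
        d = self.denominator
        if d == 0:
            raise ValueError("no resonances to evaluate")
        return {
            "correct": 100.0 * self.correct / d,
            "erroneous": 100.0 * self.erroneous / d,
            "ambiguous": 100.0 * self.ambiguous / d,
            "unassigned": 100.0 * self.unassigned / d,
        }


# ---------------------------------------------------------------------------
# coordinate generation
# ---------------------------------------------------------------------------


def synth_methyls(
    n: int,
    min_separation: float = 4.0,
    box: float | None = None,
    seed: int = 0,
    scheme: LabellingScheme | None = None,
    max_tries: int = 20000,
) -> list[MethylGroup]:
    """Random methyl coordinate set: a synthetic stand-in for a structure.

    ``n`` methyls receive residue types drawn from globular-protein
    abundances restricted to the scheme's active residues (default
    MIL(proS)V(proS)AT — one methyl per residue), and uniform positions in a
    cubic box with all pairwise distances >= ``min_separation`` (dart
    throwing).  When ``box`` is None its side is chosen to give ~175 A^3 per
    methyl, a protein-like packing where a 7 A cut-off yields roughly 4
    contacts per methyl.  Fully reproducible from ``seed``.
    """
    if scheme is None:
        scheme = LabellingScheme.from_token("MILproSVproSAT")
    rng = np.random.default_rng(seed)
    if box is None:
        box = float((n * 175.0) ** (1.0 / 3.0))
    letters = sorted(scheme.residues)
    probs = np.array([_AA_ABUNDANCE[t] for t in letters], dtype=float)
    probs /= probs.sum()
    types = rng.choice(letters, size=n, p=probs)
    positions: list[np.ndarray] = []
    tries = 0
    while len(positions) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} methyls with min separation "
                f"{min_separation} A in a {box:.1f} A box"
            )
        tries += 1
        p = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(p - q) >= min_separation for q in positions):
            positions.append(p)
    methyls = []
    for i, (t, p) in enumerate(zip(types, positions), start=1):
        atoms = scheme.atoms_for(t)
        # one methyl per synthetic residue: under non-stereospecific schemes
        # take the proS methyl as the representative site
        atom = atoms[-1] if len(atoms) > 1 else atoms[0]
        methyls.append(make_methyl((str(t), i, atom), p))
    return methyls


def synth_protein_like(
    n: int = 100, seed: int = 0, scheme: LabellingScheme | None = None
) -> list[MethylGroup]:
    """Compact globular synthetic coordinate set (sphere-packed).

    Positions are drawn uniformly in a sphere whose radius gives the same
    ~175 A^3 per methyl as :func:`synth_methyls`, producing the contiguous
    contact network of a folded domain rather than a box with corners.
    """
    if scheme is None:
        scheme = LabellingScheme.from_token("MILproSVproSAT")
    rng = np.random.default_rng(seed)
    radius = float((3.0 * n * 175.0 / (4.0 * np.pi)) ** (1.0 / 3.0))
    letters = sorted(scheme.residues)
    probs = np.array([_AA_ABUNDANCE[t] for t in letters], dtype=float)
    probs /= probs.sum()
    types = rng.choice(letters, size=n, p=probs)
    positions: list[np.ndarray] = []
    tries = 0
    while len(positions) < n:
        if tries > 200000:
            raise RuntimeError("sphere packing failed")
        tries += 1
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) > radius:
            continue
        if all(np.linalg.norm(p - q) >= 4.0 for q in positions):
            positions.append(p)
    out = []
    for i, (t, p) in enumerate(zip(types, positions), start=1):
        atoms = scheme.atoms_for(str(t))
        atom = atoms[-1] if len(atoms) > 1 else atoms[0]
        out.append(make_methyl((str(t), i, atom), p))
    return out


_ONE_TO_THREE = {"M": "MET", "I": "ILE", "L": "LEU", "V": "VAL", "A": "ALA", "T": "THR"}


def write_synthetic_pdb(methyls: list[MethylGroup] | MethylSet, path) -> None:
    """Write a synthetic coordinate set as a PDB file (methyl carbons only).

    One residue per methyl, carrying just the methyl carbon atom — enough
    for :func:`~methylwalk.structure.parse_structure` to rebuild the same
    methyl set.  The file is synthetic: it corresponds to no deposited
    structure.
    """
    if isinstance(methyls, MethylSet):
        methyls = methyls.methyls
    lines = ["REMARK   1 SYNTHETIC METHYL COORDINATE SET (methylwalk)"]
    serial = 1
    for m in sorted(methyls, key=lambda x: x.sort_key):
        x, y, z = m.conformers[sorted(m.conformers)[0]][0]
        chain = "A" if m.chain == "*" else m.chain
        lines.append(
            f"ATOM  {serial:5d}  {m.atom:<3s}{_ONE_TO_THREE[m.restype]:>4s} "
            f"{chain}{m.resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"           C"
        )
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def unique_neighbourhood_signatures(
    methyls: list[MethylGroup] | MethylSet,
    cutoff: float = DEFAULT_BASE_CUTOFF,
    refinement_rounds: int = 2,
) -> bool:
    """True if every methyl's neighbourhood signature is unique.

    The signature is the amino-acid type refined by the sorted multiset of
    neighbour signatures (Weisfeiler–Leman colour refinement on the
    fixed-cut-off structure graph).  When all signatures are distinct the
    graph has no non-trivial type-preserving automorphism candidates at the
    local level, so a noiseless NOE network determines the assignment.
    """
    if not isinstance(methyls, MethylSet):
        methyls = MethylSet(methyls)
    adj: dict[str, list[str]] = {m: [] for m in methyls.ids}
    for a, b, _ in structure_contacts(methyls, cutoff):
        adj[a].append(b)
        adj[b].append(a)
    colour = {m: methyls.types[m] for m in methyls.ids}
    for _ in range(refinement_rounds):
        colour = {
            m: f"{colour[m]}|{','.join(sorted(colour[x] for x in adj[m]))}"
            for m in methyls.ids
        }
    return len(set(colour.values())) == len(colour)


# ---------------------------------------------------------------------------
# network simulation
# ---------------------------------------------------------------------------


def simulate_noe_network(
    methyls: list[MethylGroup] | MethylSet,
    base_cutoff: float = DEFAULT_BASE_CUTOFF,
    target_density: tuple[float, float] = DEFAULT_DENSITY_INTERVAL,
    seed: int = 0,
    unidirectional_fraction: float = DEFAULT_UNIDIRECTIONAL_FRACTION,
    spurious_contacts: int = 0,
) -> SyntheticNetwork:
    """Simulate an NOE network by random contact removal from a structure graph.

    See the module docstring for the protocol.  If the base structure graph
    is already sparser than the target maximum, nothing is removed (with a
    warning).  The achieved density is measured as undirected contacts per
    methyl of the *input* coordinate set.
    """
    if not isinstance(methyls, MethylSet):
        methyls = MethylSet(methyls)
    lo, hi = target_density
    if not (0 <= lo <= hi):
        raise ValueError("invalid target density interval")
    rng = np.random.default_rng(seed)
    n = len(methyls)
    contacts = [(a, b) for a, b, _ in structure_contacts(methyls, base_cutoff)]
    base_contacts = set(contacts)
    if spurious_contacts:
        # optional noise: defaults to 0 — the baseline protocol only removes
        all_ids = methyls.ids
        added = 0
        while added < spurious_contacts:
            a, b = rng.choice(all_ids, size=2, replace=False)
            pair = tuple(sorted((str(a), str(b))))
            if pair not in base_contacts and methyls[pair[0]].residue_key != methyls[pair[1]].residue_key:
                contacts.append(pair)
                base_contacts.add(pair)
                added += 1
    if len(contacts) / n < hi:
        warnings.warn(
            f"base structure graph density {len(contacts) / n:.2f} below the "
            f"target maximum {hi}; returning the full graph",
            stacklevel=2,
        )
        kept = list(contacts)
    else:
        lo_count = int(np.ceil(lo * n - 1e-9))
        hi_count = int(np.floor(hi * n + 1e-9))
        target_count = int(rng.integers(lo_count, hi_count + 1))
        order = rng.permutation(len(contacts))
        kept = [contacts[i] for i in sorted(order[:target_count])]
    # resonance ids in randomized order so peak ids carry no information
    with_noe = sorted({m for pair in kept for m in pair})
    perm = rng.permutation(len(with_noe))
    truth = {f"P{perm[i] + 1:04d}": mid for i, mid in enumerate(with_noe)}
    rev = {mid: rid for rid, mid in truth.items()}
    noe = NOEGraph()
    for rid, mid in sorted(truth.items()):
        noe.add_resonance(rid, methyls.types[mid])
    for a, b in kept:
        ra, rb = rev[a], rev[b]
        if rng.random() < unidirectional_fraction:
            if rng.random() < 0.5:
                noe.add_contact(ra, rb)
            else:
                noe.add_contact(rb, ra)
        else:
            noe.add_contact(ra, rb)
            noe.add_contact(rb, ra)
    return SyntheticNetwork(
        noe=noe,
        truth=truth,
        base_cutoff=base_cutoff,
        target_density=(lo, hi),
        seed=seed,
        unidirectional_fraction=unidirectional_fraction,
        achieved_density=len(kept) / n,
        n_methyls=n,
    )


def simulate_restraints(
    methyls: MethylSet,
    truth: dict[str, str],
    n_sets: int = 1,
    scale: float = 0.3,
    noise: float = 0.02,
    missing_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, dict[int, float]], dict[str, dict[int, float]]]:
    """Synthetic long-range restraints (PCS-like, ppm scale).

    Theoretical values per methyl are drawn N(0, scale); the experimental
    value of each resonance is its true methyl's value plus N(0, noise),
    missing with probability ``missing_fraction``.  Returns ``(exp, theo)``
    maps suitable for :class:`~methylwalk.scoring.RestraintSets`.
    """
    rng = np.random.default_rng(seed)
    theo: dict[str, dict[int, float]] = {}
    for mid in methyls.ids:
        theo[mid] = {i: float(rng.normal(0.0, scale)) for i in range(1, n_sets + 1)}
    exp: dict[str, dict[int, float]] = {}
    for rid, mid in sorted(truth.items()):
        vals = {}
        for i in range(1, n_sets + 1):
            if rng.random() >= missing_fraction:
                vals[i] = float(theo[mid][i] + rng.normal(0.0, noise))
        if vals:
            exp[rid] = vals
    return exp, theo


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_assignments(
    report: ConfidenceReport,
    truth: dict[str, str],
    methyls: MethylSet | None = None,
    nonstereo_types: frozenset[str] = frozenset(),
) -> EvaluationResult:
    """Score a confidence report against ground truth.

    A safe assignment to the geminal partner of the true methyl counts as
    correct when that residue type is non-stereospecifically labelled
    (proS/proR methyls are NMR-equivalent then).
    """
    counts = {SAFE + "_correct": 0, SAFE + "_wrong": 0, AMBIGUOUS: 0, UNASSIGNED: 0}
    for res, verdict in report.verdicts.items():
        if res not in truth:
            raise KeyError(f"resonance {res!r} missing from ground truth")
        if verdict.status == SAFE:
            assert verdict.methyl is not None
            ok = (
                verdict.methyl == truth[res]
                if methyls is None
                else methyls_equivalent(verdict.methyl, truth[res], methyls, nonstereo_types)
            )
            counts[SAFE + ("_correct" if ok else "_wrong")] += 1
        else:
            counts[verdict.status] += 1
    return EvaluationResult(
        correct=counts[SAFE + "_correct"],
        erroneous=counts[SAFE + "_wrong"],
        ambiguous=counts[AMBIGUOUS],
        unassigned=counts[UNASSIGNED],
    )
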