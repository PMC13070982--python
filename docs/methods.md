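# Methods

`methylwalk` automates the "methyl walk" strategy used to assign
¹H,¹³C-methyl resonances of large, selectively methyl-labelled proteins
from a single NOESY dataset and a structural model. This note describes
the model, the scores, the walk engine, the synthetic benchmark, and the
design choices made where more than one reasonable implementation exists.

## Problem setting and graphs

A methyl-TROSY spectrum of a MILVAT-labelled protein shows one peak per
labelled methyl. A 3D/4D HMQC-NOESY-HMQC experiment adds, for each
auto-peak, cross-peaks to methyls within NOE distance (≲ 10 Å). We encode
this as a **directed NOE graph**: nodes are resonances with an amino-acid
type (or a candidate-type set, when typing by difference spectra is
incomplete) and optional long-range restraint values (e.g. PCS, up to four
sets); an edge `u → v` records a cross-peak in the NOESY plane of `u`.
Reciprocal edge pairs — the same contact observed from both planes — carry
more weight than unidirectional ones. NOE intensities are not used.

On the structure side, each labelled methyl carbon is a node and `u → v`
exists when `v` lies within the cut-off distance chosen for `u`. Because
observed NOEs depend on more than the internuclear distance (dynamics,
spin diffusion), the cut-off is a per-methyl free parameter sampled from a
grid (3.0–9.0 Å in 0.2 Å steps by default). With `n` grid values and `m`
methyls there are `n**m` distinct structure graphs, but only `n × m`
**structure graph building blocks** (SGBBs) — stars of one active methyl
at one cut-off — and any member of the family is a union of per-methyl
stars. The matcher therefore works entirely with building blocks: the
star of a resonance in the NOE graph (NGBB) is compared against candidate
SGBBs over the grid.

## Scores

**Rarity** ranks unassigned resonances by how unusual their local pattern
is within the pool `G_NMR` of NGBBs with unassigned active nodes:

    rarity(NGBB) = − p_active⁴ · Π_{i=1..k} p_neighbor,i ∈ [−1, 0]

where `p_active` is the frequency of the active node's amino-acid type
among active nodes of the pool and `p_neighbor,i` the frequency of the
i-th out-neighbour's type among all out-neighbours in the pool. Scores
closer to zero mark rarer patterns — the safest anchors. The pool shrinks
as assignments accumulate and the frequencies are recomputed against the
remaining unassigned NGBBs at every step. Candidate-type sets contribute
fractionally (1/|set| per member type) and a set's probability is its
total frequency mass.

**Similarity** between an NGBB and an SGBB whose active nodes share a
type:

    similarity = 2·c·W_NOE − |c − E_structure| − |c − E_NOE| − penalty

`E_*` are the neighbour counts of the two stars and `c` is the number of
neighbour correspondences. The additional-restraints `penalty` adds, per
configured restraint set i, `W_i · |a_exp − a_theo|` at the two active
nodes; when either value is missing the term falls back to
`10 · W_i · |μ_exp − μ_theo|` against the global means of absolute values
of that set, so that missing restraint data never favours an assignment.
All weights default to 1; the factor 10 is fixed.

**Common edges.** The two stars' neighbours are matched in two stages.
Neighbours whose resonance is already assigned are matched *by identity*:
they contribute 1 iff their methyl is a neighbour of the candidate SGBB.
The remaining neighbours are matched by maximum bipartite matching on
(amino-acid type, direction class) compatibility — equivalent to a
per-category multiset intersection when types are unambiguous. Direction
classes are reciprocal / out-only / in-only; a unidirectional NOE
neighbour may match a reciprocal structural neighbour (a missing return
peak reflects overlap or noise, not structural asymmetry), while an
observed reciprocal NOE requires a reciprocal structural edge. In a
candidate SGBB, unassigned neighbours count as reciprocal (a uniform
trial cut-off is distance-symmetric); assigned neighbours are reciprocal
only if their previously selected cut-off reaches back to the active
methyl, and assigned methyls beyond the trial cut-off whose own cut-off
covers the active methyl enter as in-only neighbours — the partially
built structure graph predicts an NOE the candidate must account for.

**Total score** of a walk is the sum of its step similarity scores.

## The walk engine

One *walk*: the seminal resonance is matched against every unassigned
methyl of its type across the whole cut-off grid; thereafter the engine
repeatedly takes the rarest unassigned resonance NOE-adjacent to the
assigned frontier, restricts candidates to unassigned methyls of the
right type within the grid maximum of an anchor's methyl, and commits the
best-scoring (methyl, cut-off) pair. A step is accepted only if its
similarity score is positive and it has at least 1 common edge (2 for the
seminal step, which carries more risk) — this acceptance floor blocks
zero-evidence assignments, at the price of abstaining on two-node NOE
components. Ties resolve toward the smaller cut-off first (an impostor
can mimic the true star only by inflating its cut-off; the tighter
explanation is the physically more plausible one), then toward the
lexicographically first methyl.

One *cluster*: a walk is tried from every eligible seminal (optionally
only the K rarest — a performance knob justified by the observation that
early clusters dominate the assignment) and the walk with the highest
total score is committed; its members are removed from the pool. Ties go
to the longer walk, then the earlier seminal id. Iterating clusters to
exhaustion yields the **complete protein methyl walk (CPMW)**, covering
every resonance with at least one NOE that survived the floors. Walks may
anchor on pre-assigned pairs and on previously committed clusters.

Confidence comes from three CPMW replicas with increasing cut-off ranges
(3–8, 3–9, 3–10 Å; step 0.2 Å): a resonance assigned to the same methyl
in all three is *safe*, diverging answers are *ambiguous*, never-assigned
resonances are *unassigned*. Under non-stereospecific labelling the two
prochiral methyls of a Leu/Val are NMR-equivalent; replica answers that
split across a geminal pair are flagged `stereo_pair` and reported
ambiguous, and the evaluator counts a safe assignment to the geminal
partner of the true methyl as correct.

When long-range restraints are configured, a **safeguard** examines the
residuals `a_exp − a_theo` over safe assignments per set: residuals more
than `k·σ` (default k = 1) from the mean flag the assignment and demote
it to unassigned; a set with fewer than 3 residuals is skipped, and a
zero spread flags nothing. The full experimental-vs-theoretical
correlation table is written for inspection, and the safeguard can be
disabled for re-runs without restraint data.

## Structural model handling

- The reference point of a methyl is its **carbon** atom: the NOESY
  dimensions are the methyl ¹³C/¹H, and the carbon is rotamer-invariant
  and always present in deposited models.
- Labelling schemes are tokens such as `MILproSVproSAT` or `ILV`: proS
  activates Leu-δ2/Val-γ2, proR activates δ1/γ1, an unsuffixed L/V both.
  Ile contributes δ1 only, Met ε, Ala β, Thr γ2.
- Geminal pairs (Leu δ1/δ2, Val γ1/γ2 under non-stereospecific labelling)
  are not neighbours of each other: their NOE is a trivially present
  contact with no assignment information (configurable).
- Ensembles and apo/holo pairs: every model of every input file is a
  conformer, and by default a pair is within cut-off if it is within
  cut-off in *at least one* conformer (`mode="min"`) — either
  conformation can produce an NOE. `mode="single"` restricts to one.
- Homo-multimers: symmetry-equivalent chains are NMR-indistinguishable,
  so chains are collapsed onto one node per residue identity by default,
  with the neighbour set the union over chains (distance = minimum over
  chain copies). Disable for hetero-complexes with clashing numbering.
- Alternate locations resolve to the highest-occupancy copy; residue
  numbering is taken verbatim from the file.

## Synthetic benchmark

The generator emulates how sparse experimental NOE data relate to a
structure. From a methyl coordinate set it builds the fixed-cut-off
structure graph (7.0 Å default — a mid-grid value consistent with
observable methyl-methyl NOEs), then removes undirected contacts
uniformly at random (without replacement, to a target count drawn from
the interval) until the density — undirected contacts per methyl of the
input set — lands in the target interval, 1.75–2.1 NOEs per methyl by
default, the range of realistic methyl-TROSY datasets. Each surviving
contact becomes a reciprocal edge pair, one direction of which is dropped
with probability 0.2 (cross-peaks observed in only one plane). No
spurious contacts are injected by default; a noise parameter exists but
defaults to 0 since the protocol only removes edges. Ground truth is
retained, and resonance ids are issued in randomized order so they carry
no information.

Coordinate sets are synthetic: residue types are drawn from
globular-protein abundances restricted to the scheme (Met rare, Leu
common) and positions are packed at ≥ 4 Å separation with ~175 ų per
methyl — in a cube (`synth_methyls`) or a sphere (`synth_protein_like`,
the globular stand-in used by the benchmarks), giving roughly 4 contacts
per methyl at 7 Å. Each synthetic residue carries one methyl, so the
generator produces no geminal pairs. What these sets do **not** model:
real secondary-structure clustering of methyls, loop disorder,
model-vs-solution coordinate error, chemical-shift overlap, and spectral
artefacts. Passing benchmarks on them demonstrates the correctness and
discriminative power of the matcher under the stated density and
directionality conditions, not performance on any particular real
protein.

Problem sizes used by the shipped checks: score fidelity on 1,000 random
star pairs against a direct-substitution oracle (agreement to 1e−12);
exhaustive-search equivalence on 50 connected ≤ 8-resonance instances
with a unique type-consistent mapping; noiseless recovery on 20–80-methyl
sets with unique (Weisfeiler–Leman-refined) neighbourhood signatures;
and the density-protocol benchmark on 100-methyl globular sets, three
seeds, which must average ≥ 82% correct among resonances with NOEs.

## Numerical and degenerate-input choices

- Scores are exact rational arithmetic in floating point; comparisons use
  an absolute tolerance of 1e−9 and structure-graph counting uses exact
  big integers.
- Cut-offs that add no new neighbour are skipped during matching (the
  pattern is unchanged), making the grid scan effectively O(neighbours).
- An empty NOE graph yields an empty CPMW; an empty walk list terminates
  the cluster loop; resonances with no NOEs are excluded up front.
- Pre-assignments must be injective and type-consistent; they are never
  reassigned and anchor with the most permissive cut-off (grid maximum).
- Determinism: the walker contains no randomness; generators take a
  mandatory seed; identical inputs and configuration produce
  byte-identical outputs.

## Known limitations

- Greedy, non-backtracking search: on locally degenerate instances whose
  ambiguity is resolved only jointly (circular degeneracies), the engine
  can commit early; the replica mechanism reports such cases as ambiguous
  rather than silently erring, but cannot recover the assignment.
- Theoretical restraints are consumed as input; tensor fitting, loop
  modelling and peak picking are out of scope.
- The safeguard assumes roughly unimodal residuals; systematic
  model-vs-solution differences affecting many methyls shift the mean
  rather than flagging individual outliers.
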