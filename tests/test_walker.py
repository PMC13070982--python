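"""Walk engine: seminal selection, matching, clusters, CPMW, confidence."""

import itertools

import pytest

from methylwalk import (
    CutoffGrid,
    MethylSet,
    NOEGraph,
    RestraintSets,
    make_methyl,
    simulate_noe_network,
    synth_methyls,
    synth_protein_like,
)
from methylwalk.scoring import RarityContext, rarity_score
from methylwalk.walker import (
    AMBIGUOUS,
    SAFE,
    UNASSIGNED,
    AssignmentState,
    ConfidenceReport,
    ResonanceVerdict,
    WalkerConfig,
    apply_preassignments,
    apply_restraint_safeguard,
    best_match,
    classify_confidence,
    run_cluster,
    run_cpmw,
    run_walk,
    select_seminal,
)

from conftest import simple_noe

CFG = WalkerConfig()


def chain_abc_fixture():
    """NOE chain A-B-C with unique types M, L, A and a matching structure."""
    noe = simple_noe(
        [("rA", "rB"), ("rB", "rA"), ("rB", "rC"), ("rC", "rB")],
        {"rA": "M", "rB": "L", "rC": "A"},
    )
    methyls = [
        make_methyl(("M", 1, "CE"), (0, 0, 0)),
        make_methyl(("L", 2, "CD2"), (5, 0, 0)),
        make_methyl(("A", 3, "CB"), (10, 0, 0)),
        make_methyl(("I", 4, "CD1"), (30, 0, 0)),  # decoy, far away
    ]
    return noe, MethylSet(methyls)


# ---------------------------------------------------------------------------
# seminal selection
# ---------------------------------------------------------------------------


def test_select_seminal_single_candidate():
    noe = simple_noe([("a", "b"), ("b", "a")], {"a": "M", "b": "L"})
    ms = MethylSet([make_methyl(("M", 1, "CE"), (0, 0, 0))])
    state = AssignmentState(noe, ms, CutoffGrid())
    assert select_seminal(state).active in ("a", "b")


def test_select_seminal_prefers_rare_type():
    # Met-rooted and Leu-rooted NGBBs with identical neighbourhoods in a
    # Leu-rich graph: the Met one is rarer
    edges, types = [], {}
    types["m"] = "M"
    types["l0"] = "L"
    for i in range(1, 5):
        types[f"l{i}"] = "L"
    edges += [("m", "l1"), ("l0", "l2")]
    noe = simple_noe(edges, types)
    ms = MethylSet([make_methyl(("M", 1, "CE"), (0, 0, 0))])
    state = AssignmentState(noe, ms, CutoffGrid())
    assert select_seminal(state).active == "m"


def test_select_seminal_agrees_with_score_all_oracle(rng):
    ids = [f"p{i:02d}" for i in range(15)]
    types = {i: str(rng.choice(list("MILVAT"))) for i in ids}
    edges = []
    for a, b in itertools.permutations(ids, 2):
        if rng.random() < 0.15:
            edges.append((a, b))
    noe = simple_noe(edges, types)
    ms = MethylSet([make_methyl(("M", 1, "CE"), (0, 0, 0))])
    state = AssignmentState(noe, ms, CutoffGrid())
    picked = select_seminal(state)
    ctx = RarityContext(state.unassigned_ngbbs())
    scored = [
        (rarity_score(state.ngbbs[r], ctx), r)
        for r in ids
        if state.ngbbs[r].neighbours
    ]
    best_score = max(s for s, _ in scored)
    best_ids = sorted(r for s, r in scored if s == pytest.approx(best_score))
    assert picked.active == best_ids[0]


# ---------------------------------------------------------------------------
# best_match
# ---------------------------------------------------------------------------


def test_best_match_perfect_candidate_scores_twice_edges():
    noe, ms = chain_abc_fixture()
    state = AssignmentState(noe, ms, CFG.grid)
    ngbb = state.ngbbs["rB"]  # L with M and A neighbours
    got = best_match(state, ngbb, ["L2-CD2"], CFG, None, seminal=True)
    assert got is not None
    methyl, cutoff, score, c = got
    assert methyl == "L2-CD2"
    assert score == pytest.approx(2 * ngbb.n_edges)
    assert c == 2


def test_best_match_prefers_type_compatible_neighbourhood():
    noe = simple_noe(
        [("x", "y"), ("y", "x")], {"x": "M", "y": "A"}
    )
    methyls = [
        make_methyl(("M", 1, "CE"), (0, 0, 0)),
        make_methyl(("A", 2, "CB"), (5, 0, 0)),
        make_methyl(("M", 3, "CE"), (20, 0, 0)),
        make_methyl(("L", 4, "CD2"), (24, 0, 0)),  # M3's neighbour is L, not A
    ]
    ms = MethylSet(methyls)
    state = AssignmentState(noe, ms, CFG.grid)
    got = best_match(state, state.ngbbs["x"], ["M1-CE", "M3-CE"], CFG, None, seminal=False)
    assert got[0] == "M1-CE"


def test_best_match_equals_exhaustive_scan(rng):
    from methylwalk.scoring import similarity_score_noe_with_c
    from methylwalk.walker import sgbb_pattern

    methyls = synth_methyls(12, seed=7)
    ms = MethylSet(methyls)
    net = simulate_noe_network(ms, target_density=(1e9, 1e9), seed=7, unidirectional_fraction=0.0)
    state = AssignmentState(net.noe, ms, CFG.grid)
    res = sorted(net.truth)[0]
    ngbb = state.ngbbs[res]
    candidates = state.type_compatible_methyls(res)[:5]
    got = best_match(state, ngbb, candidates, CFG, None, seminal=False)
    # exhaustive enumeration over candidates x full grid
    best = None
    for m in candidates:
        for cutoff in CFG.grid:
            pat = sgbb_pattern(state, m, cutoff)
            s, c = similarity_score_noe_with_c(ngbb, pat, 1.0, {})
            if best is None or s > best[2] + 1e-9:
                best = (m, cutoff, s, c)
    if got is None:
        assert best is None or best[2] <= 0 or best[3] < 1
    else:
        assert got[2] == pytest.approx(best[2])


# ---------------------------------------------------------------------------
# walks and clusters
# ---------------------------------------------------------------------------


def test_run_walk_recovers_unique_chain():
    noe, ms = chain_abc_fixture()
    state = AssignmentState(noe, ms, CFG.grid)
    walk = run_walk(state, "rB", CFG)
    assert len(walk.steps) == 3
    assert state.res_to_methyl == {"rA": "M1-CE", "rB": "L2-CD2", "rC": "A3-CB"}
    assert walk.steps[0].seminal and not walk.steps[1].seminal


def test_resonances_without_noes_are_excluded():
    noe = simple_noe([("a", "b"), ("b", "a")], {"a": "M", "b": "L", "lonely": "A"})
    methyls = [
        make_methyl(("M", 1, "CE"), (0, 0, 0)),
        make_methyl(("L", 2, "CD2"), (5, 0, 0)),
        make_methyl(("A", 3, "CB"), (10, 0, 0)),
    ]
    cpmw = run_cpmw(noe, MethylSet(methyls), CFG)
    assert "lonely" not in cpmw.eligible
    assert "lonely" not in cpmw.assignment


def test_run_cluster_picks_best_component_first():
    # two disjoint NOE components; the larger one wins the first iteration
    noe = simple_noe(
        [("a", "b"), ("b", "a"), ("b", "c"), ("c", "b"), ("a", "c"), ("c", "a"),
         ("x", "y"), ("y", "x"), ("y", "z"), ("z", "y")],
        {"a": "M", "b": "L", "c": "A", "x": "I", "y": "T", "z": "V"},
    )
    methyls = [
        make_methyl(("M", 1, "CE"), (0, 0, 0)),
        make_methyl(("L", 2, "CD2"), (5, 0, 0)),
        make_methyl(("A", 3, "CB"), (5, 5, 0)),
        make_methyl(("I", 7, "CD1"), (40, 0, 0)),
        make_methyl(("T", 8, "CG2"), (44, 0, 0)),
        make_methyl(("V", 9, "CG2"), (48, 0, 0)),
        make_methyl(("T", 19, "CG2"), (70, 0, 0)),  # decoy T far from everything
    ]
    ms = MethylSet(methyls)
    state = AssignmentState(noe, ms, CFG.grid)
    c1 = run_cluster(state, CFG)
    assert set(c1.members) == {"a", "b", "c"}
    c2 = run_cluster(state, CFG)
    assert set(c2.members) == {"x", "y", "z"}
    assert run_cluster(state, CFG) is None


def test_cpmw_partition_and_injectivity():
    methyls = synth_methyls(30, seed=11)
    ms = MethylSet(methyls)
    net = simulate_noe_network(ms, seed=11, target_density=(1e9, 1e9), unidirectional_fraction=0.0)
    cpmw = run_cpmw(net.noe, ms, CFG)
    assert sum(cpmw.cluster_sizes) == len(cpmw.assignment)
    # injectivity both ways
    assert len(set(cpmw.assignment.values())) == len(cpmw.assignment)
    # type consistency
    for res, methyl in cpmw.assignment.items():
        assert ms.types[methyl] in net.noe.types(res)
    # every selected cut-off lies on the grid
    for m, cut in cpmw.selected_cutoffs.items():
        assert cut in CFG.grid


def test_first_clusters_carry_most_assignments():
    # greedy-cluster concentration diagnostic: on a connected synthetic
    # network the first few clusters dominate the assignment
    methyls = synth_protein_like(60, seed=21)
    ms = MethylSet(methyls)
    net = simulate_noe_network(ms, seed=21)
    cpmw = run_cpmw(net.noe, ms, CFG)
    sizes = cpmw.cluster_sizes
    assert sum(sizes[:4]) >= 0.75 * sum(sizes)


def test_cpmw_empty_graph():
    cpmw = run_cpmw(NOEGraph(), MethylSet([make_methyl(("M", 1, "CE"), (0, 0, 0))]), CFG)
    assert cpmw.clusters == [] and cpmw.assignment == {}


def test_cpmw_deterministic():
    methyls = synth_methyls(25, seed=5)
    ms = MethylSet(methyls)
    net = simulate_noe_network(ms, seed=5, target_density=(1e9, 1e9))
    a = run_cpmw(net.noe, ms, CFG)
    b = run_cpmw(net.noe, ms, CFG)
    assert a.assignment == b.assignment
    assert a.selected_cutoffs == b.selected_cutoffs
    assert a.cluster_sizes == b.cluster_sizes


# ---------------------------------------------------------------------------
# confidence classification
# ---------------------------------------------------------------------------


def _cpmw_with(assignment, eligible):
    from methylwalk.walker import CPMW

    return CPMW(0, CutoffGrid(), [], assignment, {}, tuple(eligible))


def test_classify_identical_replicas_all_safe():
    cp = _cpmw_with({"a": "M1-CE", "b": "L2-CD2"}, ["a", "b"])
    report = classify_confidence([cp, cp, cp])
    assert all(v.status == SAFE for v in report.verdicts.values())


def test_classify_divergent_answers_ambiguous():
    c1 = _cpmw_with({"a": "L328-CD2"}, ["a"])
    c2 = _cpmw_with({"a": "L328-CD2"}, ["a"])
    c3 = _cpmw_with({"a": "L301-CD2"}, ["a"])
    report = classify_confidence([c1, c2, c3])
    assert report.verdicts["a"].status == AMBIGUOUS
    assert report.verdicts["a"].answers == ("L328-CD2", "L328-CD2", "L301-CD2")


def test_classify_never_assigned_is_unassigned():
    cp = _cpmw_with({}, ["a"])
    report = classify_confidence([cp, cp, cp])
    assert report.verdicts["a"].status == UNASSIGNED


def test_classify_requires_three_replicas():
    cp = _cpmw_with({}, ["a"])
    with pytest.raises(ValueError, match="3 replicas"):
        classify_confidence([cp, cp])


def test_classify_flags_geminal_split_under_nonstereo():
    leu = [
        make_methyl(("L", 7, "CD1"), (0, 0, 0)),
        make_methyl(("L", 7, "CD2"), (1.5, 0, 0)),
    ]
    ms = MethylSet(leu)
    c1 = _cpmw_with({"a": "L7-CD1"}, ["a"])
    c2 = _cpmw_with({"a": "L7-CD2"}, ["a"])
    report = classify_confidence([c1, c1, c2], ms, nonstereo_types=frozenset("L"))
    v = report.verdicts["a"]
    assert v.status == AMBIGUOUS and "stereo_pair" in v.flags


# ---------------------------------------------------------------------------
# restraint safeguard
# ---------------------------------------------------------------------------


def _report_from(assignment):
    return ConfidenceReport(
        {r: ResonanceVerdict(SAFE, m, (m, m, m)) for r, m in assignment.items()}
    )


def test_safeguard_no_flags_when_residuals_equal():
    assignment = {f"r{i}": f"M{i}-CE" for i in range(5)}
    rs = RestraintSets(
        exp={r: {1: 0.30} for r in assignment},
        theo={m: {1: 0.10} for m in assignment.values()},
    )
    report = _report_from(assignment)
    result = apply_restraint_safeguard(report, rs)
    assert result.flagged == {}
    assert all(v.status == SAFE for v in report.verdicts.values())


def test_safeguard_flags_planted_outlier(rng):
    assignment = {f"r{i:02d}": f"M{i:02d}-CE" for i in range(11)}
    exp, theo = {}, {}
    for i, (r, m) in enumerate(sorted(assignment.items())):
        theo[m] = {1: float(rng.normal(0, 0.3))}
        noise = 0.5 if i == 4 else float(rng.normal(0, 0.01))
        exp[r] = {1: theo[m][1] + noise}
    report = _report_from(assignment)
    result = apply_restraint_safeguard(report, RestraintSets(exp=exp, theo=theo))
    outlier = sorted(assignment)[4]
    assert outlier in result.flagged
    assert report.verdicts[outlier].status == UNASSIGNED
    assert "safeguard_set_1" in report.verdicts[outlier].flags


def test_safeguard_skipped_below_three_pairs():
    assignment = {"r1": "M1-CE", "r2": "M2-CE"}
    rs = RestraintSets(
        exp={"r1": {1: 0.3}, "r2": {1: 0.1}},
        theo={"M1-CE": {1: 0.3}, "M2-CE": {1: 0.1}},
    )
    report = _report_from(assignment)
    with pytest.warns(UserWarning, match="safeguard skipped"):
        result = apply_restraint_safeguard(report, rs)
    assert result.summary == [] and result.flagged == {}


def test_safeguard_correlation_table_shape():
    assignment = {f"r{i}": f"M{i}-CE" for i in range(4)}
    rs = RestraintSets(
        exp={r: {1: 0.1 * i} for i, r in enumerate(sorted(assignment))},
        theo={m: {1: 0.1 * i} for i, m in enumerate(sorted(assignment.values()))},
    )
    result = apply_restraint_safeguard(_report_from(assignment), rs)
    assert len(result.correlation) == 4
    assert {row["set"] for row in result.correlation} == {1}


# ---------------------------------------------------------------------------
# pre-assignments
# ---------------------------------------------------------------------------


def test_preassignments_empty_noop():
    noe, ms = chain_abc_fixture()
    state = AssignmentState(noe, ms, CFG.grid)
    apply_preassignments({}, state)
    assert state.res_to_methyl == {}


def test_preassignment_anchors_walk_and_agrees_with_truth():
    noe, ms = chain_abc_fixture()
    cpmw = run_cpmw(noe, ms, CFG, preassignments={"rA": "M1-CE"})
    assert cpmw.assignment == {"rA": "M1-CE", "rB": "L2-CD2", "rC": "A3-CB"}


def test_preassignment_contract_violations_rejected():
    noe, ms = chain_abc_fixture()
    state = AssignmentState(noe, ms, CFG.grid)
    with pytest.raises(ValueError, match="type-inconsistent"):
        apply_preassignments({"rA": "L2-CD2"}, state)
    with pytest.raises(ValueError, match="duplicate or conflicting"):
        apply_preassignments([("rA", "M1-CE"), ("rB", "M1-CE")], state)
    with pytest.raises(ValueError, match="not in the NOE graph"):
        apply_preassignments({"nope": "M1-CE"}, state)
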