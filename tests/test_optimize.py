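import math

import numpy as np
import pytest

from cea import (
    ActiveGeneSet,
    AnnotationDB,
    CEAConfig,
    NothingToCoverError,
    combination_pvalue,
    filter_solutions,
    greedy_run,
    landscape_table,
    pareto_front,
    run_cea,
    solve_escp_exact,
)
from cea.optimize import GreedyState, SolutionSet, cost_effectiveness, element_weight, set_weight
from cea.simulate import random_small_instance


def test_element_weight(worked_db):
    assert element_weight("g7", worked_db) == 1.0   # only in TC
    assert element_weight("g6", worked_db) == 0.5   # in TB and TC
    with pytest.raises(ValueError):
        element_weight("unannotated", worked_db)


def test_set_weight(worked_db, worked_ag):
    assert set_weight("TA", worked_ag, worked_db) == 0.0        # fully active
    assert set_weight("TC", worked_ag, worked_db) == 1.5        # g6 (1/2) + g7 (1)
    assert set_weight("TD", worked_ag, worked_db) == 2.0        # g8 + g9
    # active members never contribute
    assert set_weight("TE", worked_ag, worked_db) == 1.0        # g10 only


def test_cost_effectiveness(worked_db, worked_ag):
    state = GreedyState()
    assert cost_effectiveness("TC", state, worked_ag, worked_db) == pytest.approx(0.75)
    assert cost_effectiveness("TA", state, worked_ag, worked_db) == 0.0
    state.covered = {"g2", "g3", "g1"}
    assert cost_effectiveness("TE", state, worked_ag, worked_db) == math.inf


def test_deterministic_greedy_worked_path(worked_db, worked_ag):
    """d=0 reproduces the hand-traced greedy path regardless of the seed."""
    expected = [("TA",), ("TA", "TB"), ("TA", "TB", "TC")]
    for seed in range(10):
        path = greedy_run(worked_ag, worked_db, d=0.0, rng=seed)
        assert [p.members for p in path] == expected
    # hand-checked statistics of the first prefix: S=3, t=3, p = P(X>=3) = 1/12
    first = path[0]
    assert (first.union_size, first.active_overlap) == (3, 3)
    assert first.coverage == pytest.approx(0.6)


def test_disjoint_tiling_reaches_zero_objective():
    db = AnnotationDB(
        {"A": {"g1", "g2"}, "B": {"g3", "g4"}, "C": {"g5", "g6"}},
        universe=[f"g{i}" for i in range(1, 7)],
    )
    ag = ActiveGeneSet(active=frozenset(db.universe), inactive=frozenset())
    path = greedy_run(ag, db, d=1.0, rng=0)
    assert len(path) == 3
    assert path[-1].coverage == 1.0
    assert path[-1].objective == 0


def test_greedy_requires_overlap(worked_db):
    ag = ActiveGeneSet.from_genes({"g10"}, worked_db)  # g10 only in TE, which overlaps
    # choose an active set no term overlaps
    db = AnnotationDB({"A": {"g1"}}, universe=["g1", "g2"])
    lone = ActiveGeneSet.from_genes({"g2"}, db)
    with pytest.raises(NothingToCoverError):
        greedy_run(lone, db, d=0.0, rng=0)


def test_coverage_strictly_increases_along_path(worked_db, worked_ag):
    for seed in range(5):
        path = greedy_run(worked_ag, worked_db, d=1.0, rng=seed)
        overlaps = [p.active_overlap for p in path]
        assert all(b > a for a, b in zip(overlaps, overlaps[1:]))


def test_run_cea_deterministic_and_t1_matches_single_path(worked_db, worked_ag):
    cfg = CEAConfig(d=0.0, T=1, seed=42)
    sols = run_cea(worked_ag, worked_db, cfg)
    assert [s.members for s in sols] == [("TA",), ("TA", "TB"), ("TA", "TB", "TC")]

    a = run_cea(worked_ag, worked_db, CEAConfig(d=1.0, T=30, seed=7))
    b = run_cea(worked_ag, worked_db, CEAConfig(d=1.0, T=30, seed=7))
    assert [s.members for s in a] == [s.members for s in b]
    assert a.provenance == b.provenance


def test_cached_statistics_match_recomputation(worked_db, worked_ag):
    sols = run_cea(worked_ag, worked_db, CEAConfig(d=1.0, T=50, seed=3))
    for s in sols:
        res = combination_pvalue(s.members, worked_ag, worked_db)
        assert s.union_size == res.annotated
        assert s.active_overlap == res.overlap
        assert s.p_value == res.p_value
        assert s.neg_log10_p == res.neg_log10_p


def test_max_coverage_early_stop(worked_db, worked_ag):
    path = greedy_run(worked_ag, worked_db, d=0.0, rng=0, max_coverage=0.6)
    assert len(path) == 1 and path[0].coverage >= 0.6


def test_pareto_front_basics(worked_db, worked_ag):
    sols = run_cea(worked_ag, worked_db, CEAConfig(d=1.0, T=100, seed=0))
    front = pareto_front(sols)
    overlaps = [s.active_overlap for s in front]
    assert overlaps == sorted(overlaps)
    # no front point dominates another
    for a in front:
        for b in front:
            if a is not b:
                assert not (
                    a.active_overlap >= b.active_overlap
                    and a.objective <= b.objective
                    and (a.active_overlap > b.active_overlap or a.objective < b.objective)
                )
    # every pooled solution is dominated by or equal to some front point
    for s in sols:
        assert any(
            f.active_overlap >= s.active_overlap and f.objective <= s.objective for f in front
        )


def test_pareto_keeps_smaller_objective_at_equal_overlap(worked_db, worked_ag):
    sols = run_cea(worked_ag, worked_db, CEAConfig(d=1.0, T=100, seed=0))
    by_t = {}
    for s in sols:
        by_t.setdefault(s.active_overlap, []).append(s)
    front = {s.active_overlap: s for s in pareto_front(sols)}
    for t, group in by_t.items():
        if t in front:
            assert front[t].objective == min(g.objective for g in group)


def test_filter_solutions(worked_db, worked_ag):
    sols = run_cea(worked_ag, worked_db, CEAConfig(d=1.0, T=100, seed=0))
    with pytest.raises(ValueError):
        filter_solutions(sols)
    assert len(filter_solutions(sols, p_max=0.0)) == 0
    assert len(filter_solutions(sols, min_coverage=0.0)) == len(sols)
    sized = filter_solutions(sols, size=2)
    assert all(s.size == 2 for s in sized)
    ps = [s.p_value for s in sized]
    assert ps == sorted(ps)


def test_landscape_table(worked_db, worked_ag):
    sols = run_cea(worked_ag, worked_db, CEAConfig(d=1.0, T=50, seed=1))
    df = landscape_table(sols)
    assert len(df) == len(sols)
    assert ((df["coverage"] >= 0) & (df["coverage"] <= 1)).all()
    row = df[df["terms"] == "TA"].iloc[0]
    assert row["neg_log10_p"] == pytest.approx(-math.log10(1 / 12))


def test_greedy_final_objective_bounded_by_exact_optimum():
    """On small instances the greedy end point can never beat the oracle."""
    for seed in range(5):
        db, ag = random_small_instance(seed, n_terms=8, n_active=6)
        path = greedy_run(ag, db, d=1.0, rng=seed)
        final = path[-1]
        exact = solve_escp_exact(ag, db, min_overlap=final.active_overlap)
        assert final.objective >= exact.objective


def test_solution_set_dedup():
    ss = SolutionSet()
    from cea import TermCombination

    c = TermCombination(("A",), 2, 1, 0.5, 0.4, 0.39794)
    ss.add(c, repeat=0, step=1)
    ss.add(c, repeat=3, step=2)
    assert len(ss) == 1
    assert ss.provenance[("A",)] == (0, 1)
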