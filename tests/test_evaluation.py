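import numpy as np
import pandas as pd
import pytest

from cea import (
    AnnotationDB,
    ass_score,
    average_similarity,
    background_distribution,
    similarity_matrix,
    specificity_summary,
    term_level,
    term_similarity,
)


def test_wang_self_similarity(toy_dag):
    for t in toy_dag.nodes:
        assert term_similarity(t, t, dag=toy_dag) == 1.0


def test_wang_hand_computed_values(toy_dag):
    # d and e share only the root: S-values 1, 0.8, 0.64 down each chain,
    # shared part 2*0.64 over total 2*2.44
    assert term_similarity("d", "e", dag=toy_dag) == pytest.approx(16 / 61)
    # parent-child pair: shared {b, a} -> (1 + 0.8) + (0.8 + 0.64) over 1.8 + 2.44
    assert term_similarity("b", "d", dag=toy_dag) == pytest.approx(3.24 / 4.24)
    # symmetry
    assert term_similarity("d", "b", dag=toy_dag) == term_similarity("b", "d", dag=toy_dag)


def test_wang_requires_dag_membership(toy_dag):
    with pytest.raises(KeyError):
        term_similarity("a", "zz", dag=toy_dag)


def test_jaccard_similarity(tiny_db):
    assert term_similarity("A", "B", db=tiny_db, method="jaccard") == pytest.approx(1 / 3)
    db = AnnotationDB({"A": {"g1"}, "B": {"g2"}})
    assert term_similarity("A", "B", db=db, method="jaccard") == 0.0


def test_similarity_matrix_properties(toy_dag):
    sim = similarity_matrix(["b", "c", "d", "e"], dag=toy_dag)
    v = sim.to_numpy()
    assert np.allclose(v, v.T)
    assert np.allclose(np.diag(v), 1.0)
    assert ((v >= 0) & (v <= 1)).all()


def test_average_similarity_is_pair_mean():
    sim = pd.DataFrame(
        [[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]],
        index=list("abc"),
        columns=list("abc"),
    )
    assert average_similarity(["a", "b", "c"], sim) == pytest.approx(0.4)
    assert average_similarity(["a", "b"], sim) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        average_similarity(["a"], sim)


def test_ass_score_matches_matrix_route(toy_dag):
    terms = ["b", "c", "d", "e"]
    sim = similarity_matrix(terms, dag=toy_dag)
    assert ass_score(terms, dag=toy_dag) == pytest.approx(average_similarity(terms, sim))


def test_ass_parent_child_more_redundant_than_distant(toy_dag):
    assert ass_score(["b", "d"], dag=toy_dag) > ass_score(["d", "e"], dag=toy_dag)


def test_background_determinism_and_degenerate_pool(toy_dag):
    db = AnnotationDB({t: {f"g_{t}"} for t in ["b", "c", "d", "e"]})
    b1 = background_distribution(2, db, dag=toy_dag, reps=30, seed=5)
    b2 = background_distribution(2, db, dag=toy_dag, reps=30, seed=5)
    assert np.array_equal(b1.draws, b2.draws)
    assert len(b1.draws) == 30
    # degenerate pool: disjoint single-gene terms under jaccard all score 0
    flat = background_distribution(3, db, reps=10, seed=0, method="jaccard")
    assert np.all(flat.draws == 0.0)
    with pytest.raises(ValueError):
        background_distribution(9, db, dag=toy_dag, reps=5, seed=0)


def test_background_percentile(toy_dag):
    db = AnnotationDB({t: {f"g_{t}"} for t in ["b", "c", "d", "e"]})
    bg = background_distribution(2, db, dag=toy_dag, reps=100, seed=1)
    assert bg.percentile(1.1) == 1.0
    assert bg.percentile(-0.1) == 0.0


def test_term_level(toy_dag, diamond_dag):
    assert term_level(toy_dag.root, toy_dag) == 0
    assert term_level("d", toy_dag) == 2
    assert term_level("x", diamond_dag) == 2  # longest route through the diamond


def test_specificity_summary(toy_dag):
    db = AnnotationDB(
        {"b": {"g1", "g2", "g3"}, "c": {"g1"}, "d": {"g2"}, "e": {"g1", "g4"}},
    )
    per_term, summary = specificity_summary(["b", "c", "d", "e"], db=db, dag=toy_dag)
    assert per_term.loc["b", "n_genes"] == 3
    assert per_term.loc["d", "level"] == 2
    # order invariance
    pt2, _ = specificity_summary(["e", "d", "c", "b"], db=db, dag=toy_dag)
    assert per_term.sort_index().equals(pt2.sort_index())
    # five-number summary median against direct recomputation
    assert summary.loc["median", "n_genes"] == np.median(per_term["n_genes"])
    assert summary.loc["min", "level"] == 1 and summary.loc["max", "level"] == 2
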