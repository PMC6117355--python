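import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cea import (
    ActiveGeneSet,
    combination_pvalue,
    composite_gene_set,
    coverage,
    hypergeom_tail_p,
    single_term_scan,
)
from cea.stats import write_scan_tsv


def exact_tail(k, K, n, N) -> Fraction:
    """Exhaustive pmf summation with exact rational arithmetic."""
    return Fraction(
        sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
            if n - j <= N - K),
        comb(N, n),
    )


@pytest.mark.parametrize(
    "k,K,n,N,expected",
    [
        (0, 3, 4, 10, 1.0),
        (5, 5, 5, 10, 1 / comb(10, 5)),                      # 1/252
        (2, 3, 4, 10, (comb(3, 2) * comb(7, 2) + comb(3, 3) * comb(7, 1)) / comb(10, 4)),
    ],
)
def test_hypergeom_known_values(k, K, n, N, expected):
    assert hypergeom_tail_p(k, K, n, N) == pytest.approx(expected, rel=1e-12)


def test_hypergeom_bounds_errors():
    with pytest.raises(ValueError):
        hypergeom_tail_p(4, 3, 5, 10)  # k > K
    with pytest.raises(ValueError):
        hypergeom_tail_p(1, 11, 5, 10)  # K > N
    with pytest.raises(ValueError):
        hypergeom_tail_p(-1, 3, 5, 10)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_hypergeom_matches_exact_rational_oracle(data):
    N = data.draw(st.integers(1, 60))
    K = data.draw(st.integers(0, N))
    n = data.draw(st.integers(0, N))
    k = data.draw(st.integers(0, min(K, n)))
    expected = float(exact_tail(k, K, n, N))
    assert hypergeom_tail_p(k, K, n, N) == pytest.approx(expected, rel=1e-10)


def test_composite_gene_set(tiny_db):
    assert composite_gene_set(["A"], tiny_db) == {"g1", "g2"}
    assert composite_gene_set(["A", "B"], tiny_db) == {"g1", "g2", "g3"}
    assert composite_gene_set(["A", "A"], tiny_db) == composite_gene_set(["A"], tiny_db)
    with pytest.raises(KeyError, match="zz"):
        composite_gene_set(["zz"], tiny_db)
    with pytest.raises(ValueError):
        composite_gene_set([], tiny_db)


def test_combination_pvalue_cases(worked_db, worked_ag):
    # singleton equals the single-term test exactly
    scan = single_term_scan(worked_ag, worked_db).set_index("term_id")
    for tid in worked_db.term_ids:
        res = combination_pvalue([tid], worked_ag, worked_db)
        assert res.p_value == scan.loc[tid, "p"]
    # permutation invariance
    a = combination_pvalue(["TA", "TC", "TB"], worked_ag, worked_db)
    b = combination_pvalue(["TB", "TA", "TC"], worked_ag, worked_db)
    assert a == b
    # adding a term with no new genes leaves the result unchanged (TE adds g10)
    # composite exactly equal to U_G in a balanced universe: point-mass p
    db = __import__("cea").AnnotationDB({"X": {"a", "b", "c"}}, universe=["a", "b", "c", "d", "e", "f"])
    ag = ActiveGeneSet.from_genes({"a", "b", "c"}, db)
    res = combination_pvalue(["X"], ag, db)
    assert res.p_value == pytest.approx(1 / comb(6, 3), rel=1e-12)


def test_combination_disjoint_from_active_gives_p_one(worked_db):
    ag = ActiveGeneSet.from_genes({"g7", "g8"}, worked_db)
    res = combination_pvalue(["TA"], ag, worked_db)
    assert res.overlap == 0 and res.p_value == 1.0


def test_coverage(worked_db, worked_ag):
    assert coverage([], worked_ag, worked_db) == 0.0
    assert coverage(["TA"], worked_ag, worked_db) == pytest.approx(0.6)
    assert coverage(["TA", "TB", "TC"], worked_ag, worked_db) == 1.0
    # monotone non-decreasing under superset
    assert coverage(["TA", "TD"], worked_ag, worked_db) >= coverage(["TA"], worked_ag, worked_db)


def bh_by_hand(pvals):
    """Benjamini-Hochberg step-up, written independently of statsmodels."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj


def test_single_term_scan_ranks_and_bh(worked_db, worked_ag):
    df = single_term_scan(worked_ag, worked_db)
    assert list(df.columns) == ["term_id", "name", "k", "K", "n", "N", "p", "p_adj", "rank"]
    assert df["p"].is_monotonic_increasing
    # BH recomputed by hand on the 5-term fixture
    raw = df.set_index("term_id")["p"]
    expected = bh_by_hand(list(raw))
    assert np.allclose(df.set_index("term_id")["p_adj"].to_numpy(), expected)


def test_scan_tied_terms_share_minimum_rank():
    from cea import AnnotationDB

    db = AnnotationDB({"P": {"g1", "g6"}, "Q": {"g2", "g7"}, "R": {"g8", "g9"}},
                      universe=[f"g{i}" for i in range(1, 10)])
    ag = ActiveGeneSet.from_genes({"g1", "g2"}, db)
    df = single_term_scan(ag, db).set_index("term_id")
    assert df.loc["P", "p"] == df.loc["Q", "p"]  # identical (k=1, K=2) tables
    assert df.loc["P", "rank"] == df.loc["Q", "rank"] == 1
    assert df.loc["R", "rank"] == 3  # competition ranking skips the tie block


def test_scan_tsv_writer(tmp_path, worked_db, worked_ag):
    df = single_term_scan(worked_ag, worked_db)
    out = tmp_path / "scan.tsv"
    write_scan_tsv(df, out)
    header = out.read_text().splitlines()[0].split("\t")
    assert header == ["term_id", "name", "k", "K", "n", "N", "p", "p_adj", "rank"]


def test_active_gene_set_validation(tiny_db):
    with pytest.raises(ValueError):
        ActiveGeneSet(active=frozenset({"g1"}), inactive=frozenset({"g1", "g2"}))
    with pytest.raises(ValueError):
        ActiveGeneSet.from_genes({"nope"}, tiny_db)
    ag = ActiveGeneSet.from_genes({"g1", "nope"}, tiny_db)  # dropped silently
    assert ag.active == {"g1"}
    with pytest.raises(ValueError, match="outside"):
        ActiveGeneSet.from_genes({"g1", "nope"}, tiny_db, on_unknown="error")
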