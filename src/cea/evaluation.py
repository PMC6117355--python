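"""Redundancy and specificity metrics for identified term sets.

A good combination-based enrichment result should be *non-redundant*: its
terms should not be semantically close relatives of one another.  Redundancy
is quantified by the averaged semantic similarity score

    ASS(S) = C(n,2)^-1 * sum_{i<j} score(S_i, S_j),

the mean pairwise similarity of the ``n`` reported terms, compared against a
background distribution of ASS values for random term sets of the same size
drawn from the whole candidate pool.  Two pairwise scores are provided:

* ``wang`` — the graph-based measure of Wang et al. (2007): each ancestor
  ``t`` of a term ``A`` receives an S-value ``S_A(A) = 1``,
  ``S_A(t) = max over children c of w * S_A(c)`` with is_a contribution
  weight ``w = 0.8``; the similarity of A and B is the sum of S-values over
  their shared ancestors divided by the sum over all their ancestors.
* ``jaccard`` — DAG-free overlap of the annotated gene sets.

Specificity is summarized by the annotated-gene count and the ontology
level (longest is_a path to the root, root = 0) of each term.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .annotations import AnnotationDB
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "WANG_ISA_WEIGHT",
    "term_similarity",
    "similarity_matrix",
    "average_similarity",
    "ass_score",
    "BackgroundDistribution",
    "background_distribution",
    "term_level",
    "specificity_summary",
]

WANG_ISA_WEIGHT = 0.8


def _wang_svalues(term: str, dag: OntologyDAG, weight: float) -> tuple[dict[str, float], float]:
    """S-values of ``term`` over its ancestor closure (including itself)."""
    cached = dag._wang_cache.get((term, weight))
    if cached is not None:
        return cached
    closure = dag.ancestors(term) | {term}
    sub = dag.graph.subgraph(closure)
    sv = {term: 1.0}
    for node in nx.topological_sort(sub):  # children before parents
        base = sv.get(node)
        if base is None:
            continue
        for parent in sub.successors(node):
            cand = weight * base
            if cand > sv.get(parent, 0.0):
                sv[parent] = cand
    total = sum(sv.values())
    dag._wang_cache[(term, weight)] = (sv, total)
    return sv, total


def term_similarity(
    a: str,
    b: str,
    dag: OntologyDAG | None = None,
    db: AnnotationDB | None = None,
    method: str = "wang",
) -> float:
    """Pairwise semantic similarity of two terms, in [0, 1]."""
    if method == "wang":
        if dag is None:
            raise ValueError("wang similarity requires an ontology DAG")
        if a not in dag or b not in dag:
            missing = a if a not in dag else b
            raise KeyError(f"term {missing!r} not in ontology")
        if a == b:
            return 1.0
        sva, tota = _wang_svalues(a, dag, WANG_ISA_WEIGHT)
        svb, totb = _wang_svalues(b, dag, WANG_ISA_WEIGHT)
        common = sva.keys() & svb.keys()
        if not common:
            return 0.0
        return sum(sva[t] + svb[t] for t in common) / (tota + totb)
    if method == "jaccard":
        if db is None:
            raise ValueError("jaccard similarity requires an annotation database")
        ga, gb = db.term_genes(a), db.term_genes(b)
        return len(ga & gb) / len(ga | gb)
    raise ValueError(f"unknown similarity method {method!r}")


def similarity_matrix(
    terms: Iterable[str],
    dag: OntologyDAG | None = None,
    db: AnnotationDB | None = None,
    method: str = "wang",
) -> pd.DataFrame:
    """Symmetric pairwise similarity matrix as a labelled DataFrame."""
    ids = list(dict.fromkeys(terms))
    n = len(ids)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = term_similarity(ids[i], ids[j], dag=dag, db=db, method=method)
            values[i, j] = values[j, i] = s
    return pd.DataFrame(values, index=ids, columns=ids)


def average_similarity(terms: Iterable[str], sim: pd.DataFrame) -> float:
    """ASS of ``terms``: mean of the C(n,2) pairwise scores taken from ``sim``."""
    ids = list(dict.fromkeys(terms))
    n = len(ids)
    if n < 2:
        raise ValueError("ASS needs at least two terms")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += float(sim.loc[ids[i], ids[j]])
    return total / (n * (n - 1) / 2)


def ass_score(
    terms: Iterable[str],
    dag: OntologyDAG | None = None,
    db: AnnotationDB | None = None,
    method: str = "wang",
    _cache: dict[frozenset[str], float] | None = None,
) -> float:
    """ASS computed directly from pairwise similarities.

    With ``method='wang'``, terms absent from the DAG are dropped with a
    logged count rather than scored 0; at least two terms must remain.
    """
    ids = list(dict.fromkeys(terms))
    if method == "wang" and dag is not None:
        kept = [t for t in ids if t in dag]
        if len(kept) < len(ids):
            logger.warning("ASS: dropped %d terms absent from the ontology", len(ids) - len(kept))
        ids = kept
    n = len(ids)
    if n < 2:
        raise ValueError("ASS needs at least two usable terms")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if _cache is not None:
                key = frozenset((ids[i], ids[j]))
                s = _cache.get(key)
                if s is None:
                    s = term_similarity(ids[i], ids[j], dag=dag, db=db, method=method)
                    _cache[key] = s
            else:
                s = term_similarity(ids[i], ids[j], dag=dag, db=db, method=method)
            total += s
    return total / (n * (n - 1) / 2)


@dataclass(frozen=True)
class BackgroundDistribution:
    """Null ASS values for random term sets of a fixed size."""

    draws: np.ndarray
    n_terms: int
    reps: int
    seed: int
    method: str

    def mean(self) -> float:
        return float(self.draws.mean())

    def percentile(self, ass: float) -> float:
        """Empirical CDF value: fraction of background draws <= ``ass``."""
        return float((self.draws <= ass).mean())


def background_distribution(
    n_terms: int,
    db: AnnotationDB,
    dag: OntologyDAG | None = None,
    reps: int = 100_000,
    seed: int = 0,
    method: str = "wang",
) -> BackgroundDistribution:
    """ASS distribution of ``reps`` random term sets of size ``n_terms``.

    Each draw samples ``n_terms`` terms uniformly without replacement from
    the full candidate pool (all database terms, intersected with the
    ontology for the wang measure) — not only from identified terms.
    Deterministic given ``seed``.  Pairwise similarities are cached across
    draws, which keeps the default 100,000 repetitions tractable.
    """
    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    pool = list(db.term_ids)
    if method == "wang":
        if dag is None:
            raise ValueError("wang background requires an ontology DAG")
        pool = [t for t in pool if t in dag]
    if n_terms > len(pool):
        raise ValueError(f"n_terms={n_terms} exceeds the candidate pool ({len(pool)} terms)")
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool, dtype=object)
    cache: dict[frozenset[str], float] = {}
    draws = np.empty(reps)
    for r in range(reps):
        sample = rng.choice(pool_arr, size=n_terms, replace=False)
        draws[r] = ass_score(sample.tolist(), dag=dag, db=db, method=method, _cache=cache)
    return BackgroundDistribution(draws=draws, n_terms=n_terms, reps=reps, seed=seed, method=method)


def term_level(term_id: str, dag: OntologyDAG) -> int:
    """Longest is_a path length from ``term_id`` up to the root (root = 0)."""
    return dag.level(term_id)


def specificity_summary(
    terms: Iterable[str],
    db: AnnotationDB | None = None,
    dag: OntologyDAG | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotated-gene counts and ontology levels, plus five-number summaries.

    Returns ``(per_term, summary)``: ``per_term`` has one row per term with
    ``n_genes`` and/or ``level`` columns (depending on which of ``db`` /
    ``dag`` is given); ``summary`` holds min, q1, median, q3, max per column,
    ready for boxplot reproduction.
    """
    ids = list(dict.fromkeys(terms))
    if not ids:
        raise ValueError("no terms given")
    if db is None and dag is None:
        raise ValueError("need an annotation database and/or an ontology")
    data: dict[str, list] = {"term_id": ids}
    if db is not None:
        data["n_genes"] = [len(db.term_genes(t)) for t in ids]
    if dag is not None:
        data["level"] = [dag.level(t) for t in ids]
    per_term = pd.DataFrame(data).set_index("term_id")
    summary = per_term.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
    summary.index = ["min", "q1", "median", "q3", "max"]
    return per_term, summary
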