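"""Scikit-learn-style estimator interfaces.

``CEA`` is fit-shaped the way a clusterer is: parameters at construction,
``fit(X)`` on an active gene list, results in trailing-underscore
attributes.  Both estimators are plain ``BaseEstimator`` subclasses, so
``get_params`` / ``set_params`` / ``clone`` and pipeline composition work.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .annotations import AnnotationDB
from .optimize import (
    CEAConfig,
    SolutionSet,
    TermCombination,
    filter_solutions,
    landscape_table,
    pareto_front,
    run_cea,
)
from .stats import ActiveGeneSet, single_term_scan

__all__ = ["CEA", "SingleTermEnrichment"]


def _as_active(X, annotations: AnnotationDB) -> ActiveGeneSet:
    if isinstance(X, ActiveGeneSet):
        return X
    if isinstance(X, str):
        raise TypeError("X must be an iterable of gene ids, not a single string")
    return ActiveGeneSet.from_genes(X, annotations)


class CEA(BaseEstimator):
    """Combination-based enrichment analysis via randomized greedy set cover.

    Parameters
    ----------
    annotations:
        The :class:`~cea.annotations.AnnotationDB` to search over.
    d:
        Randomization width: each step samples uniformly among terms whose
        cost-effectiveness is within ``(1 + d)`` times the minimum.  ``d=0``
        is deterministic greedy.
    T:
        Number of independent greedy restarts whose prefix paths are pooled.
    max_coverage:
        Optional early stop once this fraction of active genes is covered.
    random_state:
        Master seed; results are a pure function of it.

    Attributes
    ----------
    active_ : ActiveGeneSet
        The bound active/inactive partition of the universe.
    solutions_ : SolutionSet
        Pooled, deduplicated term combinations from all restarts.
    n_solutions_ : int
    """

    def __init__(
        self,
        annotations: AnnotationDB | None = None,
        d: float = 1.0,
        T: int = 500,
        max_coverage: float = 1.0,
        random_state: int = 0,
    ) -> None:
        self.annotations = annotations
        self.d = d
        self.T = T
        self.max_coverage = max_coverage
        self.random_state = random_state

    def fit(self, X: Iterable[str] | ActiveGeneSet, y=None) -> "CEA":
        """Run the search on an active gene list ``X`` (iterable of gene ids)."""
        if not isinstance(self.annotations, AnnotationDB):
            raise ValueError("annotations must be an AnnotationDB")
        self.active_ = _as_active(X, self.annotations)
        cfg = CEAConfig(
            d=self.d, T=self.T, seed=self.random_state, max_coverage=self.max_coverage
        )
        self.solutions_ = run_cea(self.active_, self.annotations, cfg)
        self.n_solutions_ = len(self.solutions_)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "solutions_"):
            raise NotFittedError("call fit before querying results")

    def filter(
        self,
        size: int | None = None,
        p_max: float | None = None,
        min_coverage: float | None = None,
    ) -> SolutionSet:
        self._check_fitted()
        return filter_solutions(self.solutions_, size=size, p_max=p_max, min_coverage=min_coverage)

    def pareto_front(self) -> list[TermCombination]:
        self._check_fitted()
        return pareto_front(self.solutions_)

    def landscape(self) -> pd.DataFrame:
        self._check_fitted()
        return landscape_table(self.solutions_)

    def best(self, size: int | None = None) -> TermCombination:
        self._check_fitted()
        return self.solutions_.best(size=size)


class SingleTermEnrichment(BaseEstimator):
    """One-term-at-a-time Fisher's exact over-representation scan.

    After ``fit(X)``, ``results_`` holds the ranked table (ascending p) with
    Benjamini-Hochberg adjusted p-values and shared-minimum ranks.
    """

    def __init__(self, annotations: AnnotationDB | None = None) -> None:
        self.annotations = annotations

    def fit(self, X: Iterable[str] | ActiveGeneSet, y=None) -> "SingleTermEnrichment":
        if not isinstance(self.annotations, AnnotationDB):
            raise ValueError("annotations must be an AnnotationDB")
        self.active_ = _as_active(X, self.annotations)
        self.results_ = single_term_scan(self.active_, self.annotations)
        return self

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        if not hasattr(self, "results_"):
            raise NotFittedError("call fit before querying results")
        return self.results_[self.results_["p_adj"] <= fdr].reset_index(drop=True)
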