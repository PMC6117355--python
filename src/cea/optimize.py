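"""Randomized greedy search for enriched term combinations.

The search treats enrichment as a weighted set-cover trade-off.  For a
combination ``X`` let ``S(X)`` be the number of genes its composite term
annotates and ``t(X)`` the number of those that are active.  A good
combination simultaneously maximizes ``t(X)`` and minimizes the penalty
``S(X) - t(X)`` (annotated-but-inactive genes); these conflict, so the
solutions of interest form a Pareto front indexed by coverage.

Each greedy step scores every candidate term by its *cost-effectiveness*

    ce(S_i) = w(S_i) / |(S_i ∩ U_G) \\ C|,

the weighted penalty for inactive genes per newly covered active gene, where
``w(S) = sum_{e in S ∩ U_O} 1/|N_e|`` down-weights genes annotated by many
terms and ``C`` is the set of already covered active genes.  Instead of
always taking the minimum (``sigma``), the step picks uniformly among all
terms whose cost-effectiveness is at most ``(1 + d) * sigma``; ``d = 0``
degenerates to deterministic greedy, larger ``d`` trades per-run quality for
diversity across the ``T`` restarts.  Every prefix of every run is recorded,
so the pooled solution set traces combinations of every size ("the
landscape"), which can then be filtered by size, p-value or coverage or
reduced to its Pareto front.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationDB
from .stats import ActiveGeneSet, hypergeom_tail_logp

__all__ = [
    "CEAConfig",
    "GreedyState",
    "TermCombination",
    "SolutionSet",
    "NothingToCoverError",
    "element_weight",
    "set_weight",
    "cost_effectiveness",
    "greedy_run",
    "run_cea",
    "pareto_front",
    "filter_solutions",
    "landscape_table",
]

_LN10 = math.log(10.0)


class NothingToCoverError(ValueError):
    """No candidate term annotates any active gene: nothing to cover."""


@dataclass(frozen=True)
class CEAConfig:
    """Search parameters: randomization width ``d``, restarts ``T``, seed."""

    d: float = 1.0
    T: int = 500
    seed: int = 0
    max_coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 0 < self.max_coverage <= 1:
            raise ValueError("max_coverage must be in (0, 1]")


@dataclass
class GreedyState:
    """Explicit state of one greedy construction (used by the scalar API)."""

    selected: list[str] = field(default_factory=list)
    covered: set[str] = field(default_factory=set)  # covered ACTIVE genes
    sigma: float = math.inf


@dataclass(frozen=True)
class TermCombination:
    """A term combination with its cached set-cover and enrichment statistics.

    ``p_value`` may underflow to 0.0 for very strong combinations;
    ``neg_log10_p`` is always exact and is what orderings use.
    """

    members: tuple[str, ...]        # sorted term ids
    union_size: int                 # S(X)
    active_overlap: int             # t(X)
    coverage: float                 # C(X) = t(X) / |U_G|
    p_value: float
    neg_log10_p: float

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def objective(self) -> int:
        """The minimized penalty ``S(X) - t(X)`` (annotated inactive genes)."""
        return self.union_size - self.active_overlap


class SolutionSet:
    """Pooled combinations, deduplicated by member set, with provenance.

    ``provenance[members]`` records ``(repeat, step)`` of the first sighting.
    """

    def __init__(self) -> None:
        self._by_members: dict[tuple[str, ...], TermCombination] = {}
        self.provenance: dict[tuple[str, ...], tuple[int, int]] = {}

    def add(self, comb: TermCombination, repeat: int, step: int) -> None:
        if comb.members not in self._by_members:
            self._by_members[comb.members] = comb
            self.provenance[comb.members] = (repeat, step)

    @property
    def solutions(self) -> list[TermCombination]:
        return list(self._by_members.values())

    def __len__(self) -> int:
        return len(self._by_members)

    def __iter__(self) -> Iterator[TermCombination]:
        return iter(self._by_members.values())

    def __contains__(self, members: tuple[str, ...]) -> bool:
        return tuple(sorted(members)) in self._by_members

    def best(self, size: int | None = None) -> TermCombination:
        """Minimum-p solution, optionally restricted to one combination size."""
        pool = [s for s in self if size is None or s.size == size]
        if not pool:
            raise ValueError(f"no solutions of size {size}")
        return min(pool, key=lambda s: (-s.neg_log10_p, s.size, s.members))


# -- scalar building blocks (contract API; the engine below vectorizes them) -----


def element_weight(e: str, db: AnnotationDB) -> float:
    """``w(e) = 1/|N_e|``: inverse coverage frequency of gene ``e``."""
    ne = db.coverage_index.get(e)
    if not ne:
        raise ValueError(f"gene {e!r} is not annotated by any term")
    return 1.0 / len(ne)


def set_weight(term_id: str, ag: ActiveGeneSet, db: AnnotationDB) -> float:
    """``w(S) = sum of w(e) over e in S ∩ U_O`` (inactive members only)."""
    genes = db.term_genes(term_id)
    return sum(element_weight(e, db) for e in genes & ag.inactive)


def cost_effectiveness(
    term_id: str, state: GreedyState, ag: ActiveGeneSet, db: AnnotationDB
) -> float:
    """``w(S) / |new active genes|``; +inf when the term adds none."""
    new = (db.term_genes(term_id) & ag.active) - state.covered
    if not new:
        return math.inf
    return set_weight(term_id, ag, db) / len(new)


# -- vectorized greedy engine -----------------------------------------------------


class _GreedyEngine:
    """Shared precomputation for repeated greedy runs on one (db, ag) pair.

    Terms that annotate no active gene can never be selected and are pruned
    up front.  Active-gene incidence and full-gene incidence are kept as
    dense float/bool matrices: instances have at most a few hundred candidate
    terms, so one matrix-vector product per step dominates nothing.
    """

    def __init__(self, ag: ActiveGeneSet, db: AnnotationDB) -> None:
        self.ag = ag
        self.db = db
        self.n_active = len(ag.active)
        self.N = ag.universe_size
        cands = [t for t in db.term_ids if db.terms[t] & ag.active]
        if not cands:
            raise NothingToCoverError("no term annotates any active gene: nothing to cover")
        self.term_ids = cands
        coverable = sorted(frozenset().union(*(db.terms[t] for t in cands)) & ag.active)
        genes_all = sorted(frozenset().union(*(db.terms[t] for t in cands)))
        ai = {g: i for i, g in enumerate(coverable)}
        gi = {g: i for i, g in enumerate(genes_all)}
        m, na, ng = len(cands), len(coverable), len(genes_all)
        self.A_act = np.zeros((m, na), dtype=np.float64)
        self.A_act_bool = np.zeros((m, na), dtype=bool)
        self.A_full = np.zeros((m, ng), dtype=bool)
        self.w = np.zeros(m)
        cov = db.coverage_index
        inactive = ag.inactive
        for i, tid in enumerate(cands):
            for g in db.terms[tid]:
                self.A_full[i, gi[g]] = True
                if g in ai:
                    self.A_act[i, ai[g]] = 1.0
                    self.A_act_bool[i, ai[g]] = True
                if g in inactive:
                    self.w[i] += 1.0 / len(cov[g])

    def run(self, d: float, rng: np.random.Generator, max_coverage: float = 1.0) -> list[TermCombination]:
        uncov = np.ones(self.A_act.shape[1])
        union = np.zeros(self.A_full.shape[1], dtype=bool)
        selected: list[int] = []
        path: list[TermCombination] = []
        n, N = self.n_active, self.N
        while True:
            new = self.A_act @ uncov
            finite = new > 0.5
            if not finite.any():
                break
            ce = np.full(len(new), np.inf)
            np.divide(self.w, new, out=ce, where=finite)
            sigma = ce[finite].min()
            eligible = np.flatnonzero(ce <= (1.0 + d) * sigma)
            pick = int(eligible[rng.integers(len(eligible))])
            selected.append(pick)
            union |= self.A_full[pick]
            uncov[self.A_act_bool[pick]] = 0.0
            t = self.A_act.shape[1] - int(uncov.sum())
            K = int(union.sum())
            logp = hypergeom_tail_logp(t, K, n, N)
            path.append(
                TermCombination(
                    members=tuple(sorted(self.term_ids[i] for i in selected)),
                    union_size=K,
                    active_overlap=t,
                    coverage=t / n,
                    p_value=min(1.0, math.exp(logp)),
                    neg_log10_p=-logp / _LN10,
                )
            )
            if t / n >= max_coverage:
                break
        return path


def greedy_run(
    ag: ActiveGeneSet,
    db: AnnotationDB,
    d: float = 1.0,
    rng: np.random.Generator | int | None = None,
    max_coverage: float = 1.0,
) -> list[TermCombination]:
    """One randomized greedy construction; returns the full prefix path.

    A combination is recorded after every term addition, so element ``i`` of
    the result is the size-``i+1`` prefix.  The run stops when no remaining
    term covers a new active gene (or ``max_coverage`` is reached).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return _GreedyEngine(ag, db).run(d, rng, max_coverage)


def run_cea(ag: ActiveGeneSet, db: AnnotationDB, cfg: CEAConfig | None = None) -> SolutionSet:
    """Pool the prefix paths of ``T`` independent randomized greedy runs.

    Repeat ``r`` draws from an independent substream of ``cfg.seed``
    (``SeedSequence(seed, spawn_key=(r,))``), so results are a pure function
    of ``(seed, db, ag)`` and independent of any execution order.
    """
    cfg = cfg or CEAConfig()
    engine = _GreedyEngine(ag, db)
    pool = SolutionSet()
    for r in range(cfg.T):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(r,)))
        path = engine.run(cfg.d, rng, cfg.max_coverage)
        for step, comb in enumerate(path, start=1):
            pool.add(comb, repeat=r, step=step)
    return pool


def pareto_front(sols: SolutionSet | Iterable[TermCombination]) -> list[TermCombination]:
    """Non-dominated combinations under (maximize t, minimize S - t).

    Among solutions with identical ``(t, S - t)`` the lexicographically
    smallest member tuple is kept.  Sorted by ``t`` ascending.
    """
    pool = list(sols)
    if not pool:
        raise ValueError("empty solution set")
    # best representative per t: smallest objective, then lexicographic members
    best_by_t: dict[int, TermCombination] = {}
    for s in pool:
        cur = best_by_t.get(s.active_overlap)
        if cur is None or (s.objective, s.members) < (cur.objective, cur.members):
            best_by_t[s.active_overlap] = s
    front: list[TermCombination] = []
    best_obj = math.inf
    for t in sorted(best_by_t, reverse=True):
        s = best_by_t[t]
        if s.objective < best_obj:  # equal objective at lower t is dominated
            front.append(s)
            best_obj = s.objective
    front.reverse()
    return front


def filter_solutions(
    sols: SolutionSet,
    size: int | None = None,
    p_max: float | None = None,
    min_coverage: float | None = None,
) -> SolutionSet:
    """Conjunctive filter; surviving solutions ordered by (size, p ascending)."""
    if size is None and p_max is None and min_coverage is None:
        raise ValueError("give at least one filter criterion")
    keep = [
        s
        for s in sols
        if (size is None or s.size == size)
        and (p_max is None or s.p_value <= p_max)
        and (min_coverage is None or s.coverage >= min_coverage)
    ]
    keep.sort(key=lambda s: (s.size, -s.neg_log10_p, s.members))
    out = SolutionSet()
    for s in keep:
        r, st = sols.provenance[s.members]
        out.add(s, repeat=r, step=st)
    return out


def landscape_table(sols: SolutionSet | Iterable[TermCombination]) -> pd.DataFrame:
    """One row per solution: size, -log10 p, coverage, ';'-joined members."""
    pool = list(sols)
    if not pool:
        raise ValueError("empty solution set")
    pool.sort(key=lambda s: (s.size, -s.neg_log10_p, s.members))
    return pd.DataFrame(
        {
            "size": [s.size for s in pool],
            "neg_log10_p": [s.neg_log10_p for s in pool],
            "coverage": [s.coverage for s in pool],
            "terms": [";".join(s.members) for s in pool],
        }
    )
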