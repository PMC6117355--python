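"""Brute-force reference solvers for small instances.

These certify the randomized greedy search: exhaustive minimum-p combination
search, exact solving of the enrichment set cover problem (ESCP)

    min S(X) - t(X)   subject to   t(X) >= ceil(alpha * |U_G|),

and the exact Pareto front obtained by sweeping the coverage constraint.
Everything enumerates subsets over integer bitmasks, so it is only usable on
instances with at most ~20 terms; a budget guard refuses anything larger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from math import comb as ncr

from .annotations import AnnotationDB
from .optimize import TermCombination
from .stats import ActiveGeneSet, hypergeom_tail_logp

__all__ = [
    "OracleQuery",
    "BudgetExceededError",
    "InfeasibleCoverageError",
    "enumerate_best_pvalue",
    "solve_escp_exact",
    "exact_pareto",
]

_LN10 = math.log(10.0)


class BudgetExceededError(ValueError):
    """The enumeration would need more subsets than the configured budget."""


class InfeasibleCoverageError(ValueError):
    """The coverage constraint exceeds the maximum attainable overlap."""


@dataclass(frozen=True)
class OracleQuery:
    """Coverage constraint ``alpha`` and optional subset-size cap."""

    alpha: float = 1.0
    max_size: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


def _bitmasks(ag: ActiveGeneSet, db: AnnotationDB):
    """Term gene sets as int bitmasks over the genes annotated by any term."""
    term_ids = list(db.term_ids)
    genes = sorted(frozenset().union(*(db.terms[t] for t in term_ids)))
    pos = {g: i for i, g in enumerate(genes)}
    masks = [sum(1 << pos[g] for g in db.terms[t]) for t in term_ids]
    active_mask = sum(1 << pos[g] for g in ag.active if g in pos)
    return term_ids, masks, active_mask


def _make_comb(
    members: tuple[str, ...], union: int, active_mask: int, n: int, N: int
) -> TermCombination:
    K = union.bit_count()
    t = (union & active_mask).bit_count()
    logp = hypergeom_tail_logp(t, K, n, N)
    return TermCombination(
        members=members,
        union_size=K,
        active_overlap=t,
        coverage=t / n,
        p_value=min(1.0, math.exp(logp)),
        neg_log10_p=-logp / _LN10,
    )


def enumerate_best_pvalue(
    ag: ActiveGeneSet,
    db: AnnotationDB,
    max_size: int | None = None,
    budget: int = 2_000_000,
) -> TermCombination:
    """Exhaustive minimum-p combination over all subsets of size <= max_size.

    Ties are broken toward smaller combinations, then lexicographically
    smaller member tuples (guaranteed by the enumeration order: sizes
    ascending, members in lexicographic order, strict improvement only).
    """
    term_ids, masks, amask = _bitmasks(ag, db)
    m = len(term_ids)
    max_size = m if max_size is None else min(max_size, m)
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    total = sum(ncr(m, s) for s in range(1, max_size + 1))
    if total > budget:
        raise BudgetExceededError(f"enumeration needs {total} subsets (budget {budget})")
    n, N = len(ag.active), ag.universe_size
    cache: dict[tuple[int, int], float] = {}
    best_logp = math.inf
    best: tuple[tuple[str, ...], int] | None = None
    for s in range(1, max_size + 1):
        for idxs in combinations(range(m), s):
            union = 0
            for i in idxs:
                union |= masks[i]
            key = ((union & amask).bit_count(), union.bit_count())
            logp = cache.get(key)
            if logp is None:
                logp = hypergeom_tail_logp(key[0], key[1], n, N)
                cache[key] = logp
            if logp < best_logp:
                best_logp = logp
                best = (tuple(term_ids[i] for i in idxs), union)
    assert best is not None
    return _make_comb(best[0], best[1], amask, n, N)


def _required_overlap(alpha: float, n_active: int) -> int:
    # t is integral, so the continuous constraint alpha*|U_G| discretizes to
    # a ceiling; guard against float fuzz at exact multiples.
    return int(math.ceil(alpha * n_active - 1e-9))


def _enumerate_unions(masks: list[int], max_size: int, budget: int):
    """Yield (index tuple, union mask) over all subsets of size <= max_size."""
    m = len(masks)
    if max_size >= m:
        if 2**m - 1 > budget:
            raise BudgetExceededError(f"enumeration needs {2**m - 1} subsets (budget {budget})")
        unions = [0] * (2**m)
        bit_owner = {1 << i: i for i in range(m)}
        for s in range(1, 2**m):
            low = s & -s
            unions[s] = unions[s ^ low] | masks[bit_owner[low]]
        for s in range(1, 2**m):
            idxs = tuple(i for i in range(m) if s >> i & 1)
            yield idxs, unions[s]
    else:
        total = sum(ncr(m, s) for s in range(1, max_size + 1))
        if total > budget:
            raise BudgetExceededError(f"enumeration needs {total} subsets (budget {budget})")
        for s in range(1, max_size + 1):
            for idxs in combinations(range(m), s):
                union = 0
                for i in idxs:
                    union |= masks[i]
                yield idxs, union


def solve_escp_exact(
    ag: ActiveGeneSet,
    db: AnnotationDB,
    query: OracleQuery | None = None,
    *,
    min_overlap: int | None = None,
    budget: int = 2_000_000,
) -> TermCombination:
    """Exhaustive minimum of ``S(X) - t(X)`` subject to ``t(X) >= ceil(alpha |U_G|)``.

    ``min_overlap`` overrides the alpha-derived constraint with an explicit
    integral overlap requirement.  Ties break toward smaller objective, then
    smaller size, then lexicographic members.  ``alpha = 0`` (requirement 0)
    returns the empty combination with objective 0.
    """
    query = query or OracleQuery()
    term_ids, masks, amask = _bitmasks(ag, db)
    m = len(term_ids)
    n, N = len(ag.active), ag.universe_size
    req = min_overlap if min_overlap is not None else _required_overlap(query.alpha, n)
    max_size = m if query.max_size is None else min(query.max_size, m)
    union_all = 0
    for mk in masks:
        union_all |= mk
    t_max = (union_all & amask).bit_count()
    if req > t_max:
        raise InfeasibleCoverageError(
            f"required overlap {req} exceeds the maximum attainable {t_max} "
            f"(coverage {t_max / n:.3f})"
        )
    if req <= 0:
        return _make_comb((), 0, amask, n, N)
    best_key: tuple[int, int, tuple[str, ...]] | None = None
    best_union = 0
    for idxs, union in _enumerate_unions(masks, max_size, budget):
        t = (union & amask).bit_count()
        if t < req:
            continue
        obj = union.bit_count() - t
        members = tuple(term_ids[i] for i in idxs)
        key = (obj, len(members), members)
        if best_key is None or key < best_key:
            best_key = key
            best_union = union
    assert best_key is not None  # feasibility established above
    return _make_comb(best_key[2], best_union, amask, n, N)


def exact_pareto(
    ag: ActiveGeneSet,
    db: AnnotationDB,
    budget: int = 2_000_000,
    max_size: int | None = None,
) -> list[TermCombination]:
    """Exact Pareto front of (maximize t, minimize S - t) by constraint sweeping.

    Solves the ESCP for every attainable overlap requirement ``t >= k``,
    ``k = 0 .. t_max``, then drops dominated points.  The front has at most
    ``|U_G| + 1`` points (one per attainable overlap value, plus the empty
    combination).  Sorted by ``t`` ascending.
    """
    term_ids, masks, amask = _bitmasks(ag, db)
    m = len(term_ids)
    n, N = len(ag.active), ag.universe_size
    max_size = m if max_size is None else min(max_size, m)
    # best (obj, size, members, union) at each exact overlap value
    best_at_t: dict[int, tuple[int, int, tuple[str, ...], int]] = {
        0: (0, 0, (), 0)
    }
    for idxs, union in _enumerate_unions(masks, max_size, budget):
        t = (union & amask).bit_count()
        obj = union.bit_count() - t
        cur = best_at_t.get(t)
        if cur is not None and (obj, len(idxs)) > (cur[0], cur[1]):
            continue
        members = tuple(term_ids[i] for i in idxs)
        key = (obj, len(members), members, union)
        if cur is None or key[:3] < cur[:3]:
            best_at_t[t] = key
    # sweep k descending: best solution with t >= k
    chosen: dict[tuple[str, ...], tuple[int, int]] = {}
    running: tuple[int, int, tuple[str, ...], int] | None = None
    for t in sorted(best_at_t, reverse=True):
        cand = best_at_t[t]
        if running is None or cand[:3] < running[:3]:
            running = cand
        members, union = running[2], running[3]
        chosen.setdefault(members, ((union & amask).bit_count(), union))
    combos = [_make_comb(members, union, amask, n, N) for members, (_, union) in chosen.items()]
    # dominance filter on (t, objective)
    front: list[TermCombination] = []
    for c in sorted(combos, key=lambda c: (-c.active_overlap, c.objective)):
        if not front or c.objective < front[-1].objective:
            front.append(c)
    front.reverse()
    return front
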