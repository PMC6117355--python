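"""Single-term and composite-term enrichment statistics.

Over-representation of a gene set ``S`` in an active gene list ``U_G`` drawn
from a universe ``U`` is scored with the one-sided Fisher's exact test, i.e.
the hypergeometric upper tail

    p = P(X >= k),   X ~ Hypergeometric(N=|U|, K=|S|, n=|U_G|),

the probability of observing the same or larger overlap by chance.  A *term
combination* ``X`` is scored by the same test applied to its *pseudo
composite term*: the union of the member gene sets.  Tail probabilities are
accumulated in log space so that p-values far below float underflow (the
realistic regime for good combinations) keep an exact ``-log10 p``.
"""

from __future__ import annotations

import math
from collections.abc import Iterable
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .annotations import AnnotationDB

__all__ = [
    "ActiveGeneSet",
    "EnrichmentResult",
    "hypergeom_tail_logp",
    "hypergeom_tail_p",
    "composite_gene_set",
    "combination_pvalue",
    "coverage",
    "single_term_scan",
    "write_scan_tsv",
]

_LN10 = math.log(10.0)

# log-factorial table, grown on demand and shared across calls
_logfact_table = np.zeros(1)


def _logfact(nmax: int) -> np.ndarray:
    global _logfact_table
    if nmax >= _logfact_table.size:
        size = max(nmax + 1, 2 * _logfact_table.size, 1024)
        table = np.empty(size)
        table[0] = 0.0
        np.cumsum(np.log(np.arange(1.0, size)), out=table[1:])
        _logfact_table = table
    return _logfact_table


def hypergeom_tail_logp(k: int, K: int, n: int, N: int) -> float:
    """Natural log of ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    Parameters follow the sampling-without-replacement convention: ``N``
    population size, ``K`` marked items, ``n`` draws, ``k`` observed marks.
    Returns 0.0 (log 1) when the tail covers the whole support.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v != int(v) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValueError(f"require K <= N and n <= N, got K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"require k <= min(K, n), got k={k}, K={K}, n={n}")
    support_min = max(0, n + K - N)
    if k <= support_min:
        return 0.0
    jmax = min(K, n)
    lf = _logfact(N)
    j = np.arange(k, jmax + 1)
    logpmf = (
        (lf[K] - lf[j] - lf[K - j])
        + (lf[N - K] - lf[n - j] - lf[N - K - n + j])
        - (lf[N] - lf[n] - lf[N - n])
    )
    m = float(logpmf.max())
    return m + math.log(float(np.exp(logpmf - m).sum()))


def hypergeom_tail_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)`` (see logp variant)."""
    return min(1.0, math.exp(hypergeom_tail_logp(k, K, n, N)))


@dataclass(frozen=True)
class ActiveGeneSet:
    """The active gene list ``U_G`` and its complement ``U_O`` within ``U``."""

    active: frozenset[str]
    inactive: frozenset[str]

    def __post_init__(self) -> None:
        if self.active & self.inactive:
            raise ValueError("active and inactive gene sets must be disjoint")
        if not self.active:
            raise ValueError("active gene set must be non-empty")

    @property
    def universe_size(self) -> int:
        return len(self.active) + len(self.inactive)

    @classmethod
    def from_genes(
        cls, genes: Iterable[str], db: AnnotationDB, on_unknown: str = "drop"
    ) -> "ActiveGeneSet":
        """Bind an active gene list to a database's universe.

        ``on_unknown``: 'drop' silently restricts to the universe, 'error'
        raises when a gene is outside it.
        """
        gset = frozenset(genes)
        unknown = gset - db.universe
        if unknown:
            if on_unknown == "error":
                raise ValueError(
                    f"{len(unknown)} active genes outside the universe "
                    f"(e.g. {sorted(unknown)[:3]})"
                )
            gset = gset & db.universe
        if not gset:
            raise ValueError("no active genes remain inside the universe")
        return cls(active=gset, inactive=db.universe - gset)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher/hypergeometric test outcome for a term or a term combination."""

    subject: tuple[str, ...]
    overlap: int          # k
    annotated: int        # K (genes in the term or composite union)
    active_size: int      # n = |U_G|
    universe_size: int    # N = |U|
    p_value: float
    log_p: float = field(default=0.0)  # natural log; exact even when p underflows

    @property
    def neg_log10_p(self) -> float:
        return -self.log_p / _LN10


def composite_gene_set(X: Iterable[str], db: AnnotationDB) -> frozenset[str]:
    """Union of the member gene sets: the pseudo composite term of ``X``."""
    ids = list(X)
    if not ids:
        raise ValueError("term combination must be non-empty")
    out: frozenset[str] = frozenset()
    for tid in ids:
        out |= db.term_genes(tid)
    return out


def combination_pvalue(X: Iterable[str], ag: ActiveGeneSet, db: AnnotationDB) -> EnrichmentResult:
    """Enrichment of the pseudo composite term of combination ``X``."""
    ids = tuple(sorted(set(X)))
    union = composite_gene_set(ids, db)
    k = len(union & ag.active)
    K = len(union)
    n = len(ag.active)
    N = ag.universe_size
    logp = hypergeom_tail_logp(k, K, n, N)
    return EnrichmentResult(
        subject=ids, overlap=k, annotated=K, active_size=n,
        universe_size=N, p_value=min(1.0, math.exp(logp)), log_p=logp,
    )


def coverage(X: Iterable[str], ag: ActiveGeneSet, db: AnnotationDB) -> float:
    """``C(X)``: fraction of active genes annotated by at least one term of X."""
    if not ag.active:
        raise ValueError("active gene set is empty")
    ids = list(X)
    if not ids:
        return 0.0
    return len(composite_gene_set(ids, db) & ag.active) / len(ag.active)


def single_term_scan(ag: ActiveGeneSet, db: AnnotationDB) -> pd.DataFrame:
    """Classic one-term-at-a-time over-representation scan.

    Returns a DataFrame sorted by ascending p with columns
    ``term_id, name, k, K, n, N, p, p_adj, rank``; ``p_adj`` is the
    Benjamini-Hochberg adjustment over all terms and ``rank`` uses the
    competition (shared-minimum) convention so tied p-values tie in rank.
    """
    n = len(ag.active)
    N = ag.universe_size
    rows = []
    for tid in db.term_ids:
        genes = db.terms[tid]
        k = len(genes & ag.active)
        K = len(genes)
        rows.append((tid, db.names.get(tid, ""), k, K, hypergeom_tail_p(k, K, n, N)))
    df = pd.DataFrame(rows, columns=["term_id", "name", "k", "K", "p"])
    df["n"] = n
    df["N"] = N
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["rank"] = rankdata(df["p"].to_numpy(), method="min").astype(int)
    df = df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    return df[["term_id", "name", "k", "K", "n", "N", "p", "p_adj", "rank"]]


def write_scan_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
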