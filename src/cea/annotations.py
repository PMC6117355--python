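"""Gene-set annotation databases.

An annotation database maps functional terms (GO terms, pathways, any named
gene set) to the genes they annotate.  It fixes three objects that every
other module consumes:

* the candidate term family ``S_1, ..., S_m`` (one gene set per term),
* the gene universe ``U`` (by default the union of all annotated genes,
  optionally an explicit background list), and
* the per-gene coverage index ``N_e = {i : e in S_i}``, i.e. for each gene
  the set of terms annotating it.  ``1/|N_e|`` is the element weight used by
  the set-cover optimizer: promiscuously annotated genes are cheap to cover.

Gene and term identifiers are opaque strings compared by exact equality; no
symbol/alias resolution is attempted.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationDB",
    "GmtParseError",
    "UnknownTermError",
    "load_gmt",
    "write_gmt",
    "read_gene_list",
    "restrict_to_universe",
]


class GmtParseError(ValueError):
    """Raised when a GMT file violates the tab-separated three-field dialect."""


class UnknownTermError(KeyError):
    """Raised when a term id is looked up that the database does not contain."""


class AnnotationDB:
    """Immutable term -> gene-set mapping with a fixed gene universe.

    Parameters
    ----------
    terms:
        Mapping from term id to an iterable of gene ids.  Empty gene sets are
        rejected.
    names:
        Optional mapping from term id to a human-readable description.
    universe:
        Optional explicit gene universe.  Must be a superset of all annotated
        genes; defaults to their union.
    """

    def __init__(
        self,
        terms: Mapping[str, Iterable[str]],
        names: Mapping[str, str] | None = None,
        universe: Iterable[str] | None = None,
    ) -> None:
        self.terms: dict[str, frozenset[str]] = {}
        for tid, genes in terms.items():
            gs = frozenset(genes)
            if not gs:
                raise ValueError(f"term {tid!r} has an empty gene set")
            self.terms[tid] = gs
        if not self.terms:
            raise ValueError("annotation database has zero terms")
        annotated = frozenset().union(*self.terms.values())
        if universe is None:
            self.universe: frozenset[str] = annotated
        else:
            self.universe = frozenset(universe)
            extra = annotated - self.universe
            if extra:
                raise ValueError(
                    f"{len(extra)} annotated genes outside the declared universe "
                    f"(e.g. {sorted(extra)[:3]})"
                )
        self.names: dict[str, str] = {tid: "" for tid in self.terms}
        if names:
            for tid, name in names.items():
                if tid in self.names:
                    self.names[tid] = name
        self._coverage_index: dict[str, frozenset[str]] | None = None

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    @property
    def term_ids(self) -> tuple[str, ...]:
        """Term ids in sorted order (the canonical iteration order)."""
        return tuple(sorted(self.terms))

    def term_genes(self, term_id: str) -> frozenset[str]:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term id {term_id!r}") from None

    @property
    def coverage_index(self) -> dict[str, frozenset[str]]:
        """``N_e``: for each annotated gene, the set of term ids containing it."""
        if self._coverage_index is None:
            idx: dict[str, set[str]] = {}
            for tid, genes in self.terms.items():
                for g in genes:
                    idx.setdefault(g, set()).add(tid)
            self._coverage_index = {g: frozenset(ts) for g, ts in idx.items()}
        return self._coverage_index

    @property
    def annotated_genes(self) -> frozenset[str]:
        return frozenset(self.coverage_index)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AnnotationDB({len(self.terms)} terms, "
            f"{len(self.universe)} genes in universe)"
        )


def load_gmt(path: str | Path, universe: Iterable[str] | str | Path | None = None) -> AnnotationDB:
    """Read a GMT file (Broad/MSigDB dialect) into an :class:`AnnotationDB`.

    Each line holds ``term_id<TAB>description<TAB>gene1<TAB>gene2...``.  The
    description column is preserved as the term name but never used in
    computation.  Duplicate genes within a line are collapsed; lines whose
    member list is empty after collapsing are dropped with a warning.

    Parameters
    ----------
    universe:
        Optional explicit gene universe: either an iterable of gene ids or a
        path to a one-id-per-line file ('#' comments allowed).  Without it the
        universe is the union of all annotated genes.
    """
    path = Path(path)
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            tid, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if tid in terms:
                raise GmtParseError(f"{path}:{lineno}: duplicate term id {tid!r}")
            if not genes:
                logger.warning("%s:%d: term %r has no member genes; dropped", path, lineno, tid)
                continue
            terms[tid] = genes
            names[tid] = name
    if not terms:
        raise GmtParseError(f"{path}: no usable terms")
    if universe is not None and isinstance(universe, (str, Path)):
        universe = read_gene_list(universe)
    return AnnotationDB(terms, names=names, universe=universe)


def write_gmt(db: AnnotationDB, path: str | Path) -> None:
    """Write the database back to GMT; genes are sorted for reproducible bytes."""
    path = Path(path)
    with path.open("w") as fh:
        for tid in db.term_ids:
            genes = "\t".join(sorted(db.terms[tid]))
            fh.write(f"{tid}\t{db.names.get(tid, '')}\t{genes}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-id-per-line file; '#'-prefixed lines are comments."""
    out: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def restrict_to_universe(db: AnnotationDB, universe: Iterable[str]) -> AnnotationDB:
    """Intersect every term with ``universe`` and rebuild the database.

    Terms that become empty are removed (logged).  Raises ``ValueError`` when
    no term survives.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    kept: dict[str, frozenset[str]] = {}
    dropped = 0
    for tid, genes in db.terms.items():
        inter = genes & uni
        if inter:
            kept[tid] = inter
        else:
            dropped += 1
    if not kept:
        raise ValueError("restriction removed every term")
    if dropped:
        logger.info("restrict_to_universe: dropped %d empty terms", dropped)
    return AnnotationDB(kept, names=db.names, universe=uni & db.universe | frozenset().union(*kept.values()))
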