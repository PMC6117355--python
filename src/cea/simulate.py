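"""Synthetic annotation databases and active gene lists with planted truth.

The generator emulates the shape of GO-style annotation data: a universe of
a couple thousand genes, a few hundred terms whose sizes follow a
log-uniform distribution (many small specific terms, few large general
ones), and controlled pairwise overlap created by resampling a fraction of
each new term's members from previously generated terms.  A *planted
instance* additionally designates ``k`` mutually disjoint terms as the true
combination, sets the active list to their union plus a few noise genes
outside it (experimental noise that no planted term explains), and records
the provenance of every active gene.  Everything is a pure function of its
seed and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import AnnotationDB
from .stats import ActiveGeneSet

__all__ = [
    "make_synthetic_db",
    "PlantedInstance",
    "make_planted_instance",
    "random_small_instance",
    "write_instance",
]


def make_synthetic_db(
    n_genes: int = 2000,
    n_terms: int = 300,
    size_range: tuple[int, int] = (5, 200),
    overlap: float = 0.3,
    seed: int = 0,
) -> AnnotationDB:
    """Random annotation database with log-uniform term sizes.

    ``overlap`` is the expected fraction of each term's members resampled
    from the union of previously generated terms (0 keeps terms maximally
    independent; with small sizes and 0 overlap they end up disjoint whenever
    the universe is large enough).  The universe is all ``n_genes`` genes,
    annotated or not.
    """
    lo, hi = size_range
    if not (1 <= lo <= hi <= n_genes):
        raise ValueError(f"invalid size_range {size_range} for n_genes={n_genes}")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    if n_terms < 1 or n_genes < 1:
        raise ValueError("n_genes and n_terms must be positive")
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    terms: dict[str, frozenset[str]] = {}
    prev_union: list[str] = []
    prev_set: set[str] = set()
    for j in range(n_terms):
        size = int(round(float(np.exp(rng.uniform(np.log(lo), np.log(hi))))))
        size = max(1, min(size, n_genes))
        n_old = min(int(round(overlap * size)), len(prev_union))
        members: set[str] = set()
        if n_old:
            members.update(rng.choice(np.array(prev_union, dtype=object), size=n_old, replace=False))
        n_new = size - len(members)
        if n_new > 0:
            # fresh members come from still-unused genes so the overlap knob is
            # the only source of inter-term overlap; fall back to the whole
            # universe when unused genes run out
            unused = sorted(set(genes.tolist()) - prev_set - members)
            if len(unused) >= n_new:
                members.update(rng.choice(np.array(unused, dtype=object), size=n_new, replace=False))
            else:
                members.update(unused)
                rest = sorted(set(genes.tolist()) - members)
                members.update(
                    rng.choice(np.array(rest, dtype=object), size=size - len(members), replace=False)
                )
        tid = f"T{j:04d}"
        terms[tid] = frozenset(members)
        for g in members:
            if g not in prev_set:
                prev_set.add(g)
                prev_union.append(g)
    return AnnotationDB(terms, names={t: f"synthetic term {t}" for t in terms}, universe=genes.tolist())


@dataclass(frozen=True)
class PlantedInstance:
    """A synthetic instance with a known true term combination."""

    db: AnnotationDB
    active: ActiveGeneSet
    planted: frozenset[str]
    planted_genes: frozenset[str] = field(repr=False)
    noise_genes: frozenset[str] = field(repr=False)

    @property
    def noise_active(self) -> int:
        return len(self.noise_genes)

    @property
    def decoy_terms(self) -> int:
        return len(self.db) - len(self.planted)

    def truth_dict(self) -> dict:
        return {
            "planted_terms": sorted(self.planted),
            "noise_genes": sorted(self.noise_genes),
            "n_planted_genes": len(self.planted_genes),
        }


def make_planted_instance(
    db_params: dict | None = None,
    k_planted: int = 10,
    noise_active: int = 5,
    seed: int = 0,
) -> PlantedInstance:
    """Plant ``k_planted`` mutually disjoint terms as the true combination.

    The active list is their union plus ``noise_active`` genes sampled
    outside it.  With no noise the planted set is the unique zero-penalty
    cover of the active list (disjoint terms whose genes are all active),
    hence the unique minimum of ``S(X) - t(X)`` at its coverage; the exact
    oracle can certify this on small instances.  Raises when ``k_planted``
    disjoint terms cannot be found (lower the overlap or term sizes).
    """
    params = {"n_genes": 2000, "n_terms": 300, "size_range": (5, 200), "overlap": 0.3, "seed": seed}
    if db_params:
        params.update(db_params)
    db = make_synthetic_db(**params)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    tids = np.array(db.term_ids, dtype=object)
    planted: list[str] = []
    for _ in range(50):  # reshuffle attempts
        order = rng.permutation(tids)
        chosen: list[str] = []
        used: set[str] = set()
        for t in order:
            genes = db.terms[t]
            if not (genes & used):
                chosen.append(str(t))
                used |= genes
                if len(chosen) == k_planted:
                    break
        if len(chosen) == k_planted:
            planted = chosen
            break
    if len(planted) < k_planted:
        raise ValueError(
            f"could not find {k_planted} mutually disjoint terms; "
            "lower the overlap or term sizes"
        )
    planted_genes = frozenset().union(*(db.terms[t] for t in planted))
    outside = np.array(sorted(db.universe - planted_genes), dtype=object)
    if noise_active > len(outside):
        raise ValueError("noise_active exceeds the genes outside the planted union")
    noise = frozenset(rng.choice(outside, size=noise_active, replace=False)) if noise_active else frozenset()
    active = ActiveGeneSet.from_genes(planted_genes | noise, db)
    return PlantedInstance(
        db=db,
        active=active,
        planted=frozenset(planted),
        planted_genes=planted_genes,
        noise_genes=noise,
    )


def random_small_instance(
    seed: int,
    n_genes: int = 40,
    n_terms: int = 12,
    size_range: tuple[int, int] = (2, 8),
    n_active: int = 8,
) -> tuple[AnnotationDB, ActiveGeneSet]:
    """Small random instance for oracle-vs-greedy certification tests.

    Terms are uniform random subsets; the active list is a random sample of
    the universe, redrawn until at least one active gene is annotated.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:03d}" for i in range(n_genes)], dtype=object)
    terms = {}
    for j in range(n_terms):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        terms[f"t{j:02d}"] = frozenset(rng.choice(genes, size=size, replace=False))
    db = AnnotationDB(terms, universe=genes.tolist())
    annotated = db.annotated_genes
    for _ in range(100):
        active = frozenset(rng.choice(genes, size=n_active, replace=False))
        if active & annotated:
            return db, ActiveGeneSet(active=active, inactive=db.universe - active)
    raise RuntimeError("could not draw an active set overlapping the annotations")


def write_instance(inst: PlantedInstance, prefix: str | Path) -> None:
    """Write PREFIX.gmt, PREFIX.active.txt and PREFIX.truth.json."""
    from .annotations import write_gmt

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_gmt(inst.db, Path(str(prefix) + ".gmt"))
    with Path(str(prefix) + ".active.txt").open("w") as fh:
        for g in sorted(inst.active.active):
            fh.write(g + "\n")
    with Path(str(prefix) + ".truth.json").open("w") as fh:
        json.dump(inst.truth_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
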