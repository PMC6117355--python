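"""Ontology DAG handling: OBO loading, levels, ancestor queries.

The ontology is a directed acyclic graph whose edges point child -> parent
along ``is_a`` relations only.  The root is the unique node without parents.
A term's *level* is the length (edge count) of the longest is_a path from
the term up to the root; the root sits at level 0.  Levels are the standard
specificity proxy: deeper terms annotate fewer, more specific genes.
"""

from __future__ import annotations

from collections.abc import Iterable
from pathlib import Path

import networkx as nx

__all__ = ["OntologyDAG", "OntologyError", "load_obo"]


class OntologyError(ValueError):
    """Structural problem in an ontology graph (cycle, missing/multiple roots)."""


class OntologyDAG:
    """Directed acyclic is_a hierarchy with a single root.

    Parameters
    ----------
    graph:
        ``networkx.DiGraph`` with edges pointing child -> parent.
    """

    def __init__(self, graph: nx.DiGraph) -> None:
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"ontology graph contains a cycle: {cycle}")
        roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one root (node without parents), found {len(roots)}: "
                f"{sorted(roots)[:5]}"
            )
        self.graph = graph
        self.root: str = roots[0]
        self._levels: dict[str, int] | None = None
        self._wang_cache: dict[tuple[str, float], tuple[dict[str, float], float]] = {}

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] | None = None
    ) -> "OntologyDAG":
        """Build from (child, parent) pairs; handy for fixtures."""
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return cls(g)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def parents(self, term_id: str) -> frozenset[str]:
        return frozenset(self.graph.successors(term_id))

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All strict ancestors of ``term_id`` (is_a closure, excluding itself)."""
        if term_id not in self.graph:
            raise KeyError(f"term {term_id!r} not in ontology")
        return frozenset(nx.descendants(self.graph, term_id))

    def levels(self) -> dict[str, int]:
        """Longest-path level of every node (root = 0).

        Computed by dynamic programming in an order where parents precede
        children, so ``level(n) = 1 + max(level(p) for p in parents(n))``.
        """
        if self._levels is None:
            order = list(nx.topological_sort(self.graph))  # children before parents
            levels: dict[str, int] = {}
            for node in reversed(order):  # parents before children
                parents = list(self.graph.successors(node))
                levels[node] = 0 if not parents else 1 + max(levels[p] for p in parents)
            self._levels = levels
        return self._levels

    def level(self, term_id: str) -> int:
        try:
            return self.levels()[term_id]
        except KeyError:
            raise KeyError(f"term {term_id!r} not in ontology") from None


def load_obo(path: str | Path, namespace: str = "biological_process") -> OntologyDAG:
    """Load an OBO 1.2 ontology restricted to one namespace and is_a edges.

    Obsolete terms are excluded.  Terms without a ``namespace`` tag are kept
    only when ``namespace`` is None.  Raises :class:`OntologyError` on cycles
    or when the namespace does not induce a single-rooted hierarchy.
    """
    import obonet

    multigraph = obonet.read_obo(str(path))  # skips obsolete stanzas by default
    g = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        if namespace is None or data.get("namespace") == namespace:
            g.add_node(node, name=data.get("name", ""))
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a" and child in g and parent in g:
            g.add_edge(child, parent)
    if g.number_of_nodes() == 0:
        raise OntologyError(f"no terms in namespace {namespace!r}")
    return OntologyDAG(g)
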