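"""Gene Ontology containers: annotation table and a BP/CC is_a DAG.

The DAG is restricted to the biological_process (BP) and cellular_component
(CC) namespaces and to ``is_a`` edges.  Term depth ("layer") counts the root
as layer 1; by default it is the length of the *longest* is_a path from the
namespace root, the stricter of the two common conventions (shortest-path
depth is available as an option).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

BP = "BP"
CC = "CC"
NAMESPACES = (BP, CC)

#: accepted namespace spellings -> canonical token
_NS_ALIASES = {
    "BP": BP,
    "CC": CC,
    "biological_process": BP,
    "cellular_component": CC,
    "P": BP,
    "C": CC,
}
#: molecular_function is a known GO namespace but out of scope; silently dropped
_NS_DROPPED = {"MF", "molecular_function", "F"}


def normalize_namespace(token: str) -> str | None:
    """Canonical BP/CC token, ``None`` for molecular_function, error otherwise."""
    if token in _NS_ALIASES:
        return _NS_ALIASES[token]
    if token in _NS_DROPPED:
        return None
    raise ValueError(f"unknown GO namespace token {token!r}")


@dataclass(frozen=True)
class AnnotationTable:
    """Deduplicated (gene, term, namespace) annotation triples, BP/CC only."""

    records: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for gene, term, ns in self.records:
            if ns not in NAMESPACES:
                raise ValueError(f"annotation namespace must be BP/CC, got {ns!r}")
            if not gene or not term:
                raise ValueError("gene and term identifiers must be non-empty")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> set[str]:
        return {g for g, _, _ in self.records}

    @property
    def terms(self) -> set[str]:
        return {t for _, t, _ in self.records}

    def term_to_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for gene, term, _ in self.records:
            out[term].add(gene)
        return dict(out)

    def gene_to_terms(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for gene, term, _ in self.records:
            out[gene].add(term)
        return dict(out)

    def restricted_to_genes(self, genes: set[str]) -> "AnnotationTable":
        return AnnotationTable(
            frozenset(r for r in self.records if r[0] in genes)
        )


class GoDag:
    """Acyclic is_a hierarchy over BP/CC terms (edges child -> parent).

    Validates acyclicity, known endpoints, namespace consistency along edges,
    and a single root (parentless term) per populated namespace.
    """

    def __init__(
        self,
        namespaces: Mapping[str, str],
        parent_edges: Iterable[tuple[str, str]],
    ) -> None:
        self._ns = dict(namespaces)
        for term, ns in self._ns.items():
            if ns not in NAMESPACES:
                raise ValueError(f"term {term!r} has namespace {ns!r}, expected BP/CC")
        g = nx.DiGraph()
        g.add_nodes_from(self._ns)
        for child, parent in parent_edges:
            if child not in self._ns or parent not in self._ns:
                raise ValueError(f"parent edge ({child!r}, {parent!r}) touches unknown term")
            if self._ns[child] != self._ns[parent]:
                raise ValueError(
                    f"is_a edge crosses namespaces: {child!r} -> {parent!r}"
                )
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("GO hierarchy contains a cycle")
        self._g = g
        roots_by_ns: dict[str, list[str]] = defaultdict(list)
        for term in g.nodes:
            if g.out_degree(term) == 0:
                roots_by_ns[self._ns[term]].append(term)
        for ns in {self._ns[t] for t in g.nodes}:
            if len(roots_by_ns[ns]) != 1:
                raise ValueError(
                    f"namespace {ns} must have exactly one root, "
                    f"found {sorted(roots_by_ns[ns])}"
                )
        self._roots = {ns: r[0] for ns, r in roots_by_ns.items()}
        self._depth_cache: dict[str, dict[str, int]] = {}

    # -- basic structure ---------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self._g.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def namespace(self, term: str) -> str:
        return self._ns[term]

    def roots(self) -> dict[str, str]:
        return dict(self._roots)

    def parents(self, term: str) -> set[str]:
        return set(self._g.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self._g.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All transitive is_a ancestors (excluding the term itself)."""
        return nx.descendants(self._g, term)

    def descendants(self, term: str) -> set[str]:
        return nx.ancestors(self._g, term)

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        return ancestor in self.ancestors(descendant)

    # -- depth -------------------------------------------------------------

    def depth(self, term: str, method: str = "longest") -> int:
        """Layer of ``term`` counting the namespace root as layer 1."""
        if method not in ("longest", "shortest"):
            raise ValueError(f"unknown depth method {method!r}")
        if method not in self._depth_cache:
            agg = max if method == "longest" else min
            depths: dict[str, int] = {}
            # children precede parents in topological order; walk parents first
            for t in reversed(list(nx.topological_sort(self._g))):
                ps = self.parents(t)
                depths[t] = 1 if not ps else 1 + agg(depths[p] for p in ps)
            self._depth_cache[method] = depths
        return self._depth_cache[method][term]

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_obo(cls, source) -> "GoDag":
        """Read an OBO (v1.2) ontology, keeping BP/CC terms and is_a edges."""
        import obonet

        graph = obonet.read_obo(source)
        namespaces: dict[str, str] = {}
        for term, data in graph.nodes(data=True):
            ns = normalize_namespace(data.get("namespace", ""))
            if ns is not None:
                namespaces[term] = ns
        edges = [
            (child, parent)
            for child, parent, key in graph.edges(keys=True)
            if key == "is_a" and child in namespaces and parent in namespaces
        ]
        return cls(namespaces, edges)

    @classmethod
    def from_edge_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "GoDag":
        """Build from (child, parent, namespace) rows; MF rows are dropped."""
        namespaces: dict[str, str] = {}
        edges = []
        for child, parent, token in rows:
            ns = normalize_namespace(token)
            if ns is None:
                logger.warning("dropping molecular_function edge %s -> %s", child, parent)
                continue
            for term in (child, parent):
                if namespaces.get(term, ns) != ns:
                    raise ValueError(f"term {term!r} assigned to two namespaces")
                namespaces[term] = ns
            edges.append((child, parent))
        return cls(namespaces, edges)
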