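"""Core network containers: regulatory interactions, edge layers, and the
integrated two-layer network.

A gene pair can be linked by co-transcriptional regulation (CT: the two genes
share at least one regulating transcription factor) and/or by a physical
protein-protein interaction (PPI).  The integrated network keeps only genes
that carry at least one link of *each* type and that are GO-annotated; both
edge layers live over that shared gene universe.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

CT = "CT"
PPI = "PPI"
LAYER_KINDS = (CT, PPI)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered gene pair deterministically (lexicographically)."""
    if not a or not b:
        raise ValueError("gene identifiers must be non-empty")
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid edge")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class RegulatoryInteractionSet:
    """Deduplicated directed TF -> target-gene interactions (TIs)."""

    interactions: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for tf, target in self.interactions:
            if not tf or not target:
                raise ValueError("tf and target identifiers must be non-empty")

    def __len__(self) -> int:
        return len(self.interactions)

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self.interactions}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.interactions}

    def targets_by_tf(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for tf, target in self.interactions:
            out[tf].add(target)
        return dict(out)


@dataclass(frozen=True)
class EdgeLayer:
    """One undirected simple-graph layer (CT or PPI) as canonical gene pairs."""

    kind: str
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        for a, b in self.edges:
            if not a or not b or a >= b:
                raise ValueError(f"edge {(a, b)!r} is not a canonical pair")

    @classmethod
    def from_pairs(
        cls, kind: str, pairs: Iterable[tuple[str, str]], drop_self: bool = True
    ) -> "EdgeLayer":
        """Canonicalize arbitrary (a, b) pairs; self-pairs are dropped
        (``drop_self``) or rejected."""
        edges = set()
        for a, b in pairs:
            if a == b:
                if drop_self:
                    continue
                raise ValueError(f"self-pair {a!r}")
            edges.add(canonical_pair(a, b))
        return cls(kind, frozenset(edges))

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a < b else (b, a)) in self.edges

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.sorted_edges())

    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = defaultdict(int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return dict(deg)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def restricted_to(self, genes: set[str]) -> "EdgeLayer":
        return EdgeLayer(
            self.kind,
            frozenset(e for e in self.edges if e[0] in genes and e[1] in genes),
        )


@dataclass(frozen=True)
class IntegratedNetwork:
    """Two edge layers (CT, PPI) over a shared, lexicographically ordered gene
    universe in which every gene carries at least one link of each type."""

    genes: tuple[str, ...]
    ct: EdgeLayer
    ppi: EdgeLayer

    def __post_init__(self) -> None:
        if list(self.genes) != sorted(set(self.genes)):
            raise ValueError("gene list must be sorted and duplicate-free")
        if self.ct.kind != CT or self.ppi.kind != PPI:
            raise ValueError("layers must be (CT, PPI) in that order")
        universe = set(self.genes)
        for layer in (self.ct, self.ppi):
            stray = layer.genes() - universe
            if stray:
                raise ValueError(f"{layer.kind} edges touch unknown genes {sorted(stray)[:5]}")
        ct_genes = self.ct.genes()
        ppi_genes = self.ppi.genes()
        lonely = universe - (ct_genes & ppi_genes)
        if lonely:
            raise ValueError(
                f"genes without both link types: {sorted(lonely)[:5]}"
            )

    @property
    def gene_set(self) -> set[str]:
        return set(self.genes)

    def to_graph(self) -> nx.Graph:
        """One networkx graph with a ``layer`` edge attribute; an edge present
        in both layers is labelled ``CT+PPI``."""
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for a, b in self.ct.sorted_edges():
            g.add_edge(a, b, layer=CT)
        for a, b in self.ppi.sorted_edges():
            if g.has_edge(a, b):
                g[a][b]["layer"] = "CT+PPI"
            else:
                g.add_edge(a, b, layer=PPI)
        return g
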