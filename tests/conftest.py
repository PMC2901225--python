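"""Shared fixtures: tiny hand-built networks and a small synthetic study."""

from __future__ import annotations

import io

import numpy as np
import pytest

import ctppi
from ctppi.mantel import AdjacencyPair


def make_adjacency(n: int, a_edges, b_edges, genes=None) -> AdjacencyPair:
    """AdjacencyPair from 0-based index edge lists (A = PPI, B = CT)."""
    genes = tuple(genes) if genes else tuple(f"g{i}" for i in range(n))
    A = np.zeros((n, n), dtype=int)
    B = np.zeros((n, n), dtype=int)
    for mat, edges in ((A, a_edges), (B, b_edges)):
        for i, j in edges:
            mat[i, j] = mat[j, i] = 1
    return AdjacencyPair(genes, A, B)


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.4) -> AdjacencyPair:
    def rand_sym():
        m = np.triu((rng.random((n, n)) < p).astype(int), 1)
        return m + m.T

    return AdjacencyPair(tuple(f"g{i}" for i in range(n)), rand_sym(), rand_sym())


def random_layer(rng: np.random.Generator, n_genes: int, n_edges: int, kind="PPI"):
    """Random simple layer with exactly up to n_edges distinct edges."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    edges = set()
    while len(edges) < n_edges:
        i, j = rng.choice(n_genes, size=2, replace=False)
        a, b = genes[i], genes[j]
        edges.add((a, b) if a < b else (b, a))
    return ctppi.EdgeLayer(kind, frozenset(edges))


@pytest.fixture
def triangle_net() -> ctppi.IntegratedNetwork:
    """3 genes, identical CT and PPI triangles."""
    pairs = [("a", "b"), ("a", "c"), ("b", "c")]
    return ctppi.IntegratedNetwork(
        ("a", "b", "c"),
        ctppi.EdgeLayer.from_pairs("CT", pairs),
        ctppi.EdgeLayer.from_pairs("PPI", pairs),
    )


@pytest.fixture(scope="session")
def small_study() -> ctppi.StudyInputs:
    return ctppi.simulate_study(seed=7)


@pytest.fixture(scope="session")
def small_study_net(small_study) -> ctppi.IntegratedNetwork:
    return small_study.integrated_network()


def text(s: str) -> io.StringIO:
    return io.StringIO(s)
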