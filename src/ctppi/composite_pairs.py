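"""Composite CT-PPI pairs (C-pairs): detection, degree-preserving null model,
and functional-coherence testing.

A C-pair is a gene pair linked simultaneously in the CT and PPI layers — the
two-node composite motif.  Its over-representation is assessed against a null
in which each layer is rewired by double-edge swaps that keep every node's
degree exactly, then the layers are re-intersected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy import stats

from .network import EdgeLayer, IntegratedNetwork, RegulatoryInteractionSet
from .ontology import AnnotationTable, GoDag
from .seeding import derive_seed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositePairSet:
    """Unordered gene pairs present in both layers."""

    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.pairs))

    def restricted_to(self, genes: set[str]) -> "CompositePairSet":
        return CompositePairSet(
            frozenset(p for p in self.pairs if p[0] in genes and p[1] in genes)
        )


@dataclass(frozen=True)
class RandomizationSummary:
    """Observed C-pair count against the degree-preserving null."""

    n_real: int
    null_counts: tuple[int, ...]
    null_mean: float
    null_sd: float
    z_score: float  # NaN when the null is degenerate (sd = 0)
    n_randomizations: int
    empirical_p: float

    def to_dict(self) -> dict:
        return {
            "n_real": self.n_real,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z_score": None if math.isnan(self.z_score) else self.z_score,
            "n_randomizations": self.n_randomizations,
            "empirical_p": self.empirical_p,
        }


def find_cpairs(net: IntegratedNetwork) -> CompositePairSet:
    """Exact intersection of the CT and PPI edge sets."""
    return CompositePairSet(frozenset(net.ct.edges & net.ppi.edges))


def z_score(n_real: float, null_mean: float, null_sd: float) -> float:
    """(N_real - mean) / sd; NaN when sd is zero."""
    if null_sd <= 0:
        return float("nan")
    return (n_real - null_mean) / null_sd


# ---------------------------------------------------------------------------
# degree-preserving randomization
# ---------------------------------------------------------------------------


def _attempt_swaps(
    edges: list[tuple[str, str]], rng: np.random.Generator, n_attempts: int
) -> list[tuple[str, str]]:
    """Attempt ``n_attempts`` double-edge swaps on a simple undirected graph.

    Each attempt draws two edges and an orientation; swaps creating self-loops
    or duplicate edges are rejected, so the per-node degree sequence is
    preserved exactly.  The proposal is symmetric, hence the chain's
    stationary distribution is uniform over simple graphs with this degree
    sequence.
    """
    m = len(edges)
    edges = [tuple(e) for e in edges]
    if m < 2 or n_attempts <= 0:
        return edges
    present = set(edges)
    i_arr = rng.integers(0, m, size=n_attempts).tolist()
    j_arr = rng.integers(0, m, size=n_attempts).tolist()
    flips = (rng.random(n_attempts) < 0.5).tolist()
    n_success = 0
    for i, j, flip in zip(i_arr, j_arr, flips):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        e1 = (a, c) if a < c else (c, a)
        e2 = (b, d) if b < d else (d, b)
        if e1 in present or e2 in present:
            continue
        present.discard(edges[i])
        present.discard(edges[j])
        present.add(e1)
        present.add(e2)
        edges[i] = e1
        edges[j] = e2
        n_success += 1
    if n_success == 0:
        logger.warning("no admissible double-edge swap; layer returned unchanged")
    return edges


def randomize_layer(layer: EdgeLayer, seed: int, swap_factor: int = 100) -> EdgeLayer:
    """Degree-preserving rewiring attempting ``swap_factor * |edges|`` swaps."""
    if len(layer) < 2:
        return layer
    rng = np.random.default_rng(seed)
    edges = _attempt_swaps(layer.sorted_edges(), rng, swap_factor * len(layer))
    return EdgeLayer(layer.kind, frozenset(edges))


def _attempt_bipartite_swaps(
    interactions: list[tuple[str, str]], rng: np.random.Generator, n_attempts: int
) -> list[tuple[str, str]]:
    """Swap targets between TF->target interactions, preserving every TF's
    out-degree and every gene's in-degree."""
    m = len(interactions)
    interactions = [tuple(e) for e in interactions]
    if m < 2 or n_attempts <= 0:
        return interactions
    present = set(interactions)
    i_arr = rng.integers(0, m, size=n_attempts).tolist()
    j_arr = rng.integers(0, m, size=n_attempts).tolist()
    for i, j in zip(i_arr, j_arr):
        if i == j:
            continue
        t1, g1 = interactions[i]
        t2, g2 = interactions[j]
        if t1 == t2 or g1 == g2:
            continue
        e1, e2 = (t1, g2), (t2, g1)
        if e1 in present or e2 in present:
            continue
        present.discard(interactions[i])
        present.discard(interactions[j])
        present.add(e1)
        present.add(e2)
        interactions[i] = e1
        interactions[j] = e2
    return interactions


def randomize_regulatory(
    reg: RegulatoryInteractionSet, seed: int, swap_factor: int = 100
) -> RegulatoryInteractionSet:
    """Randomize the bipartite TF->target graph, preserving each TF's target
    count and each gene's regulator count."""
    rng = np.random.default_rng(seed)
    edges = _attempt_bipartite_swaps(
        sorted(reg.interactions), rng, swap_factor * len(reg)
    )
    return RegulatoryInteractionSet(frozenset(edges))


def cpair_significance(
    net: IntegratedNetwork,
    n_randomizations: int = 1000,
    seed: int = 0,
    swap_factor: int = 100,
    ct_null: str = "direct",
    reg: "RegulatoryInteractionSet | None" = None,
) -> RandomizationSummary:
    """Observed C-pair count vs the null in which both layers are rewired
    independently per replicate and re-intersected.

    ``ct_null="direct"`` (default) rewires the CT layer as an undirected
    graph; ``"bipartite"`` instead rewires the TF->target graph (``reg``
    required) and re-derives CT, which confines the null to CT layers a TF
    assignment could actually generate.  The empirical p uses the add-one
    estimator ``(1 + #{null >= observed}) / (1 + n_randomizations)``; the
    null sd uses the n-1 denominator.
    """
    if len(net.ct) == 0 or len(net.ppi) == 0:
        raise ValueError("both layers must contain edges")
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be positive")
    if ct_null not in ("direct", "bipartite"):
        raise ValueError(f"unknown ct_null {ct_null!r}")
    if ct_null == "bipartite" and reg is None:
        raise ValueError("bipartite CT null requires the regulatory interactions")
    n_real = len(find_cpairs(net))
    ct_edges = net.ct.sorted_edges()
    ppi_edges = net.ppi.sorted_edges()
    universe = net.gene_set
    counts = []
    for rep in range(n_randomizations):
        rng = np.random.default_rng(derive_seed(seed, "cpair-null", str(rep)))
        if ct_null == "direct":
            rct = set(_attempt_swaps(ct_edges, rng, swap_factor * len(ct_edges)))
        else:
            from .network_io import derive_ct_edges

            interactions = _attempt_bipartite_swaps(
                sorted(reg.interactions), rng, swap_factor * len(reg)
            )
            derived = derive_ct_edges(
                RegulatoryInteractionSet(frozenset(interactions))
            )
            rct = {
                e for e in derived.edges if e[0] in universe and e[1] in universe
            }
        rppi = _attempt_swaps(ppi_edges, rng, swap_factor * len(ppi_edges))
        counts.append(len(rct & set(rppi)))
    arr = np.asarray(counts)
    null_mean = float(arr.mean())
    null_sd = float(arr.std(ddof=1)) if n_randomizations > 1 else 0.0
    z = z_score(n_real, null_mean, null_sd)
    if math.isnan(z):
        logger.warning("degenerate null (sd = 0); Z-score undefined")
    empirical_p = (1 + int((arr >= n_real).sum())) / (1 + n_randomizations)
    return RandomizationSummary(
        n_real=n_real,
        null_counts=tuple(counts),
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        n_randomizations=n_randomizations,
        empirical_p=empirical_p,
    )


# ---------------------------------------------------------------------------
# functional coherence
# ---------------------------------------------------------------------------


def coherence_fraction(
    pairs: Iterable[tuple[str, str]],
    annotation: AnnotationTable,
    background: str = "general",
    dag: GoDag | None = None,
) -> float:
    """Fraction of gene pairs whose members share at least one GO term.

    ``background="general"`` uses all annotated terms; ``"narrow"`` keeps only
    leaf terms — terms with no child among the retained (annotated) terms —
    and needs the DAG.
    """
    pair_list = list(pairs)
    if not pair_list:
        raise ValueError("empty pair set")
    gene_terms = annotation.gene_to_terms()
    if background == "narrow":
        if dag is None:
            raise ValueError("narrow background requires the GO DAG")
        retained = annotation.terms
        leaves = {t for t in retained if t in dag and not (dag.children(t) & retained)}
        gene_terms = {g: ts & leaves for g, ts in gene_terms.items()}
    elif background != "general":
        raise ValueError(f"unknown background {background!r}")
    n_coherent = sum(
        1
        for a, b in pair_list
        if gene_terms.get(a, set()) & gene_terms.get(b, set())
    )
    return n_coherent / len(pair_list)


@dataclass(frozen=True)
class CoherenceTestInput:
    """Hypergeometric setup for the coherence comparison: of M population
    pairs K are coherent; drawing N C-pairs observed x coherent ones."""

    x: int
    M: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.M and 0 <= self.N <= self.M):
            raise ValueError("require 0 <= K, N <= M")
        if not (0 <= self.x <= min(self.N, self.K)):
            raise ValueError("require 0 <= x <= min(N, K)")


def coherence_hypergeometric_p(inp: CoherenceTestInput) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeometric(M, K, N)."""
    return float(stats.hypergeom.sf(inp.x - 1, inp.M, inp.K, inp.N))
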