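"""GO-defined functional-module catalog, the Mantel scan over modules, the
ascendant/descendant hierarchy analysis, and the CT-PPI module selection rule.

A functional module is the gene set annotated (directly or via descendants)
to one GO term, restricted to the integrated network, kept when it has at
least ``min_genes`` genes and sits at DAG layer >= ``min_depth`` (root =
layer 1).  A module is a CT-PPI module when its CT/PPI sub-networks are
significantly consistent (Mantel p < alpha and BH q < q_max), its r exceeds
``r_min``, and it is a descendant or isolated term among the significant set.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace

from .mantel import (
    MantelResult,
    adjacency_pair,
    bh_fdr,
    mantel_permutation_test,
)
from .network import IntegratedNetwork
from .ontology import AnnotationTable, GoDag
from .seeding import derive_seed

logger = logging.getLogger(__name__)

CLASS_DESCENDANT = "descendant"
CLASS_ASCENDANT = "ascendant"
CLASS_ISOLATED = "isolated"


@dataclass(frozen=True)
class FunctionalModule:
    term_id: str
    namespace: str
    genes: frozenset[str]
    depth: int

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ModuleCatalog:
    modules: tuple[FunctionalModule, ...]
    dag: GoDag

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def by_term(self) -> dict[str, FunctionalModule]:
        return {m.term_id: m for m in self.modules}


@dataclass(frozen=True)
class HierarchyPair:
    ascendant: str
    descendant: str
    r_ascendant: float
    r_descendant: float


@dataclass(frozen=True)
class ModuleClassification:
    term_id: str
    klass: str
    selected: bool


def build_module_catalog(
    annotation: AnnotationTable,
    dag: GoDag,
    network_genes: set[str],
    min_genes: int = 10,
    min_depth: int = 6,
    propagate: bool = True,
    depth_method: str = "longest",
) -> ModuleCatalog:
    """Build the filtered module catalog.

    Annotations are intersected with the network gene universe and (by
    default) propagated to ancestor terms per the true-path rule.  Modules
    with fewer than ``min_genes`` genes or at a layer shallower than
    ``min_depth`` are dropped.  When an ancestor and a descendant term carry
    identical gene sets, the descendant is kept.
    """
    network_genes = set(network_genes)
    direct = {
        t: genes & network_genes
        for t, genes in annotation.term_to_genes().items()
        if t in dag
    }
    if propagate:
        term_genes: dict[str, set[str]] = defaultdict(set)
        for t, genes in direct.items():
            term_genes[t] |= genes
            for anc in dag.ancestors(t):
                term_genes[anc] |= genes
    else:
        term_genes = {t: set(g) for t, g in direct.items()}

    modules = []
    for t in sorted(term_genes):
        genes = term_genes[t]
        depth = dag.depth(t, depth_method)
        if len(genes) >= min_genes and depth >= min_depth:
            modules.append(
                FunctionalModule(t, dag.namespace(t), frozenset(genes), depth)
            )

    # ancestor/descendant duplicates with identical gene sets -> keep descendant
    by_geneset: dict[frozenset, list[str]] = defaultdict(list)
    for m in modules:
        by_geneset[m.genes].append(m.term_id)
    dropped = set()
    for terms in by_geneset.values():
        if len(terms) < 2:
            continue
        for anc in terms:
            if any(t != anc and dag.is_ancestor(anc, t) for t in terms):
                dropped.add(anc)
    modules = [m for m in modules if m.term_id not in dropped]
    if not modules:
        raise ValueError("no functional module survives the size/depth filters")
    modules.sort(key=lambda m: (m.namespace, m.term_id))
    logger.info(
        "module catalog: %d modules (%d BP, %d CC), %d ancestor duplicates dropped",
        len(modules),
        sum(m.namespace == "BP" for m in modules),
        sum(m.namespace == "CC" for m in modules),
        len(dropped),
    )
    return ModuleCatalog(tuple(modules), dag)


def scan_modules(
    net: IntegratedNetwork,
    catalog: ModuleCatalog,
    n_permutations: int = 10000,
    seed: int = 0,
    alpha: float = 0.01,
    q_max: float = 0.05,
) -> list[tuple[FunctionalModule, MantelResult]]:
    """Per-module Mantel test of CT-vs-PPI sub-network consistency.

    BH-FDR q-values are computed across testable modules only; untestable
    modules are carried with their status and never enter the ranking.
    """
    results: list[tuple[FunctionalModule, MantelResult]] = []
    for mod in catalog.modules:
        pair = adjacency_pair(net, mod.genes)
        res = mantel_permutation_test(
            pair, n_permutations, derive_seed(seed, "scan", mod.term_id)
        )
        results.append((mod, res))
    tested_idx = [i for i, (_, r) in enumerate(results) if r.tested]
    if tested_idx:
        qvals = bh_fdr([results[i][1].p for i in tested_idx])
        for i, q in zip(tested_idx, qvals):
            mod, res = results[i]
            results[i] = (mod, replace(res, q=float(q)))
    n_sig = sum(
        1 for _, r in results if is_significant(r, alpha, q_max)
    )
    logger.info(
        "scan: %d modules, %d testable, %d significant (p < %g, q < %g)",
        len(results),
        len(tested_idx),
        n_sig,
        alpha,
        q_max,
    )
    return results


def is_significant(res: MantelResult, alpha: float = 0.01, q_max: float = 0.05) -> bool:
    return res.tested and res.p < alpha and res.q is not None and res.q < q_max


def hierarchy_pairs(
    significant_terms, dag: GoDag, r_by_term: dict[str, float]
) -> list[HierarchyPair]:
    """All ordered (ascendant, descendant) couples among the significant
    terms, with ancestry taken transitively in the is_a DAG."""
    terms = sorted(set(significant_terms))
    for t in terms:
        if t not in dag:
            raise ValueError(f"term {t!r} absent from the DAG")
    pairs = []
    for desc in terms:
        ancestors = dag.ancestors(desc)
        for asc in terms:
            if asc != desc and asc in ancestors:
                pairs.append(
                    HierarchyPair(asc, desc, r_by_term[asc], r_by_term[desc])
                )
    pairs.sort(key=lambda p: (p.ascendant, p.descendant))
    return pairs


def hierarchy_violations(pairs: list[HierarchyPair]) -> list[HierarchyPair]:
    """Pairs where the descendant's r is *not* greater than the ascendant's —
    the exception the hierarchy analysis merely records, never enforces."""
    return [p for p in pairs if p.r_descendant <= p.r_ascendant]


def classify_terms(
    r_by_term: dict[str, float],
    pairs: list[HierarchyPair],
    r_min: float = 0.2,
) -> list[ModuleClassification]:
    """Classify significant terms and apply the CT-PPI selection rule.

    A term is selected iff its r is strictly above ``r_min`` and it is a
    descendant or isolated term within the compared set.  Chains of
    candidates resolve to the DAG-deepest term: a candidate that is an
    ascendant of another candidate is not selected.
    """
    in_pairs: set[str] = set()
    appears_descendant: set[str] = set()
    descendants_of: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        in_pairs.update((p.ascendant, p.descendant))
        appears_descendant.add(p.descendant)
        descendants_of[p.ascendant].add(p.descendant)

    candidates = {
        t
        for t, r in r_by_term.items()
        if r > r_min and (t not in in_pairs or t in appears_descendant)
    }
    selected = {t for t in candidates if not (descendants_of.get(t, set()) & candidates)}

    classifications = []
    for t in sorted(r_by_term):
        if t not in in_pairs:
            klass = CLASS_ISOLATED
        elif t in appears_descendant and not (descendants_of.get(t, set()) & selected):
            klass = CLASS_DESCENDANT
        else:
            klass = CLASS_ASCENDANT
        classifications.append(ModuleClassification(t, klass, t in selected))
    return classifications


def select_ctppi_modules(
    scan_results: list[tuple[FunctionalModule, MantelResult]],
    pairs: list[HierarchyPair],
    r_min: float = 0.2,
    alpha: float = 0.01,
    q_max: float = 0.05,
) -> list[ModuleClassification]:
    """CT-PPI module selection over a Mantel scan: significant modules are
    classified by hierarchy and selected per :func:`classify_terms`."""
    r_by_term = {
        m.term_id: res.r
        for m, res in scan_results
        if is_significant(res, alpha, q_max)
    }
    classifications = classify_terms(r_by_term, pairs, r_min)
    logger.info(
        "selection: %d significant, %d above r > %g, %d CT-PPI modules",
        len(r_by_term),
        sum(1 for r in r_by_term.values() if r > r_min),
        sum(1 for c in classifications if c.selected),
    )
    return classifications
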