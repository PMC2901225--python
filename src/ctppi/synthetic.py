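"""Synthetic study generator: null two-layer networks, planted
high-consistency modules, and a toy GO catalog with known ground truth.

The null model draws each TF's targets uniformly without replacement and PPI
edges independently per gene pair, so the two layers are statistically
independent — exactly the null the Mantel permutation p assumes.  A planted
module adds a dedicated TF over a gene subset (a CT clique, the way real CT
layers arise from shared regulators) and mirrors a controlled fraction of
those CT pairs as PPI edges; the mirrored pairs are the planted C-pairs.

Planted terms are annotated with the clique genes plus a few padded network
genes that are *not* co-regulated by the planted TF.  Real GO modules are
never perfectly co-regulated, and without the padding the planted CT
sub-matrix would be constant (an all-ones clique), which the Mantel test
rightly declares untestable.  The number of padding genes also bounds the
smallest attainable permutation p: every relabeling that maps the clique
onto itself ties the observed r, so with a size-s clique and k padding genes
the tie floor is about s!.k!/(s+k)!; k must be large enough that this floor
sits well below the significance threshold divided by the catalog size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import CT, PPI, EdgeLayer, IntegratedNetwork, RegulatoryInteractionSet
from .network_io import (
    build_integrated_network,
    derive_ct_edges,
    write_annotation_tsv,
    write_dag_tsv,
    write_edge_layer_tsv,
    write_regulatory_tsv,
)
from .ontology import AnnotationTable, GoDag
from .seeding import derive_seed

logger = logging.getLogger(__name__)


def gene_ids(n_genes: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n_genes)]


def simulate_null_network(
    n_genes: int = 150,
    n_tfs: int = 12,
    targets_per_tf: int = 15,
    ppi_edge_prob: float = 0.02,
    seed: int = 0,
) -> tuple[RegulatoryInteractionSet, EdgeLayer]:
    """Independent CT and PPI layers with no planted structure."""
    if min(n_genes, n_tfs, targets_per_tf) <= 0:
        raise ValueError("sizes must be positive")
    if targets_per_tf > n_genes:
        raise ValueError("targets_per_tf cannot exceed n_genes")
    if not 0.0 <= ppi_edge_prob < 1.0:
        raise ValueError("ppi_edge_prob must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = gene_ids(n_genes)
    interactions = set()
    for t in range(n_tfs):
        tf = f"tf{t:02d}"
        for i in rng.choice(n_genes, size=targets_per_tf, replace=False):
            interactions.add((tf, genes[i]))
    iu = np.triu_indices(n_genes, 1)
    mask = rng.random(len(iu[0])) < ppi_edge_prob
    ppi_edges = frozenset(
        (genes[i], genes[j]) for i, j in zip(iu[0][mask], iu[1][mask])
    )
    return RegulatoryInteractionSet(frozenset(interactions)), EdgeLayer(PPI, ppi_edges)


def plant_module(
    reg: RegulatoryInteractionSet,
    ppi: EdgeLayer,
    gene_subset,
    overlap_fraction: float,
    seed: int,
    tf_id: str = "tf_planted",
) -> tuple[RegulatoryInteractionSet, EdgeLayer, frozenset[tuple[str, str]]]:
    """Add a dedicated TF over ``gene_subset`` (a CT clique) and mirror
    ``overlap_fraction`` of the clique pairs as PPI edges (round-half-even).

    Returns the modified inputs and the planted C-pair set.
    """
    subset = sorted(set(gene_subset))
    if len(subset) < 3:
        raise ValueError("planted module needs at least 3 genes")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    interactions = reg.interactions | {(tf_id, g) for g in subset}
    clique = [
        (a, b) for i, a in enumerate(subset) for b in subset[i + 1 :]
    ]
    n_mirror = round(overlap_fraction * len(clique))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(clique), size=n_mirror, replace=False)
    planted_pairs = frozenset(clique[i] for i in chosen)
    return (
        RegulatoryInteractionSet(frozenset(interactions)),
        EdgeLayer(PPI, ppi.edges | planted_pairs),
        planted_pairs,
    )


def make_toy_catalog(
    genes,
    planted: dict[str, frozenset[str]],
    n_decoys: int = 20,
    seed: int = 0,
    decoy_size: tuple[int, int] = (12, 18),
    leaf_depth: int = 7,
    decoy_pool=None,
    with_ancestors: bool = False,
    ancestor_extra_genes: int = 3,
) -> tuple[AnnotationTable, GoDag]:
    """Small two-namespace GO catalog: every term is a leaf at ``leaf_depth``
    on its own chain from the namespace root, so hierarchy/depth logic is
    exercised while the filtered catalog contains exactly the leaves.

    ``planted`` maps term ids to their annotated gene sets (BP).  Decoy terms
    are annotated to random gene sets from ``decoy_pool`` (defaults to all
    genes), alternating BP/CC.  ``with_ancestors`` additionally annotates the
    depth-6 chain node above each planted term with a few extra genes; with
    annotation propagation its module is a strict superset of the planted
    one, creating an ascendant/descendant pair.
    """
    genes = sorted(genes)
    rng = np.random.default_rng(seed)
    namespaces: dict[str, str] = {}
    parent_edges: set[tuple[str, str]] = set()
    records: set[tuple[str, str, str]] = set()

    def add_chain(term: str, ns: str) -> None:
        root = f"GO:ROOT_{ns}"
        namespaces[root] = ns
        prev = root
        for level in range(2, leaf_depth):
            node = f"{term}_L{level}"
            namespaces[node] = ns
            parent_edges.add((node, prev))
            prev = node
        namespaces[term] = ns
        parent_edges.add((term, prev))

    planted_genes: set[str] = set()
    for term in sorted(planted):
        planted_genes |= set(planted[term])
    for term in sorted(planted):
        add_chain(term, "BP")
        records |= {(g, term, "BP") for g in planted[term]}
        if with_ancestors:
            anc = f"{term}_L{leaf_depth - 1}"
            extra_pool = [g for g in genes if g not in planted[term]]
            extras = rng.choice(len(extra_pool), size=ancestor_extra_genes, replace=False)
            records |= {(extra_pool[i], anc, "BP") for i in extras}

    pool = sorted(set(decoy_pool) - planted_genes) if decoy_pool is not None else [
        g for g in genes if g not in planted_genes
    ]
    for d in range(n_decoys):
        ns = "BP" if d % 2 == 0 else "CC"
        term = f"GO:DEC{d:03d}"
        add_chain(term, ns)
        size = int(rng.integers(decoy_size[0], decoy_size[1] + 1))
        members = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
        records |= {(pool[i], term, ns) for i in members}

    return AnnotationTable(frozenset(records)), GoDag(namespaces, parent_edges)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedModuleTruth:
    term_id: str
    clique_genes: frozenset[str]
    annotated_genes: frozenset[str]
    overlap_fraction: float
    planted_pairs: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class SyntheticTruth:
    planted: tuple[PlantedModuleTruth, ...]
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def planted_terms(self) -> set[str]:
        return {p.term_id for p in self.planted}

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "params": self.params,
            "planted": [
                {
                    "term_id": p.term_id,
                    "clique_genes": sorted(p.clique_genes),
                    "annotated_genes": sorted(p.annotated_genes),
                    "overlap_fraction": p.overlap_fraction,
                    "planted_pairs": [list(e) for e in sorted(p.planted_pairs)],
                }
                for p in self.planted
            ],
        }


@dataclass(frozen=True)
class StudyInputs:
    reg: RegulatoryInteractionSet
    ppi: EdgeLayer
    annotation: AnnotationTable
    dag: GoDag
    truth: SyntheticTruth

    def integrated_network(self) -> IntegratedNetwork:
        return build_integrated_network(
            derive_ct_edges(self.reg), self.ppi, self.annotation.genes
        )


def simulate_study(
    seed: int = 0,
    n_genes: int = 150,
    n_tfs: int = 12,
    targets_per_tf: int = 15,
    ppi_edge_prob: float = 0.02,
    n_planted: int = 2,
    module_size: int = 12,
    overlap: float = 0.9,
    n_decoys: int = 20,
    annotation_padding: int = 5,
    with_ancestors: bool = False,
) -> StudyInputs:
    """Full synthetic study: a null two-layer network with ``n_planted``
    high-consistency modules among ``n_decoys`` decoy GO terms.

    Module, padding, and decoy genes are drawn from genes that already carry
    both link types in the null layers, so annotated module genes survive the
    integrated-network restriction.
    """
    reg, ppi = simulate_null_network(
        n_genes, n_tfs, targets_per_tf, ppi_edge_prob, derive_seed(seed, "null-net")
    )
    ct = derive_ct_edges(reg)
    eligible = sorted(ct.genes() & ppi.genes())
    need = n_planted * (module_size + annotation_padding)
    if len(eligible) < need + module_size:
        raise ValueError(
            f"only {len(eligible)} genes carry both link types; "
            f"need at least {need + module_size}"
        )
    rng = np.random.default_rng(derive_seed(seed, "plant-draw"))
    pool = [eligible[i] for i in rng.permutation(len(eligible))]

    planted_records = []
    planted_annotation: dict[str, frozenset[str]] = {}
    cursor = 0
    for k in range(n_planted):
        term = f"GO:PLANT{k + 1}"
        clique = frozenset(pool[cursor : cursor + module_size])
        cursor += module_size
        padding = frozenset(pool[cursor : cursor + annotation_padding])
        cursor += annotation_padding
        reg, ppi, pairs = plant_module(
            reg,
            ppi,
            clique,
            overlap,
            derive_seed(seed, "plant", term),
            tf_id=f"tfP{k + 1}",
        )
        annotated = clique | padding
        planted_annotation[term] = annotated
        planted_records.append(
            PlantedModuleTruth(term, clique, annotated, overlap, pairs)
        )

    annotation, dag = make_toy_catalog(
        gene_ids(n_genes),
        planted_annotation,
        n_decoys=n_decoys,
        seed=derive_seed(seed, "catalog"),
        decoy_pool=pool[cursor:],
        with_ancestors=with_ancestors,
    )
    truth = SyntheticTruth(
        planted=tuple(planted_records),
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_tfs": n_tfs,
            "targets_per_tf": targets_per_tf,
            "ppi_edge_prob": ppi_edge_prob,
            "n_planted": n_planted,
            "module_size": module_size,
            "overlap": overlap,
            "n_decoys": n_decoys,
            "annotation_padding": annotation_padding,
        },
    )
    return StudyInputs(reg, ppi, annotation, dag, truth)


def write_study(study: StudyInputs, outdir) -> dict[str, Path]:
    """Write the three pipeline inputs plus the truth record to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "regulatory": outdir / "regulatory.tsv",
        "ppi": outdir / "ppi.tsv",
        "annotation": outdir / "annotation.tsv",
        "go_dag": outdir / "go_dag.tsv",
        "truth": outdir / "truth.json",
    }
    write_regulatory_tsv(study.reg, paths["regulatory"])
    write_edge_layer_tsv(study.ppi, paths["ppi"])
    write_annotation_tsv(study.annotation, paths["annotation"])
    write_dag_tsv(study.dag, paths["go_dag"])
    paths["truth"].write_text(json.dumps(study.truth.to_dict(), indent=2, sort_keys=True))
    logger.info("wrote synthetic study to %s", outdir)
    return paths
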