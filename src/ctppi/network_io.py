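"""Readers and writers for the delimited interchange formats, CT derivation,
and assembly of the integrated two-layer network.

All tabular inputs are whitespace/tab-delimited text with ``#`` comment lines;
a single header line is tolerated when its first field is a recognizable
column token (``tf`` / ``geneA`` / ``gene_a``).
"""

from __future__ import annotations

import io
import logging
import os
from typing import Iterable, Iterator, TextIO

import networkx as nx

from .network import (
    CT,
    PPI,
    EdgeLayer,
    IntegratedNetwork,
    RegulatoryInteractionSet,
    canonical_pair,
)
from .ontology import AnnotationTable, GoDag, normalize_namespace

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {"tf", "genea", "gene_a", "gene", "child", "term"}


def _open_text(source) -> tuple[TextIO, bool]:
    """Accept a path or an open text stream; returns (stream, should_close)."""
    if isinstance(source, (str, os.PathLike)):
        return open(source, "rt", encoding="utf-8"), True
    return source, False


def _iter_fields(source, min_fields: int) -> Iterator[tuple[int, list[str]]]:
    stream, close = _open_text(source)
    try:
        first_data_line = True
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields]
            if first_data_line and fields[0].lower() in _HEADER_TOKENS:
                first_data_line = False
                continue
            first_data_line = False
            if len(fields) < min_fields or any(not f for f in fields[:min_fields]):
                raise ValueError(
                    f"malformed line {lineno}: expected >= {min_fields} fields, got {line!r}"
                )
            yield lineno, fields
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# regulatory / PPI readers and the CT derivation
# ---------------------------------------------------------------------------


def read_regulatory_interactions(source) -> RegulatoryInteractionSet:
    """Read TF<TAB>target interactions, collapsing duplicates."""
    interactions = set()
    n_rows = 0
    for _, fields in _iter_fields(source, 2):
        interactions.add((fields[0], fields[1]))
        n_rows += 1
    if not interactions:
        raise ValueError("regulatory input contains no interactions")
    logger.info(
        "read %d unique TF-target interactions (%d rows, %d TFs, %d targets)",
        len(interactions),
        n_rows,
        len({tf for tf, _ in interactions}),
        len({t for _, t in interactions}),
    )
    return RegulatoryInteractionSet(frozenset(interactions))


def read_ppi_edges(source) -> EdgeLayer:
    """Read an undirected PPI edge list; self-pairs (homomultimers) dropped,
    unordered duplicates collapsed."""
    pairs = []
    for _, fields in _iter_fields(source, 2):
        pairs.append((fields[0], fields[1]))
    layer = EdgeLayer.from_pairs(PPI, pairs, drop_self=True)
    if not layer.edges:
        logger.warning("PPI input yielded no edges")
    else:
        logger.info("read %d unique PPI edges over %d genes", len(layer), len(layer.genes()))
    return layer


def derive_ct_edges(reg: RegulatoryInteractionSet) -> EdgeLayer:
    """Co-transcriptional-regulation layer: {a, b} is a CT edge iff some TF
    regulates both a and b (each TF contributes the clique over its targets)."""
    if not reg.interactions:
        raise ValueError("empty regulatory interaction set")
    edges: set[tuple[str, str]] = set()
    for targets in reg.targets_by_tf().values():
        ts = sorted(targets)
        for i, a in enumerate(ts):
            for b in ts[i + 1 :]:
                edges.add((a, b))
    logger.info("derived %d CT edges from %d TFs", len(edges), len(reg.tfs))
    return EdgeLayer(CT, frozenset(edges))


def build_integrated_network(
    ct: EdgeLayer, ppi: EdgeLayer, annotated_genes: set[str]
) -> IntegratedNetwork:
    """Restrict both layers to annotated genes carrying at least one link of
    each type, iterating to a fixed point (an edge drop may strand a gene)."""
    if not annotated_genes:
        raise ValueError("no annotated genes supplied")
    universe = ct.genes() & ppi.genes() & set(annotated_genes)
    while True:
        ct_r = ct.restricted_to(universe)
        ppi_r = ppi.restricted_to(universe)
        new_universe = ct_r.genes() & ppi_r.genes()
        if new_universe == universe:
            break
        universe = new_universe
    if not universe:
        raise ValueError("integrated network is empty after restriction")
    net = IntegratedNetwork(tuple(sorted(universe)), ct_r, ppi_r)
    logger.info(
        "integrated network: %d genes, %d CT edges, %d PPI edges",
        len(net.genes),
        len(net.ct),
        len(net.ppi),
    )
    return net


# ---------------------------------------------------------------------------
# GO inputs
# ---------------------------------------------------------------------------


def _looks_like_obo(source) -> tuple[bool, object]:
    """Sniff OBO vs TSV; returns (is_obo, reusable_source)."""
    stream, close = _open_text(source)
    text = stream.read()
    if close:
        stream.close()
    head = text[:4096]
    is_obo = "[Term]" in head or head.lstrip().startswith("format-version")
    return is_obo, io.StringIO(text)


def read_go_dag(source) -> GoDag:
    """Read a GO DAG from an OBO v1.2 file (is_a only) or a
    child<TAB>parent<TAB>namespace edge list."""
    is_obo, stream = _looks_like_obo(source)
    if is_obo:
        return GoDag.from_obo(stream)
    rows = []
    for _, fields in _iter_fields(stream, 3):
        rows.append((fields[0], fields[1], fields[2]))
    return GoDag.from_edge_rows(rows)


def read_annotations(source, dag: GoDag) -> AnnotationTable:
    """Read gene->term annotations (2-column TSV or GAF 2.x rows).

    GAF rows use columns 2 (object symbol), 5 (GO id) and 9 (aspect).
    Annotations to terms absent from the DAG are dropped with a warning;
    molecular_function rows are dropped.
    """
    records = set()
    n_unknown = 0
    for lineno, fields in _iter_fields(source, 2):
        if len(fields) >= 15:  # GAF 2.x data row
            gene, term, aspect = fields[1], fields[4], fields[8]
            if normalize_namespace(aspect) is None:
                continue
        else:
            gene, term = fields[0], fields[1]
        if term not in dag:
            n_unknown += 1
            continue
        records.add((gene, term, dag.namespace(term)))
    if n_unknown:
        logger.warning("dropped %d annotations to terms absent from the DAG", n_unknown)
    logger.info("kept %d annotation records", len(records))
    return AnnotationTable(frozenset(records))


def load_go_inputs(annotation_source, dag_source) -> tuple[AnnotationTable, GoDag]:
    dag = read_go_dag(dag_source)
    table = read_annotations(annotation_source, dag)
    return table, dag


# ---------------------------------------------------------------------------
# writers (interchange TSVs, GraphML)
# ---------------------------------------------------------------------------


def write_regulatory_tsv(reg: RegulatoryInteractionSet, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# tf\ttarget\n")
        for tf, target in sorted(reg.interactions):
            fh.write(f"{tf}\t{target}\n")


def write_edge_layer_tsv(layer: EdgeLayer, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# geneA\tgeneB\n")
        for a, b in layer.sorted_edges():
            fh.write(f"{a}\t{b}\n")


def write_annotation_tsv(table: AnnotationTable, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# gene\tterm\n")
        for gene, term, _ in sorted(table.records):
            fh.write(f"{gene}\t{term}\n")


def write_dag_tsv(dag: GoDag, path) -> None:
    rows = sorted(
        (child, parent, dag.namespace(child))
        for child in dag.terms
        for parent in dag.parents(child)
    )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# child\tparent\tnamespace\n")
        for child, parent, ns in rows:
            fh.write(f"{child}\t{parent}\t{ns}\n")


def write_network_tsv(net: IntegratedNetwork, path) -> None:
    """Typed edge list: geneA<TAB>geneB<TAB>layer with layer in {CT, PPI}."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# geneA\tgeneB\tlayer\n")
        for a, b in net.ct.sorted_edges():
            fh.write(f"{a}\t{b}\t{CT}\n")
        for a, b in net.ppi.sorted_edges():
            fh.write(f"{a}\t{b}\t{PPI}\n")


def read_network_tsv(source) -> IntegratedNetwork:
    ct_edges, ppi_edges = set(), set()
    for lineno, fields in _iter_fields(source, 3):
        a, b, layer = fields[0], fields[1], fields[2]
        pair = canonical_pair(a, b)
        if layer == CT:
            ct_edges.add(pair)
        elif layer == PPI:
            ppi_edges.add(pair)
        else:
            raise ValueError(f"malformed line {lineno}: unknown layer {layer!r}")
    genes = {g for e in ct_edges | ppi_edges for g in e}
    return IntegratedNetwork(
        tuple(sorted(genes)), EdgeLayer(CT, frozenset(ct_edges)), EdgeLayer(PPI, frozenset(ppi_edges))
    )


def write_graphml(net: IntegratedNetwork, path) -> None:
    nx.write_graphml(net.to_graph(), path)
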