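"""Module catalog filters, Mantel scan, hierarchy pairing, and selection."""

from __future__ import annotations

import numpy as np
import pytest

import ctppi
from ctppi.mantel import MantelResult, STATUS_TESTED, STATUS_NO_EDGES
from ctppi.modules import (
    FunctionalModule,
    HierarchyPair,
    build_module_catalog,
    classify_terms,
    hierarchy_pairs,
    hierarchy_violations,
    is_significant,
    scan_modules,
    select_ctppi_modules,
)
from ctppi.ontology import AnnotationTable, GoDag


def chain_dag(n: int, prefix: str = "t", ns: str = "BP") -> GoDag:
    terms = [f"{prefix}{i}" for i in range(n)]
    return GoDag(
        {t: ns for t in terms},
        [(terms[i + 1], terms[i]) for i in range(n - 1)],
    )


def annotate(term_genes: dict[str, list[str]], dag: GoDag) -> AnnotationTable:
    return AnnotationTable(
        frozenset(
            (g, t, dag.namespace(t)) for t, genes in term_genes.items() for g in genes
        )
    )


GENES = [f"g{i:02d}" for i in range(30)]


class TestBuildModuleCatalog:
    def test_size_boundary_needs_ten_genes(self):
        dag = chain_dag(7)
        nine, ten = GENES[:9], GENES[:10]
        table = annotate({"t6": nine}, dag)
        with pytest.raises(ValueError):
            build_module_catalog(table, dag, set(GENES))
        table = annotate({"t6": ten}, dag)
        catalog = build_module_catalog(table, dag, set(GENES))
        assert [m.term_id for m in catalog] == ["t6"]

    def test_depth_boundary_layer_six_kept_five_dropped(self):
        dag = chain_dag(7)  # t4 is layer 5, t5 is layer 6
        table = annotate({"t4": GENES[:12], "t5": GENES[12:24]}, dag)
        catalog = build_module_catalog(table, dag, set(GENES), propagate=False)
        assert [m.term_id for m in catalog] == ["t5"]
        assert catalog.modules[0].depth == 6

    def test_network_restriction_shrinks_gene_sets(self):
        dag = chain_dag(7)
        table = annotate({"t6": GENES[:15]}, dag)
        catalog = build_module_catalog(table, dag, set(GENES[:12]))
        assert catalog.modules[0].genes == frozenset(GENES[:12])

    def test_identical_ancestor_descendant_sets_keep_descendant(self):
        dag = chain_dag(8)  # t6 (layer 7) is parent of t7 (layer 8)
        table = annotate({"t6": GENES[:12], "t7": GENES[:12]}, dag)
        catalog = build_module_catalog(table, dag, set(GENES))
        assert [m.term_id for m in catalog] == ["t7"]

    def test_propagation_adds_descendant_genes_to_ancestors(self):
        dag = chain_dag(8)
        table = annotate({"t6": GENES[:6], "t7": GENES[6:16]}, dag)
        catalog = build_module_catalog(table, dag, set(GENES))
        by_term = catalog.by_term()
        # t6 inherits t7's genes (16 total); t7 keeps its 10
        assert by_term["t6"].genes == frozenset(GENES[:16])
        assert by_term["t7"].genes == frozenset(GENES[6:16])


class TestScanModules:
    def test_module_without_internal_ppi_is_untestable(self, small_study_net):
        net = small_study_net
        dag = chain_dag(7)
        # pick module genes guaranteed to have no internal PPI edge
        genes = []
        for g in net.genes:
            if all(
                (min(g, h), max(g, h)) not in net.ppi.edges for h in genes
            ):
                genes.append(g)
            if len(genes) == 10:
                break
        table = annotate({"t6": genes}, dag)
        catalog = build_module_catalog(table, dag, net.gene_set)
        results = scan_modules(net, catalog, n_permutations=50, seed=0)
        assert results[0][1].status == STATUS_NO_EDGES
        assert results[0][1].q is None

    def test_planted_module_scores_near_minimal_p(self, small_study, small_study_net):
        cfg_alpha, cfg_q = 0.01, 0.05
        catalog = build_module_catalog(
            small_study.annotation, small_study.dag, small_study_net.gene_set
        )
        results = scan_modules(small_study_net, catalog, n_permutations=999, seed=5)
        by_term = {m.term_id: res for m, res in results}
        for term in small_study.truth.planted_terms:
            res = by_term[term]
            assert res.status == STATUS_TESTED
            assert res.r > 0.5
            assert is_significant(res, cfg_alpha, cfg_q)

    def test_seed_changes_p_but_not_r(self, small_study, small_study_net):
        catalog = build_module_catalog(
            small_study.annotation, small_study.dag, small_study_net.gene_set
        )
        r1 = scan_modules(small_study_net, catalog, n_permutations=200, seed=1)
        r2 = scan_modules(small_study_net, catalog, n_permutations=200, seed=2)
        for (m1, a), (m2, b) in zip(r1, r2):
            assert m1.term_id == m2.term_id
            assert (a.r is None and b.r is None) or a.r == pytest.approx(b.r)


class TestHierarchyPairs:
    def test_chain_gives_transitive_pairs(self):
        dag = chain_dag(3)
        r = {"t0": 0.3, "t1": 0.4, "t2": 0.5}
        pairs = hierarchy_pairs(["t0", "t1", "t2"], dag, r)
        got = {(p.ascendant, p.descendant) for p in pairs}
        assert got == {("t0", "t1"), ("t0", "t2"), ("t1", "t2")}

    def test_unrelated_terms_give_no_pairs(self):
        dag = GoDag(
            {"r": "BP", "a": "BP", "b": "BP"}, [("a", "r"), ("b", "r")]
        )
        assert hierarchy_pairs(["a", "b"], dag, {"a": 0.5, "b": 0.6}) == []

    def test_single_term_no_pairs(self):
        dag = chain_dag(2)
        assert hierarchy_pairs(["t1"], dag, {"t1": 0.9}) == []

    def test_unknown_term_raises(self):
        dag = chain_dag(2)
        with pytest.raises(ValueError):
            hierarchy_pairs(["ghost"], dag, {"ghost": 0.5})

    def test_violations_recorded_not_enforced(self):
        pairs = [
            HierarchyPair("a", "b", 0.3, 0.5),
            HierarchyPair("a", "c", 0.3, 0.2),
        ]
        assert hierarchy_violations(pairs) == [pairs[1]]


def result(r, p=0.001, q=0.01):
    return MantelResult(r=r, p=p, q=q, n_permutations=999, status=STATUS_TESTED)


def module(term):
    return FunctionalModule(term, "BP", frozenset(GENES[:10]), 7)


class TestSelection:
    def test_boundary_r_exactly_rmin_not_selected(self):
        scan = [(module("a"), result(0.2))]
        out = select_ctppi_modules(scan, [], r_min=0.2)
        assert out == [ctppi.ModuleClassification("a", "isolated", False)]

    def test_descendant_selected_over_ascendant(self):
        scan = [(module("a"), result(0.3)), (module("b"), result(0.5))]
        pairs = [HierarchyPair("a", "b", 0.3, 0.5)]
        out = {c.term_id: c for c in select_ctppi_modules(scan, pairs)}
        assert out["b"].selected and out["b"].klass == "descendant"
        assert not out["a"].selected and out["a"].klass == "ascendant"

    def test_isolated_significant_module_selected(self):
        scan = [(module("x"), result(0.61))]
        out = select_ctppi_modules(scan, [])
        assert out[0].selected and out[0].klass == "isolated"

    def test_mixed_chain_resolves_to_deepest(self):
        # chain a -> b -> c, all candidates: only the deepest (c) is selected
        scan = [
            (module("a"), result(0.3)),
            (module("b"), result(0.4)),
            (module("c"), result(0.5)),
        ]
        pairs = [
            HierarchyPair("a", "b", 0.3, 0.4),
            HierarchyPair("a", "c", 0.3, 0.5),
            HierarchyPair("b", "c", 0.4, 0.5),
        ]
        out = {c.term_id: c for c in select_ctppi_modules(scan, pairs)}
        assert [out[t].selected for t in "abc"] == [False, False, True]
        assert out["b"].klass == "ascendant"

    def test_insignificant_modules_never_classified(self):
        scan = [
            (module("a"), result(0.9)),
            (module("b"), MantelResult(0.9, 0.2, 0.3, 999, STATUS_TESTED)),
        ]
        out = select_ctppi_modules(scan, [])
        assert [c.term_id for c in out] == ["a"]

    def test_classify_terms_descendant_without_candidate_ancestor(self):
        # b's ascendant a falls below r_min: b still selected as descendant
        pairs = [HierarchyPair("a", "b", 0.1, 0.5)]
        out = {c.term_id: c for c in classify_terms({"a": 0.1, "b": 0.5}, pairs)}
        assert out["b"].selected
        assert not out["a"].selected
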