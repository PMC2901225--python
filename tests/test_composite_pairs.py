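"""C-pair detection, degree-preserving randomization, and coherence tests."""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np
import pytest

import ctppi
from ctppi.composite_pairs import (
    CoherenceTestInput,
    coherence_fraction,
    coherence_hypergeometric_p,
    cpair_significance,
    find_cpairs,
    randomize_layer,
    z_score,
)
from ctppi.network import CT, PPI, EdgeLayer, IntegratedNetwork
from ctppi.ontology import AnnotationTable, GoDag

from conftest import random_layer


def two_layer_net(ct_pairs, ppi_pairs) -> IntegratedNetwork:
    ct = EdgeLayer.from_pairs(CT, ct_pairs)
    ppi = EdgeLayer.from_pairs(PPI, ppi_pairs)
    return ctppi.build_integrated_network(ct, ppi, ct.genes() | ppi.genes())


class TestFindCpairs:
    def test_shared_edge_is_cpair(self, triangle_net):
        assert len(find_cpairs(triangle_net)) == 3

    def test_random_two_layer_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(10)]

        def rand_pairs(p):
            return [
                (a, b)
                for a, b in itertools.combinations(genes, 2)
                if rng.random() < p
            ]

        ct, ppi = rand_pairs(0.5), rand_pairs(0.5)
        net = two_layer_net(ct, ppi)
        got = find_cpairs(net).pairs
        oracle = {
            tuple(sorted(p))
            for p in itertools.combinations(net.genes, 2)
            if tuple(sorted(p)) in net.ct.edges and tuple(sorted(p)) in net.ppi.edges
        }
        assert got == frozenset(oracle)

    def test_relabeling_equivariance(self, small_study_net):
        net = small_study_net
        mapping = {g: f"x{i:04d}" for i, g in enumerate(reversed(net.genes))}

        def relabel_layer(layer):
            return EdgeLayer.from_pairs(
                layer.kind, [(mapping[a], mapping[b]) for a, b in layer.edges]
            )

        relabeled = IntegratedNetwork(
            tuple(sorted(mapping.values())),
            relabel_layer(net.ct),
            relabel_layer(net.ppi),
        )
        expected = {
            tuple(sorted((mapping[a], mapping[b])))
            for a, b in find_cpairs(net).pairs
        }
        assert find_cpairs(relabeled).pairs == frozenset(expected)


class TestRandomizeLayer:
    def test_single_edge_unchanged(self):
        layer = EdgeLayer.from_pairs(PPI, [("a", "b")])
        assert randomize_layer(layer, seed=0).edges == layer.edges

    def test_star_is_rigid(self):
        layer = EdgeLayer.from_pairs(PPI, [("a", "b"), ("a", "c"), ("a", "d")])
        assert randomize_layer(layer, seed=1).edges == layer.edges

    def test_path_degrees_preserved_and_output_is_valid_realization(self):
        layer = EdgeLayer.from_pairs(
            PPI, [("a", "b"), ("b", "c"), ("c", "d")]
        )
        want = layer.degrees()
        # enumeration oracle: all simple graphs on these 4 nodes with the
        # same per-node degrees
        nodes = sorted(layer.genes())
        realizations = set()
        for edges in itertools.combinations(itertools.combinations(nodes, 2), 3):
            deg = {n: 0 for n in nodes}
            for a, b in edges:
                deg[a] += 1
                deg[b] += 1
            if deg == want:
                realizations.add(frozenset(edges))
        for seed in range(20):
            out = randomize_layer(layer, seed=seed)
            assert out.degrees() == want
            assert frozenset(out.edges) in realizations

    def test_degree_preservation_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for seed in range(25):
            layer = random_layer(rng, n_genes=20, n_edges=30)
            out = randomize_layer(layer, seed=seed, swap_factor=20)
            assert out.degrees() == layer.degrees()

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(0)
        layer = random_layer(rng, 15, 25)
        assert randomize_layer(layer, 9).edges == randomize_layer(layer, 9).edges


class TestRandomizeRegulatory:
    def test_bipartite_degrees_preserved(self):
        for seed in range(10):
            reg, _ = ctppi.simulate_null_network(
                n_genes=30, n_tfs=5, targets_per_tf=6, ppi_edge_prob=0.0, seed=seed
            )
            out = ctppi.randomize_regulatory(reg, seed=seed, swap_factor=20)
            by_tf = {t: len(g) for t, g in reg.targets_by_tf().items()}
            assert {t: len(g) for t, g in out.targets_by_tf().items()} == by_tf
            in_deg = lambda r: {
                g: sum(1 for _, t in r.interactions if t == g) for g in r.targets
            }
            assert in_deg(out) == in_deg(reg)

    def test_bipartite_ct_null_runs_and_requires_reg(self):
        reg, ppi = ctppi.simulate_null_network(
            n_genes=30, n_tfs=4, targets_per_tf=5, ppi_edge_prob=0.1, seed=2
        )
        ct = ctppi.derive_ct_edges(reg)
        net = ctppi.build_integrated_network(ct, ppi, ct.genes() | ppi.genes())
        summary = cpair_significance(
            net, n_randomizations=30, seed=0, swap_factor=10,
            ct_null="bipartite", reg=reg,
        )
        assert summary.n_randomizations == 30
        assert 0 < summary.empirical_p <= 1
        with pytest.raises(ValueError, match="regulatory"):
            cpair_significance(net, 5, 0, 10, ct_null="bipartite")


class TestCpairSignificance:
    def test_zscore_formula(self):
        assert z_score(168, 109.8, 9.66) == pytest.approx(6.0248, abs=1e-4)
        assert math.isnan(z_score(5, 5.0, 0.0))

    def test_single_edge_layers_degenerate_null(self):
        net = two_layer_net([("a", "b")], [("a", "b")])
        summary = cpair_significance(net, n_randomizations=50, seed=0)
        assert summary.null_counts == (1,) * 50
        assert math.isnan(summary.z_score)
        assert summary.empirical_p == 1.0

    def test_null_mean_matches_exhaustive_enumeration(self):
        # 6-node network: CT path, PPI perfect matching
        ct_pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f")]
        ppi_pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        net = two_layer_net(ct_pairs, ppi_pairs)
        nodes = sorted(net.genes)
        all_pairs = list(itertools.combinations(nodes, 2))

        def realizations(layer):
            want = layer.degrees()
            out = []
            for edges in itertools.combinations(all_pairs, len(layer)):
                deg = dict.fromkeys(nodes, 0)
                for a, b in edges:
                    deg[a] += 1
                    deg[b] += 1
                if deg == want:
                    out.append(frozenset(edges))
            return out

        ct_real = realizations(net.ct)
        ppi_real = realizations(net.ppi)
        exact_mean = np.mean(
            [len(c & p) for c in ct_real for p in ppi_real]
        )
        summary = cpair_significance(net, n_randomizations=400, seed=3, swap_factor=50)
        se = summary.null_sd / math.sqrt(summary.n_randomizations)
        assert abs(summary.null_mean - exact_mean) <= 3 * se + 0.02

    def test_empirical_p_superuniform_on_null_networks(self):
        """On independently generated layers the C-pair test should reject at
        no more than the nominal rate (binomial bound over 100 seeds)."""
        rejections = 0
        for seed in range(100):
            reg, ppi = ctppi.simulate_null_network(
                n_genes=40, n_tfs=6, targets_per_tf=6, ppi_edge_prob=0.05, seed=seed
            )
            ct = ctppi.derive_ct_edges(reg)
            genes = ct.genes() & ppi.genes()
            net = ctppi.build_integrated_network(ct, ppi, genes)
            summary = cpair_significance(
                net, n_randomizations=99, seed=seed, swap_factor=10
            )
            rejections += summary.empirical_p <= 0.05
        # Binomial(100, 0.05): P(X >= 12) < 0.005
        assert rejections <= 11


class TestCoherence:
    @pytest.fixture
    def annotation(self):
        return AnnotationTable(
            frozenset(
                {
                    ("a", "t1", "BP"),
                    ("b", "t1", "BP"),
                    ("b", "t2", "BP"),
                    ("c", "t2", "BP"),
                    ("d", "t3", "CC"),
                }
            )
        )

    def test_shared_term_pair_is_coherent(self, annotation):
        assert coherence_fraction([("a", "b")], annotation) == 1.0

    def test_no_shared_terms_gives_zero(self, annotation):
        assert coherence_fraction([("a", "d")], annotation) == 0.0

    def test_random_pairs_match_set_intersection_oracle(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(12)]
        terms = [f"t{i}" for i in range(5)]
        records = frozenset(
            (g, t, "BP") for g in genes for t in terms if rng.random() < 0.3
        )
        table = AnnotationTable(records)
        pairs = [tuple(rng.choice(genes, 2, replace=False)) for _ in range(20)]
        g2t = table.gene_to_terms()
        oracle = sum(
            bool(g2t.get(a, set()) & g2t.get(b, set())) for a, b in pairs
        ) / len(pairs)
        assert coherence_fraction(pairs, table) == pytest.approx(oracle)

    def test_narrow_background_uses_leaf_terms_only(self, annotation):
        # t1 is the parent of t2; b and c share only the leaf t2
        dag = GoDag(
            {"t1": "BP", "t2": "BP", "t3": "CC"},
            [("t2", "t1")],
        )
        assert coherence_fraction([("a", "b")], annotation, "narrow", dag) == 0.0
        assert coherence_fraction([("b", "c")], annotation, "narrow", dag) == 1.0
        with pytest.raises(ValueError):
            coherence_fraction([("a", "b")], annotation, "narrow")

    def test_empty_pair_set_raises(self, annotation):
        with pytest.raises(ValueError):
            coherence_fraction([], annotation)


class TestCoherenceHypergeometric:
    def test_zero_observed_gives_one(self):
        assert coherence_hypergeometric_p(CoherenceTestInput(0, 20, 5, 6)) == 1.0

    def test_worked_example_matches_enumeration(self):
        # M=10, K=5, N=4, x=4 -> C(5,4)/C(10,4) = 5/210
        p = coherence_hypergeometric_p(CoherenceTestInput(4, 10, 5, 4))
        assert p == pytest.approx(comb(5, 4) / comb(10, 4), abs=1e-15)

    def test_all_successes_population(self):
        assert coherence_hypergeometric_p(CoherenceTestInput(3, 7, 7, 3)) == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            CoherenceTestInput(5, 10, 4, 6)  # x > K
        with pytest.raises(ValueError):
            CoherenceTestInput(1, 5, 6, 2)  # K > M
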