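"""Per-module characterization: C-pair enrichment in pairs space,
inner/outer link-density compactness per layer and integrated, and the
TF-regulator summary of module C-pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import groupby
from math import comb

import pandas as pd
from scipy import stats

from .composite_pairs import CompositePairSet, find_cpairs
from .modules import FunctionalModule, ModuleCatalog
from .network import EdgeLayer, IntegratedNetwork, RegulatoryInteractionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentTestInput:
    """Hypergeometric setup in pairs space: of X = C(G,2) candidate gene
    pairs in the network, Y are C-pairs; the module spans Z = C(g,2) pairs of
    which a are C-pairs."""

    a: int
    X: int
    Y: int
    Z: int

    def __post_init__(self) -> None:
        if not (0 <= self.Y <= self.X and 0 <= self.Z <= self.X):
            raise ValueError("require 0 <= Y, Z <= X")
        if not (0 <= self.a <= min(self.Y, self.Z)):
            raise ValueError("require 0 <= a <= min(Y, Z)")


def enrichment_p(inp: EnrichmentTestInput) -> float:
    """Upper-tail P(X_rv >= a) for X_rv ~ Hypergeometric(X, Y, Z)."""
    return float(stats.hypergeom.sf(inp.a - 1, inp.X, inp.Y, inp.Z))


def module_cpair_count(module_genes: frozenset[str], cpairs: CompositePairSet) -> int:
    return sum(1 for a, b in cpairs.pairs if a in module_genes and b in module_genes)


def cpair_enrichment_p(
    module: FunctionalModule,
    net: IntegratedNetwork,
    cpairs: CompositePairSet | None = None,
) -> float:
    """C-pair enrichment of a module against the whole integrated network."""
    g = module.size
    if g < 2:
        raise ValueError("module must contain at least 2 genes")
    if not module.genes <= net.gene_set:
        raise ValueError("module genes must be a subset of the network genes")
    cp = cpairs if cpairs is not None else find_cpairs(net)
    inp = EnrichmentTestInput(
        a=module_cpair_count(module.genes, cp),
        X=comb(len(net.genes), 2),
        Y=len(cp),
        Z=comb(g, 2),
    )
    return enrichment_p(inp)


# ---------------------------------------------------------------------------
# compactness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompactnessResult:
    layer_kind: str
    L_in: int
    G_in: int
    L_out: int
    G_out: int
    C_in: float
    C_out: float
    compact: bool


def compactness(
    module: FunctionalModule, layer: EdgeLayer, net: IntegratedNetwork
) -> CompactnessResult:
    """Inner vs outer link density of the module in one layer.

    L_in: links between module genes; G_in: module genes with such links;
    L_out: links between G_in genes and non-module genes; G_out: non-module
    genes carrying such links.  C_in = L_in/G_in, C_out = L_out/G_out (0 when
    the denominator is 0); compact iff C_in > C_out strictly.
    """
    if not module.genes <= net.gene_set:
        raise ValueError("module genes must be a subset of the network genes")
    inner = module.genes
    L_in = 0
    g_in: set[str] = set()
    boundary: list[tuple[str, str]] = []
    for a, b in layer.edges:
        a_in, b_in = a in inner, b in inner
        if a_in and b_in:
            L_in += 1
            g_in.update((a, b))
        elif a_in or b_in:
            boundary.append((a, b))
    # only boundary links incident to G_in genes count
    L_out = 0
    g_out: set[str] = set()
    for a, b in boundary:
        inner_gene, outer_gene = (a, b) if a in inner else (b, a)
        if inner_gene in g_in:
            L_out += 1
            g_out.add(outer_gene)
    C_in = L_in / len(g_in) if g_in else 0.0
    C_out = L_out / len(g_out) if g_out else 0.0
    return CompactnessResult(
        layer_kind=layer.kind,
        L_in=L_in,
        G_in=len(g_in),
        L_out=L_out,
        G_out=len(g_out),
        C_in=C_in,
        C_out=C_out,
        compact=C_in > C_out,
    )


def integrated_compactness(
    module: FunctionalModule, net: IntegratedNetwork
) -> tuple[CompactnessResult, CompactnessResult, bool]:
    """Compactness in each layer; the integrated sub-network is compact iff
    both layers are."""
    ct_res = compactness(module, net.ct, net)
    ppi_res = compactness(module, net.ppi, net)
    return ct_res, ppi_res, ct_res.compact and ppi_res.compact


# ---------------------------------------------------------------------------
# TF-regulator summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TfRegulatorSummary:
    """Per TF, the count of module C-pairs whose genes are both its targets;
    zero-count TFs omitted, sorted by descending count then TF id."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if any(c < 1 for _, c in self.entries):
            raise ValueError("entries must have positive counts")


def tf_regulator_summary(
    module: FunctionalModule,
    cpairs: CompositePairSet,
    reg: RegulatoryInteractionSet,
) -> TfRegulatorSummary:
    module_pairs = [
        (a, b) for a, b in cpairs.pairs if a in module.genes and b in module.genes
    ]
    entries = []
    for tf, targets in reg.targets_by_tf().items():
        n = sum(1 for a, b in module_pairs if a in targets and b in targets)
        if n:
            entries.append((tf, n))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return TfRegulatorSummary(tuple(entries))


def format_tf_summary(summary: TfRegulatorSummary) -> str:
    """Display form grouping TFs by count, e.g. ``HAP4(21)`` or
    ``HIR1,HIR2(6)SWI4(1)``."""
    parts = []
    for count, group in groupby(summary.entries, key=lambda e: e[1]):
        tfs = ",".join(sorted(tf for tf, _ in group))
        parts.append(f"{tfs}({count})")
    return "".join(parts)


# ---------------------------------------------------------------------------
# catalog-level enrichment report
# ---------------------------------------------------------------------------


def enrichment_report(
    catalog: ModuleCatalog, net: IntegratedNetwork
) -> pd.DataFrame:
    """Enrichment p per module with mean ranks (ties share the average rank)
    computed among modules that contain at least one C-pair."""
    cp = find_cpairs(net)
    rows = []
    for mod in catalog.modules:
        rows.append(
            {
                "term_id": mod.term_id,
                "n_cpairs": module_cpair_count(mod.genes, cp),
                "p": cpair_enrichment_p(mod, net, cp),
            }
        )
    df = pd.DataFrame(rows)
    with_cpairs = df["n_cpairs"] >= 1
    df["rank"] = df.loc[with_cpairs, "p"].rank(method="average")
    return df.sort_values(["p", "term_id"]).reset_index(drop=True)
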