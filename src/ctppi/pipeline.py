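"""End-to-end orchestration: read inputs, build the integrated network,
C-pair statistics, the Mantel module scan, hierarchy-aware selection, and the
per-module characterization, with deterministic seeding and TSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .composite_pairs import (
    CompositePairSet,
    RandomizationSummary,
    cpair_significance,
    find_cpairs,
)
from .mantel import MantelResult
from .modules import (
    HierarchyPair,
    ModuleCatalog,
    ModuleClassification,
    FunctionalModule,
    build_module_catalog,
    hierarchy_pairs,
    hierarchy_violations,
    is_significant,
    scan_modules,
    select_ctppi_modules,
)
from .network import IntegratedNetwork, RegulatoryInteractionSet, EdgeLayer
from .network_io import (
    build_integrated_network,
    derive_ct_edges,
    load_go_inputs,
    read_ppi_edges,
    read_regulatory_interactions,
    write_graphml,
    write_network_tsv,
)
from .ontology import AnnotationTable, GoDag
from .seeding import derive_seed
from .statistics import (
    cpair_enrichment_p,
    format_tf_summary,
    integrated_compactness,
    module_cpair_count,
    tf_regulator_summary,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, thresholds and sampling sizes; the threshold defaults are the
    published operating point of the method (p < 0.01 with q < 0.05, r > 0.2,
    10,000 Mantel permutations, 1000 layer randomizations, modules with >= 10
    genes at GO layer >= 6)."""

    regulatory: str | None = None
    ppi: str | None = None
    annotation: str | None = None
    go_dag: str | None = None
    term_names: str | None = None
    out_dir: str | None = None
    min_genes: int = 10
    min_depth: int = 6
    alpha: float = 0.01
    q_max: float = 0.05
    r_min: float = 0.2
    n_permutations: int = 10000
    n_randomizations: int = 1000
    swap_factor: int = 100
    ct_null: str = "direct"
    seed: int = 0
    propagate_annotations: bool = True
    depth_method: str = "longest"
    write_graphml: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1 and 0 < self.q_max <= 1):
            raise ValueError("alpha and q_max must lie in (0, 1]")
        if self.min_genes < 2 or self.min_depth < 1:
            raise ValueError("min_genes >= 2 and min_depth >= 1 required")
        if self.n_permutations < 1 or self.n_randomizations < 1 or self.swap_factor < 1:
            raise ValueError("sampling sizes must be positive")
        if self.ct_null not in ("direct", "bipartite"):
            raise ValueError(f"unknown ct_null {self.ct_null!r}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    net: IntegratedNetwork
    cpairs: CompositePairSet
    randomization: RandomizationSummary
    catalog: ModuleCatalog
    scan: list[tuple[FunctionalModule, MantelResult]]
    pairs: list[HierarchyPair]
    classifications: list[ModuleClassification]
    report: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_analysis(
    reg: RegulatoryInteractionSet,
    ppi: EdgeLayer,
    annotation: AnnotationTable,
    dag: GoDag,
    config: PipelineConfig,
    term_names: dict[str, str] | None = None,
) -> PipelineResult:
    """The full in-memory inference on already-loaded inputs."""
    cfg = config
    with _stage("build-network"):
        ct = derive_ct_edges(reg)
        net = build_integrated_network(ct, ppi, annotation.genes)
    with _stage("cpair-stats"):
        cpairs = find_cpairs(net)
        randomization = cpair_significance(
            net,
            cfg.n_randomizations,
            derive_seed(cfg.seed, "cpair-significance"),
            cfg.swap_factor,
            ct_null=cfg.ct_null,
            reg=reg,
        )
    with _stage("catalog"):
        catalog = build_module_catalog(
            annotation,
            dag,
            net.gene_set,
            cfg.min_genes,
            cfg.min_depth,
            cfg.propagate_annotations,
            cfg.depth_method,
        )
    with _stage("scan"):
        scan = scan_modules(
            net, catalog, cfg.n_permutations, cfg.seed, cfg.alpha, cfg.q_max
        )
    with _stage("select"):
        r_by_term = {
            m.term_id: res.r
            for m, res in scan
            if is_significant(res, cfg.alpha, cfg.q_max)
        }
        pairs = hierarchy_pairs(list(r_by_term), dag, r_by_term)
        classifications = select_ctppi_modules(
            scan, pairs, cfg.r_min, cfg.alpha, cfg.q_max
        )
    with _stage("stats"):
        report = _build_report(net, cpairs, reg, scan, classifications, term_names)
    n_tested = sum(1 for _, r in scan if r.tested)
    n_sig = sum(1 for _, r in scan if is_significant(r, cfg.alpha, cfg.q_max))
    n_sel = sum(1 for c in classifications if c.selected)
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "counts": {
            "genes": len(net.genes),
            "ct_edges": len(net.ct),
            "ppi_edges": len(net.ppi),
            "cpairs": len(cpairs),
            "modules": len(catalog),
            "tested": n_tested,
            "significant": n_sig,
            "selected": n_sel,
            "hierarchy_pairs": len(pairs),
            "hierarchy_violations": len(hierarchy_violations(pairs)),
        },
        "cpair_randomization": randomization.to_dict(),
    }
    assert n_sel <= n_sig <= n_tested <= len(catalog)
    return PipelineResult(
        net, cpairs, randomization, catalog, scan, pairs, classifications, report, manifest
    )


def _build_report(
    net: IntegratedNetwork,
    cpairs: CompositePairSet,
    reg: RegulatoryInteractionSet,
    scan,
    classifications,
    term_names: dict[str, str] | None,
) -> pd.DataFrame:
    cls_by_term = {c.term_id: c for c in classifications}
    names = term_names or {}
    rows = []
    for mod, res in scan:
        ct_sub = net.ct.restricted_to(set(mod.genes))
        ppi_sub = net.ppi.restricted_to(set(mod.genes))
        ct_c, ppi_c, both = integrated_compactness(mod, net)
        summary = tf_regulator_summary(mod, cpairs, reg)
        cls = cls_by_term.get(mod.term_id)
        rows.append(
            {
                "namespace": mod.namespace,
                "term_id": mod.term_id,
                "description": names.get(mod.term_id, ""),
                "n_genes": mod.size,
                "depth": mod.depth,
                "n_ct_edges": len(ct_sub),
                "n_ppi_edges": len(ppi_sub),
                "n_cpairs": module_cpair_count(mod.genes, cpairs),
                "r": res.r,
                "p": res.p,
                "q": res.q,
                "status": res.status,
                "class": cls.klass if cls else "",
                "selected": bool(cls.selected) if cls else False,
                "enrichment_p": cpair_enrichment_p(mod, net, cpairs),
                "ct_compact": ct_c.compact,
                "ppi_compact": ppi_c.compact,
                "integrated_compact": both,
                "tf_summary": format_tf_summary(summary),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["namespace", "term_id"]).reset_index(drop=True)


def write_outputs(result: PipelineResult, out_dir, config: PipelineConfig) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        p = out / "module_report.tsv"
        result.report.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)
        p = out / "network.tsv"
        write_network_tsv(result.net, p)
        written.append(p)
        p = out / "cpairs.tsv"
        with open(p, "wt", encoding="utf-8") as fh:
            fh.write("# geneA\tgeneB\n")
            for a, b in result.cpairs:
                fh.write(f"{a}\t{b}\n")
        written.append(p)
        p = out / "cpair_randomization.json"
        payload = dict(result.randomization.to_dict(), seed=config.seed)
        p.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written.append(p)
        p = out / "manifest.json"
        p.write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
        written.append(p)
        if config.write_graphml:
            p = out / "network.graphml"
            write_graphml(result.net, p)
            written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written


def _read_term_names(path) -> dict[str, str]:
    names = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 2:
            names[parts[0]] = parts[1]
    return names


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read the configured inputs, run the analysis, write outputs."""
    for key in ("regulatory", "ppi", "annotation", "go_dag", "out_dir"):
        if getattr(config, key) is None:
            raise ValueError(f"config is missing required path {key!r}")
    with _stage("read-inputs"):
        reg = read_regulatory_interactions(config.regulatory)
        ppi = read_ppi_edges(config.ppi)
        annotation, dag = load_go_inputs(config.annotation, config.go_dag)
        names = _read_term_names(config.term_names) if config.term_names else None
    result = run_analysis(reg, ppi, annotation, dag, config, names)
    with _stage("write-outputs"):
        write_outputs(result, config.out_dir, config)
    return result
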