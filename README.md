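# ctppi — composite CT-PPI functional module inference

Transcriptional regulation and physical protein interaction are usually
studied as separate networks, yet a cell runs them together: genes that are
co-regulated by the same transcription factors often also interact at the
protein level. `ctppi` is a tool for systems biologists who have (a) a
TF→target regulatory map, (b) a protein–protein interaction (PPI) edge list,
and (c) GO annotations over the same genes, and who want to know **which
GO-defined functional modules show structurally consistent co-regulation and
interaction** — composite CT-PPI modules.

## The method

1. **Integrated network.** Genes sharing ≥ 1 regulating TF are linked by a
   co-transcriptional-regulation (CT) edge; PPI edges form a second layer.
   Only GO-annotated genes carrying both link types are kept (iterated to a
   fixed point).
2. **C-pairs.** Pairs linked in *both* layers are the 2-node composite
   motif. Their over-representation is scored as
   `Z = (N_real − N̄_rand)/sd(N_rand)` against a null that rewires each layer
   by degree-preserving double-edge swaps; functional coherence of pair
   classes is compared with an upper-tail hypergeometric test.
3. **Mantel scan.** Per GO module (≥ 10 genes, GO layer ≥ 6), the CT and PPI
   sub-network adjacency matrices A, B are compared by the simple Mantel
   test: r = Pearson correlation of the lower-triangle entries, with a
   one-sided permutation p (simultaneous row/column relabeling) and
   Benjamini–Hochberg q across testable modules.
4. **Selection.** Significant modules (p < 0.01, q < 0.05) with r > 0.2 that
   are descendant or isolated terms in the GO is_a hierarchy are the CT-PPI
   modules.
5. **Characterization.** Per module: C-pair enrichment in pairs space
   (hypergeometric over C(G,2) gene pairs), inner/outer link-density
   compactness per layer (C_in = L_in/G_in vs C_out = L_out/G_out, compact
   iff C_in > C_out in both layers), and the TFs whose targets cover module
   C-pairs.

See `docs/methods.md` for assumptions, parameter meanings, and limitations.

## Worked example

The package ships a synthetic-study generator with planted ground truth, so
the whole pipeline can be exercised without external data:

```sh
ctppi simulate --out demo --seed 1          # writes regulatory.tsv, ppi.tsv,
                                            # annotation.tsv, go_dag.tsv, truth.json
ctppi run --regulatory demo/regulatory.tsv --ppi demo/ppi.tsv \
          --annotation demo/annotation.tsv --go-dag demo/go_dag.tsv \
          --out demo_out --seed 1
```

which prints

```
92 genes | 141 C-pairs | 22 modules | 2 significant | 2 CT-PPI modules
```

The study planted two high-consistency modules (a dedicated TF over 12 genes
with 90 % of the co-regulated pairs mirrored as PPI edges) among 20 decoy GO
terms. The integrated network retains 92 genes; 141 gene pairs are linked in
both layers; of the 22 catalog modules exactly the two planted terms are
significant and selected. `demo_out/module_report.tsv` holds one row per
module; the planted rows look like

```
term_id    n_genes  n_cpairs  r       p          q        class     selected  enrichment_p  integrated_compact  tf_summary
GO:PLANT1  17       60        0.668   9.999e-05  0.0021   isolated  True      1.29e-56      True                tfP1(60)tf03(6)...
GO:PLANT2  17       60        0.679   2.000e-04  0.0021   isolated  True      1.29e-56      True                tfP2(60)tf01,tf07(6)...
```

— r is the CT-vs-PPI Mantel consistency, p/q its permutation significance
and FDR, `enrichment_p` the local C-pair enrichment, and `tf_summary` the
TFs regulating module C-pairs in `TF(count)` form. `manifest.json` records
the stage counts and the C-pair randomization summary (here
N_real = 141 vs a null of 72.8 ± 5.4).

The same analysis is available as a library:

```python
import ctppi

study = ctppi.simulate_study(seed=1)
result = ctppi.run_analysis(
    study.reg, study.ppi, study.annotation, study.dag,
    ctppi.PipelineConfig(seed=1),
)
print(result.report[result.report.selected][["term_id", "r", "p", "q"]])
```

Subcommands `build-network`, `cpair-stats`, `scan`, `select`, and `stats`
run individual stages over the TSV interchange files; real data enters as
plain TF/target and gene/gene edge lists, GAF or two-column annotations, and
an OBO or child–parent GO file.

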