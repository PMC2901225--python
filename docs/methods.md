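# Methods

## The model

`ctppi` infers *composite functional modules* from a two-layer gene network
over a shared gene universe:

- **CT layer** (co-transcriptional regulation): genes *a* and *b* are linked
  when at least one transcription factor regulates both, so each TF with *k*
  targets contributes the k·(k−1)/2 pairs of its target clique and the layer
  is the union over TFs.
- **PPI layer**: undirected physical protein-protein interactions, with
  self-pairs (homomultimers) excluded.

The integrated network keeps only GO-annotated genes that carry at least one
link of *each* type. Because dropping an edge can strand a gene, the
restriction is iterated to a fixed point; the resulting network is idempotent
under re-application.

A **C-pair** is a gene pair present in both layers — the two-node composite
motif. A **functional module** is the gene set of one GO term (BP or CC)
restricted to the network. A module is a **CT-PPI module** when its CT and
PPI sub-networks are *globally* consistent and it sits at the specific end of
the GO hierarchy among the consistent modules.

## Statistics

**C-pair significance.** The observed C-pair count N_real is compared with a
null in which each layer is independently rewired by double-edge swaps that
preserve every node's degree, then re-intersected. Each replicate attempts
`swap_factor × |E|` swaps (default 100 per edge), rejecting any swap that
would create a self-loop or duplicate edge; the proposal is symmetric, so the
chain's stationary law is uniform over simple graphs with the given degree
sequence. Summary: null mean/sd (sd with the n−1 denominator),
Z = (N_real − mean)/sd, and an add-one empirical p
(1 + #{null ≥ N_real})/(1 + n). With the published yeast summary counts
(168 observed vs 109.8 ± 9.66 over 1000 randomizations) this Z formula
reproduces the published 6.03.

**Functional coherence.** A pair is coherent when its genes share ≥ 1 GO
term. The "narrow" background restricts sharing to leaf terms, defined
relative to the retained (annotated) term set: a term with no annotated
child. Whether C-pairs are more coherent than CT (or PPI) pairs is an
upper-tail hypergeometric test: population M = CT pairs, successes K =
coherent CT pairs, draws N = C-pairs, observed x coherent C-pairs.

**Mantel consistency.** For a module with gene order g₁…gₙ, A is the 0/1 PPI
sub-network adjacency matrix and B the CT one. The statistic r is the
Pearson correlation of the n(n−1)/2 strictly-lower-triangle entries.
Significance is one-sided (consistency means positive r): each permutation
relabels B's rows and columns simultaneously and p is the add-one tail
fraction, with ties r_perm ≥ r_obs counted into the tail. Which matrix is
permuted is immaterial (r is symmetric in A and B) and fixed for
reproducibility. Degenerate inputs are carried, not tested: an edgeless
sub-network is `untestable_no_edges`; a constant non-empty one (or n < 3) is
`untestable_zero_variance`. An exact mode enumerates all n! relabelings for
n ≤ 8 and returns the exact tail fraction. Across the catalog, q-values are
Benjamini–Hochberg over *testable* modules only; a module is significant
when p < alpha **and** q < q_max.

**Selection rule.** Among significant modules, every transitive
ancestor/descendant couple in the is_a DAG forms a hierarchy pair; terms in
no pair are isolated. A module is selected as a CT-PPI module when it is
significant, r > r_min strictly, and a descendant or isolated term. A chain
of candidates resolves to the DAG-deepest term: a candidate that is an
ascendant of another candidate is not selected. The tendency of descendants
to have larger r than their ascendants is *recorded* (as violations in the
manifest), never enforced.

**Enrichment and compactness.** C-pair enrichment of a module is an
upper-tail hypergeometric in pairs space: of X = C(G,2) gene pairs in the
G-gene network, Y are C-pairs; the g-gene module spans Z = C(g,2) pairs of
which a are C-pairs. Compactness per layer: L_in inner links, G_in inner
genes with inner links, L_out links between G_in genes and outside (links
from inner genes *without* inner links do not count, per the definition),
G_out outside genes so linked; C_in = L_in/G_in, C_out = L_out/G_out (0 when
the denominator is 0), compact iff C_in > C_out strictly; the integrated
sub-network is compact iff both layers are.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_genes` | 10 | smallest retained module (genes, after network restriction) |
| `min_depth` | 6 | shallowest retained GO layer, root = layer 1 |
| `alpha` | 0.01 | Mantel p threshold |
| `q_max` | 0.05 | BH-FDR threshold |
| `r_min` | 0.2 | consistency threshold for selection (strict) |
| `n_permutations` | 10000 | Mantel permutations per module |
| `n_randomizations` | 1000 | degree-preserving replicates for C-pair Z |
| `swap_factor` | 100 | attempted swaps per edge per replicate |

The thresholds and sampling sizes are the method's published operating
point. Depth uses the longest is_a path from the namespace root (root =
layer 1) — the stricter and more common "layer" convention; shortest-path
depth is available via `depth_method="shortest"`. Ancestry uses is_a edges
only; `part_of` is out of scope. Annotations are propagated to ancestor
terms (true-path rule) by default, which is what makes the
identical-gene-set ancestor/descendant filter (descendant kept) meaningful;
propagation can be disabled.

## The synthetic study generator

`simulate_study` emulates the three inputs with known ground truth:

- a null network: each of 12 TFs draws 15 targets uniformly without
  replacement from 150 genes; PPI edges are independent per pair with
  probability 0.02. The layers are statistically independent — exactly the
  null hypothesis of both the Mantel p and the C-pair Z.
- 2 planted modules: a dedicated TF over a 12-gene subset (a CT clique, the
  way real CT structure arises) with 90% of the clique pairs mirrored as PPI
  edges; the mirrored pairs are the planted C-pairs.
- 20 decoy GO terms annotated to random 12–18-gene sets, and a toy two-
  namespace DAG placing every term as a leaf at layer 7 on its own chain.

These sizes are desk-scale analogues of the yeast layers (dense CT from
shared regulators, sparse PPI, a catalog of a few dozen candidate modules)
chosen so a full default-parameter run completes in minutes on one core.

Two generator details matter and are deliberate:

- **Annotation padding.** Each planted term is annotated with its clique
  plus 5 padded network genes not co-regulated by the planted TF. Real GO
  modules are never perfectly co-regulated; without padding the planted CT
  sub-matrix is an all-ones clique — constant, hence rightly untestable.
  Padding also controls the attainable significance: every relabeling that
  maps the clique onto itself ties the observed r, so with clique size s and
  k padding genes the permutation p can never drop below ≈ s!·k!/(s+k)!.
  With s = 12, k = 5 the floor is ~1.6×10⁻⁴, comfortably below
  alpha/|catalog|; at k ≤ 3 the floor collides with the BH threshold and
  recovery becomes a coin flip. 
- **Eligibility-aware drawing.** Module, padding, and decoy genes are drawn
  from genes that already carry both link types in the null layers, so
  annotated module genes survive the integrated-network restriction — the
  synthetic analogue of overlapping the two data sets before annotating.

What the generator does **not** emulate: scale-free degree distributions,
the size and density of the real yeast layers, annotation noise, or
multi-TF combinatorial regulation. Passing tests therefore demonstrate the
statistical machinery (calibration, recovery, selection logic) on networks
with the right *structure*, not performance claims on real data.

## Numerical choices

- Permutation ties count toward the tail with a 1e-12 tolerance on r.
- Sampled permutation p uses the add-one estimator (guarantees p > 0 and is
  conservative); the exact mode divides by n! with the identity included.
- The null sd of the C-pair count uses the n−1 denominator; Z is reported as
  NaN (with a warning) when sd = 0 and the empirical p remains valid.
- The mirrored-pair count in planting rounds with round-half-even.
- Per-module and per-replicate seeds are derived from the master seed and a
  stable token (stage name, term id, replicate index) via CRC32 +
  SeedSequence, so module results are independent of catalog order and all
  randomness reproduces from one integer.
- Matrices are validated as symmetric binary with zero diagonal; weighted
  variants are rejected.

## Known limitations

- The degree-preserving swap chain is run for a fixed attempt budget, not to
  a mixing diagnostic; for very constrained degree sequences (stars, single
  edges) no swap is admissible and the layer is returned unchanged with a
  warning — which is also the correct null for those layers.
- CT layers are randomized directly as undirected graphs by default. Real CT
  layers are unions of TF-target cliques, so the direct swap null can realize
  CT graphs no TF assignment could generate; `ct_null="bipartite"` instead
  rewires the TF→target graph (preserving TF out-degrees and gene
  in-degrees) and re-derives CT, at a higher per-replicate cost.
- Hypergeometric coherence/enrichment tests treat pairs as exchangeable
  draws, ignoring the dependence between pairs sharing a gene.
- GO `part_of` relations and annotation evidence codes are ignored.
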