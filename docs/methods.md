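# Methods

This note documents the models and procedures implemented in `xassess`,
the parameter choices that matter, and what the synthetic benchmark does
and does not show.

## Homology-aware concatenation

Gene groups are the **connected components** of the undirected gene–gene
graph over all pairwise ortholog records. Pairwise homology annotations
(the form ENSEMBL exports) do not define multi-species groups directly;
component closure handles chained one-to-many relations across three or
more species, at the cost of occasionally merging groups through a shared
paralog. A group is *usable* only if it has at least one gene in every
studied species and every member is quantified in its species' matrix —
unusable groups are kept in the `GeneGroupSet` but never become columns.
A quantified gene with no homology record forms a species-specific group;
these are exported as unshared features for methods that accept them.

Paralog selection within one-to-many / many-to-many groups:

- **HE** picks the member with the highest arithmetic mean of *raw* counts
  over all cells of its species. Concatenation is defined on raw counts, so
  the selection statistic is computed on the same layer; zeros count.
- **SH** compares ENSEMBL-style confidence attributes lexicographically in
  the order: orthology confidence, gene-order conservation score,
  whole-genome-alignment coverage, query %identity, target %identity.
  Higher is better; a missing attribute ranks below any recorded value.
  A gene's attribute vector is the element-wise best over the records that
  link it into its group (a paralog may appear in several records with
  different partners).
- All residual ties (equal means, equal attribute vectors) break by
  ascending gene id, so output is deterministic and order-invariant.

Counts are carried over unchanged — each output column equals the selected
source gene's raw counts exactly.

## Ontology alignment

Annotation granularity is aligned on the `is_a` DAG only; other Cell
Ontology relations (`part_of`, `develops_from`) encode composition and
lineage, not the ancestor–descendant generality the alignment needs.
The algorithm is a two-stage fixed-point collapse:

1. **Trim** each dataset: while any used term has a strict ancestor also
   used in the same dataset, remap it to the *nearest* used ancestor
   (shortest `is_a` path; ties by term id).
2. **Match** across datasets: pool all trimmed terms and apply the same
   collapse over the pooled set, so descendants in one dataset meet
   ancestors in another at their last common ancestor.

At the fixed point the surviving terms are exactly the used terms with no
strict ancestor in use — an antichain, and the finest one consistent with
the collapse rule (verified in the tests by exhaustive search on small
DAGs). Sibling terms with no used ancestor are deliberately **not** merged
to their LCA: a dataset-specific cell type with no counterpart elsewhere
must survive alignment. Choosing the nearest (rather than topmost) present
ancestor does not change the final term set, only the provenance of
intermediate steps; we fix "nearest, iterated to fixed point".

## Metric suite

Integration outputs come in three kinds — latent embedding, corrected
pseudo-count matrix, k-NN graph — and metrics declare applicability per
kind. Embeddings are used as-is (first 20 dimensions); corrected matrices
are unit-variance scaled (clipped at 10) and reduced to 20 principal
components; graph-only outputs support only the graph metrics, so such
strategies are reported but excluded from composite scoring and ranking.

Conventions, fixed package-wide: k = 20 nearest neighbours, Euclidean
distance on the first 20 dimensions, silhouettes on the same 20
dimensions. The standard reduction of raw counts is: total-count
normalisation to 10,000, log1p, dispersion-based HVG selection (min mean
0.0125, max mean 3, min normalised dispersion 0.5; with a batch key the
per-batch HVG sets are intersected), scaling clipped at 10, PCA
(`arpack`, 40 components).

- **Alignment score (AS)** — mean over cells of (cross-species neighbour
  count) / min(k, cells of other species). The min caps the denominator at
  what is attainable when one species has fewer than k cells.
- **PCR** — for each representation, Var_expl = Σ_j λ_j R²_j / Σ_j λ_j
  over its principal components, with R²_j from regressing PC j on the
  one-hot species covariate; score = clip((pre − post)/pre, 0, 1) against
  the unintegrated reference.
- **bASW** — per cell type spanning ≥ 2 batches, mean of 1 − |silhouette|
  with batch labels; unweighted mean over qualifying cell types
  (weighting by type size would let abundant types dominate exactly the
  comparison the metric is meant to balance).
- **cASW** — (mean silhouette with cell-type labels + 1) / 2.
- **GC** — per cell type, the fraction of its cells in the largest
  connected component of the subgraph they induce (symmetrised k-NN);
  mean over types.
- **kBET** — a simplified acceptance-rate variant: per cell type, each
  cell's neighbourhood batch composition is tested by chi-squared
  goodness-of-fit against the type's global batch proportions; acceptance
  rate = fraction with p > 0.05, averaged over types, sub-sampling at most
  500 cells per type with a fixed seed. No parity with the reference kBET
  implementation is claimed — what composite scoring needs is correct
  behaviour at the extremes (i.i.d. batches ≈ 1, separated batches ≈ 0),
  which this variant has.
- **NMI / ARI** — agreement between cell-type labels and the best Leiden
  clustering over resolutions 0.1–2.0 in steps of 0.1
  (RB-configuration quality, fixed seed); NMI uses arithmetic
  normalisation and is 0 by convention for a constant labeling.
- **isolated-label F1** — isolated labels are the cell types present in
  the minimum number of batches (if every type is in every batch, all
  types count as isolated — degenerate but defined); per label, the best
  F1 of predicting the label by membership of a single cluster, maximised
  over the same resolution sweep; mean over isolated labels. The
  best-cluster assignment rule is declared here, not inherited from any
  particular external implementation.

Local inverse-Simpson indices (iLISI/cLISI) and trajectory conservation
are out of scope; a `Traj` column, if supplied externally, joins the
biology-conservation mean.

## Composite scoring

Raw metrics are min-max scaled **per task across all strategies,
including the unintegrated references**; the references anchor the scale
so that near-ties between well-performing algorithms are not inflated.
A constant column scales to 0.5 everywhere — an uninformative metric
should not separate strategies. Not-applicable entries propagate: the
species-mixing score is the mean of the *applicable* scaled batch metrics,
biology conservation the mean of the applicable scaled biology metrics,
and a strategy with no applicable batch metric (graph-only outputs) gets
no composite score and no rank, though its AS and ALCS are still
reported. The integrated score weights species mixing 0.4 and biology
conservation 0.6. Ranking ties break by biology conservation, then
strategy id. ALCS is reported alongside the scores, never inside them.

## Self-projection, ALCS and transfer

Self-projection: a stratified 50/50 split (fixed seed), multinomial
logistic regression (L2, C = 1.0, lbfgs, max 1000 iterations — fixed and
recorded; only the classifier family is essential), held-out accuracy.
Labels with a single cell cannot be stratified and are dropped with a
warning.

ALCS per species = held-out accuracy on that species' own standard
reduction (first 20 PCs, HVGs recomputed on that species alone) minus
held-out accuracy on that species' rows of the integrated representation.
Zero means integration preserved cell-type distinguishability; with c
balanced cell types, collapsing one pair caps integrated accuracy at
(c − 1)/c, so ALCS ≈ accuracy_original − (c − 1)/c. Graph-only outputs
have no representation to classify on, so ALCS is not applicable to them.

Annotation transfer trains the same classifier on all source-species cells
of the integrated representation, predicts all target cells, and scores by
ARI against the target's own annotation; runs over all ordered species
pairs are averaged. A coverage flag records whether every cell type shared
by source and target appeared among the predictions. ARI can be negative —
worse than random assignment — when integration has failed.

## Synthetic data generator

The generator emulates the structure of a multi-species benchmark at desk
scale. Counts for gene g, cell type t, species s are negative binomial
with mean μ_gt · f_sg (· Dirichlet share for one-to-many paralogs) and
shape θ:

- μ_gt = base_g · exp(N(0, celltype_program_sd)) with base_g lognormal
  around `base_mean` = 2 — cell-type programs shared across species;
- f_sg = exp(N(0, species_effect_sd)) — a gene-wise multiplicative species
  effect. At sd ≈ 1 unintegrated embeddings cluster primarily by species,
  reproducing the phenotype that motivates cross-species integration.

Defaults: 2 species, 4 shared cell types, 60 cells per type, 2000 gene
groups (10% one-to-many, 10% species-specific, the rest one-to-one),
θ = 2, species_effect_sd = 1. The gene-group count is chosen so that the
standard HVG mean window behaves as it does on real data after
normalisation to 10,000 counts; one-to-many paralogs split the parent
program by Dirichlet(1,1) shares so the higher-expression paralog is a
well-defined ground truth; homology confidence attributes are sampled per
record. Everything is reproducible per seed.

Mock integration outputs place each cell at its cell type's 20-dimensional
latent coordinate (drawn N(0, 4²) per type) plus isotropic noise
(sd 0.5): `perfect` stops there; `none` adds a per-species offset of norm
50 — larger than typical inter-centroid distances (≈ 25), so species
separation dominates, as in uncorrected data; `overcorrected` maps chosen
pairs of shared cell types onto their midpoint, making them exactly
indistinguishable.

What the generator does **not** model: library-size variation, dropout
beyond NB sampling, doublets, ambient RNA, species-by-cell-type program
divergence, or any real tissue's composition. Consequences worth knowing:
because the species effect is gene-wise multiplicative, it is nearly a
translation in log space, and a translation-robust classifier can still
transfer labels across an unintegrated embedding at moderate effect sizes
— transfer only breaks down (ARI near 0) at extreme effect sizes (sd ≈ 5)
where zero-inflation distorts the geometry. Passing tests on this
generator therefore demonstrate correctness of the assessment machinery,
not integration performance on real atlases.

## Numerical and design choices

- Distance ties in k-NN search break by ascending cell index; all sweeps,
  splits and subsamples take explicit seeds; reports serialise with fixed
  ordering and formatting, so identical runs produce identical files.
- Min-max scaling of a column with fewer than two defined values is
  impossible; such columns are dropped with a warning.
- Chi-squared tests in kBET restrict to batches with non-zero expected
  counts within the cell type.
- PCA uses `arpack` on the standard reduction and a full SVD elsewhere,
  with component counts clamped to the data's rank.
- Problem sizes in the test-suite (hundreds of cells, thousands of genes,
  toy ontologies of ≤ 15 terms) are the scale at which exhaustive oracles
  — brute-force neighbour search, pair-counting ARI, enumeration of all
  antichains — remain feasible; they are the point of the synthetic
  benchmark, not a limitation of the implementation.

## Known limitations

- Gene-id matching is exact string matching; no id-version reconciliation.
- The ontology aligner reads `is_a` only and requires inputs already
  annotated with ontology term ids.
- kBET is the simplified variant described above.
- The homology concatenation recomputes paralog selection per task; a
  group may legitimately select different paralogs in tasks that share a
  species but differ in the cell population.
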