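# Methods

## Model

`targetnet` treats drug-target discovery as one-class novelty detection.
Let `P` be the set of known drug target genes mapped onto a PPI network
with node set `V`.  Every node `v ∈ V` is encoded as a feature vector
`x_v ∈ R^52` (blocks below), and a one-class SVM with RBF kernel
`k(x, y) = exp(−γ‖x − y‖²)` is fitted to `{x_p : p ∈ P}` only.  The
signed decision value `f(x_v)` is the prediction score; `f(x_v) ≥ 0`
calls the gene target-like (the LIBSVM one-class convention).  The
`ν ∈ (0, 1]` parameter upper-bounds the fraction of training positives
allowed outside the learned region.

The rationale for one-class rather than binary learning is label noise:
the non-target pool certainly contains undiscovered targets, so a
discriminative boundary against it would be fitted partly to mislabeled
examples.

### Feature blocks (primary variant, 52 columns)

1. **Centralities (3)** — degree (normalized by `n − 1`), betweenness
   (normalized, computed exactly), closeness with the Wasserman–Faust
   reachable-set correction, so disconnected graphs are handled without
   special cases.
2. **Class distances (14)** — for each of the seven node types (DTG,
   DAG, PFG, PUG, URG, DRG, OG): the average and the minimum
   shortest-path hop count from the gene to the members of that type.
   The gene itself is excluded when it belongs to the type, since a
   guaranteed zero would encode class membership directly into the
   feature.  Unreachable or empty target sets yield the sentinel `|V|`,
   which exceeds any realizable distance and keeps "farther" monotone;
   it is configurable.  On directed networks, distances follow outgoing
   edges (node → class); the reverse orientation is available.
3. **Neighborhood composition (7)** — the fraction of the gene's direct
   neighbors belonging to each node type.  Labels are not exclusive, so
   the seven ratios may sum above 1.  Isolated nodes get all zeros.
4. **Gene dependency (14)** — the gene's essentiality score in each
   cell line (lower = more essential).  Missing cells, and genes absent
   from the screen, are imputed with the per-cell-line mean over all
   scored genes — a neutral value that preserves the background
   distribution — and flagged.
5. **Neighbor dependency (14)** — the per-cell-line mean over the
   gene's *scored* neighbors.  Unscored neighbors are skipped rather
   than imputed, to avoid averaging imputed values into a second
   smoothing pass; only a gene with no scored neighbor at all falls
   back to the imputation value.

Feature order is frozen (centralities; distances by type in label order
with average before minimum; ratios; own dependency by sorted cell
line; neighbor dependency) so tables are byte-comparable across runs.
Variants: `no_centrality` (49), `extended_centrality` (55; adds
PageRank, eigenvector with power iteration at tolerance 1e-8, and Katz
with attenuation `0.9/λ_max`), and three variants that consume external
rank-propagation scores through the `(N − rank)/N` transform:
`dada_replace` (56), `dada_append` (59), `dada_only` (7).

### Scaling

Features are min–max scaled to `[0, 1]`; constant features map to 0.
Statistics are fitted on training rows only (training-fold positives
plus the training-side unlabeled pool during cross-validation) and
stored, so held-out and future genes are transformed with training
statistics — they may legitimately fall outside `[0, 1]`.  Z-scoring is
available as an alternative.

## Evaluation protocol

Five-fold cross-validation repeated ten times.  Negatives never enter
SVM training, but both classes are folded so that Table-style metrics
are well defined: per repeat, positives and negatives are independently
partitioned into five folds; for fold `i` the model is trained on the
other positive folds and scores the held-out positives and the held-out
negatives, so each gene receives exactly one out-of-fold score per
repeat.  Sensitivity, specificity and MCC pool the confusion counts
across the five folds at threshold 0 (MCC is defined as 0 when a margin
vanishes); AUC is computed on the pooled scores with midrank tie
handling.  Hyperparameters default to `ν = 0.1`, `γ = 1/d`; an optional
grid (`ν ∈ {0.05, 0.1, 0.2, 0.3, 0.5}`, `γ = 4^{−2..2}/d`) is searched
once by mean AUC on partitions disjoint from the reported rounds.
All partitioning derives from a single master seed via 31-bit
sub-seeds stored in each round result, so runs are bit-reproducible.

Final scores are the mean of the ten out-of-fold scores; the consensus
predicted set is the intersection of the ten per-round positive-call
sets, which makes it monotone non-increasing in the number of rounds
required.  For scoring new genes, per-round models are refitted on all
positives with the selected hyperparameters and their scores averaged.

## Supporting statistics

* Wilcoxon rank-sum class-vs-background batteries for centralities and
  for dependency scores (per class × measure/cell line).  Tests are
  two-sided — exact for tie-free samples up to n = 25, normal
  approximation with continuity correction otherwise — with direction
  reported separately by median.  The background includes the class
  members ("versus all genes"), configurable to exclude them.  Raw
  p-values are reported; a BH-adjusted column is emitted alongside,
  without gating any decision.
* Group distance analysis: per class-A node, average/minimum distance
  to class B versus to the unlabeled background, compared by rank-sum.
* Enrichment of the predicted set for an independent positive reference:
  one-sided (greater) Fisher exact test on the 2×2 table over the gene
  universe, since the claim being tested is directional.
* Alternative-negative-set ROC: stored final scores re-labelled against
  a supplied negative gene set (overlaps with positives dropped with a
  warning).
* `(N − rank)/N` rank transform, strictly decreasing in rank, satisfying
  `s(r) + s(N+1−r) = (N−1)/N` and mean `(N−1)/(2N)` over a full ranking.

Differential expression calling uses a paired t-test on `log2(x + 1)`
values (RNA-seq convention; the pseudocount avoids log 0), linear fold
change `(mean_T + 1)/(mean_N + 1)`, BH FDR, and inclusive thresholds
`q ≤ 0.05`, `FC ≥ 2` (up) or `≤ 0.5` (down).  Zero-variance paired
differences yield `p = 1` when the mean difference is zero and a
machine-epsilon floor (with a warning) otherwise, so degenerate genes
cannot produce NaNs downstream.

## Synthetic data generator

The generator emulates the marginal structure the real data exhibit, so
every stage is testable without restricted downloads:

* **Network** — Barabási–Albert preferential attachment (`m = 3`) over
  `n` genes gives a heavy-tailed degree distribution.  Target-like and
  disease-associated-like genes receive `hub_boost = 8` extra random
  edges each (unfavorable/up-regulated genes a quarter of that),
  planting elevated centrality; each target gene additionally attempts
  two links to random members of each of the DAG, PUG and URG classes,
  each realized with probability `proximity_boost = 0.6`, planting
  short target→disease distances per class.  Favorable and
  down-regulated genes are sampled from the low-degree half of the
  graph.  PFG∩PUG and DRG∩URG are kept empty (contradictory labels);
  other overlaps arise naturally from independent sampling.
* **Class sizes** — proportional to a real HCC annotation of the human
  interactome (217 DTG, 322 DAG, 230 PFG, 2,574 PUG, 4,004 URG, 434 DRG
  among 17,257 nodes), scaled to `n` with a floor of 5.  The
  default `n = 2000` keeps exact betweenness and the distance features
  computable in seconds while preserving the class imbalance
  (~1.25% positives).
* **Dependency** — `N(μ_class, 0.3)` per gene × 14 cell lines with
  `μ = −0.4` for PUG/URG (more essential), `+0.3` for PFG/DRG, `0` for
  DTG/DAG and background, matching the sign structure observed in liver
  cancer screens; 5% of genes are dropped from the matrix and 1% of
  cells blanked to exercise the imputation paths.
* **Expression** — 43 tumor/normal pairs (the real study's pairing
  count); per-gene baseline `N(5, 2)` on the log2 scale, planted shifts
  of +2 / −2 log2 units for URG/DRG, noise sd 0.5, exponentiated to
  non-negative linear units.

What it deliberately does not emulate: gene–gene correlation from
shared complexes or pathways, screen batch effects and quality
differences, transcriptome covariance, and symbol-mapping noise.
Passing tests therefore demonstrate that the pipeline recovers planted
marginal structure, not that it would attain any particular performance
on real interactome-scale data.

A zero-effect configuration (`null_config`) switches off every planted
effect, including the peripheral placement of favorable genes.  Note
that a single null draw carries only ~25 positives, so its CV AUC
fluctuates around 0.5 with a standard deviation near 0.05; calibration
checks therefore average over several independent null draws rather
than conditioning on one class assignment.

Frozen-seed golden fixtures: `small` (200 genes, 14 cell lines, 10
pairs) for fast unit tests, `medium` (the 2,000-gene default) for
end-to-end evaluation.

## Numerical and design choices

* Distance sentinel `|V|`: keeps features finite and monotone;
  configurable.
* "Absolute fold change ≥ 2" is interpreted symmetrically on the linear
  scale (`FC ≥ 2` or `≤ 0.5`).
* Betweenness is computed exactly; at interactome scale (~17k nodes)
  this is minutes of CPU, and a seeded sampling fallback is a natural
  extension point but not implemented.
* Eigenvector non-convergence raises with a hint to use Katz instead.
* Symbol handling is trim + uppercase only; alias/HGNC resolution is a
  curation step upstream of this package.  A gene listed as both
  prognostically favorable and unfavorable is dropped from both lists
  by default (configurable to keep), with a warning.
* The consensus rule requires a positive call in *all* rounds; relaxing
  it to a quorum is a one-line change but alters the precision/recall
  trade-off reported here.

## Known limitations

* One-class SVM scores are not calibrated probabilities; only their
  ranking and the sign are interpreted.
* The distance features of class members are computed against slightly
  smaller target sets (self-exclusion), a small but unavoidable
  asymmetry of class-aware features; its effect on a null fixture is
  within the sampling noise of the positive-set draw.
* Grid search refits on the same gene universe it later evaluates on
  (standard for this protocol, but scores should not be read as an
  unbiased estimate of performance on a new interactome).
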