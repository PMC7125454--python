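# Methods

`mirpathnet` implements an integrative miRNA–mRNA–pathway analysis for bulk
tumor/control RNA-seq count data. This note documents the statistical model
behind each stage, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical conventions.

## Differential expression of counts

Counts for feature *i* in sample *j* are modeled as negative binomial with
mean μ_ij and variance μ_ij + φ·μ_ij², where φ ≥ 0 is a common dispersion
(φ = 0 is the Poisson limit). The two-group test is the conditional exact
test: after rescaling counts to a common effective library size, group
totals are formed, and the fact that a sum of n i.i.d. NB(μ, φ) variables
is NB(nμ, φ/n) makes the distribution of the group-A total conditional on
the grand total exactly computable. The two-sided p-value sums all
conditional outcomes whose probability does not exceed the observed one
(minimum-likelihood rule), so identical group totals give p = 1 and at
φ = 0 the test reduces to the exact binomial test.

Supporting estimates:

* **Library sizes** — trimmed mean of M-values (TMM): log2 expression
  ratios against the deepest sample are trimmed 30% per tail (5% per tail
  on average log-intensity A) and combined with inverse-variance weights;
  the resulting factors are rescaled to geometric mean 1 and multiplied by
  raw depth. The quantile adjustment to a common size is approximated by
  scaling plus rounding to the nearest integer.
* **Dispersion** — a method-of-moments estimate: per feature and condition
  (s² − m̄)/m̄² on depth-adjusted counts, averaged across conditions,
  median over features, floored at 0. A common φ (no tagwise shrinkage)
  keeps the test exact and verifiable by full enumeration. The moments
  estimator is slightly conservative but recovers planted φ well at the
  cohort sizes used here (see tests).
* **Fold change** — log2 of depth-adjusted group means with a pseudocount
  of 0.5 for stability at zero counts.
* **Multiple testing** — Benjamini–Hochberg step-up.

A feature is called DE iff adjusted p < 0.05 **and** |log2FC| > 1.0, both
strict. At the pathway level the fold-change rule is inclusive
(|log2FC| ≥ 1); the asymmetry is deliberate and mirrors the conventions of
the study design this pipeline reproduces.

## Risk genes

A *risk gene* is a DE gene that is also a validated target of at least one
DE miRNA; the (miRNA, gene) pairing is retained. No direction-of-regulation
filter is applied — an up-regulated gene may pair with an up-regulated
miRNA, since validated-interaction databases record regulation without
guaranteeing detectable anti-correlation in any given cohort.

## Pathway scores and correlated pairs

The activity of pathway *i* in sample *k* is the **median** of the
depth-adjusted expression of its member genes measured in the matrix
(midpoint convention for even counts). Scores use depth-adjusted rather
than raw counts: medians of raw counts would mostly rank samples by
sequencing depth, and any pathway "differential activity" would be an
artifact of library size.

Pathway-level differential activity rounds the scores to integers and
reuses the NB machinery above (applying a count model to pathway summary
values is statistically unusual but is the convention this pipeline
reproduces); a Wilcoxon rank-sum backend is available as a sensitivity
check (`pathway_de_backend: wilcoxon`).

Two pathways form a *correlated pair* when the Pearson correlation of
their score vectors exceeds 0.8 in absolute value **separately** within
tumor samples and within control samples (both strict). Pathways with
constant scores in either condition are excluded (correlation undefined).
By default, pairing is restricted to the differentially active pathways —
the flow the downstream network assumes — but `restrict_pairs_to_de_pathways:
false` pairs all scored pathways.

## Tripartite network and topology metrics

For each correlated pair (X, Y), the risk genes common to both pathways'
member lists are collected; a qualifying pair contributes the
pathway–pathway edge X–Y plus gene–pathway edges g–X, g–Y for every common
risk gene g, and each miRNA–risk-gene interaction whose gene entered the
network adds a miRNA–gene edge. Pathway–pathway edges can be disabled
(`include_pathway_pathway_edges: false`), but they are on by default: they
are required for pathway degrees to exceed the number of risk genes, which
the reference analysis exhibits.

Six per-node metrics are computed directly on adjacency sets, following
Cytoscape NetworkAnalyzer conventions on the undirected, unweighted graph:

* degree;
* average shortest path length (mean hop distance to reachable nodes);
* closeness = 1 / ASPL (0 for isolated nodes);
* betweenness via Brandes' accumulation, normalized by (N−1)(N−2)/2 with
  N the whole-graph node count (component-wise normalization is a known
  dialect difference; whole-graph is used and documented);
* clustering coefficient 2e/(k(k−1));
* topological coefficient TC(n) = avg_m J(n, m)/k_n over nodes m sharing
  ≥ 1 neighbor with n, where J counts shared neighbors plus 1 for a direct
  n–m edge; nodes of degree < 2 get 0.

All six are verified against brute-force oracles (Floyd–Warshall
distances, exhaustive shortest-path counting, neighbor-set arithmetic) and
against networkx on seeded random graphs.

## Cross-validated single-feature classification

Each candidate is scored by stratified ten-fold cross-validation. On each
training split only the marker's direction is learned (the sign of the
tumor-minus-control mean difference); held-out samples are scored as
value × direction, and the **pooled** out-of-fold scores give one AUC per
feature (pooling is stabler than averaging per-fold AUCs at tens of
samples per fold; per-fold values are retained for inspection). AUC is the
Mann–Whitney rank statistic with ties counted ½. A single-feature logistic
scorer is available behind `model="logistic"`. The minimal
direction-calibrated scorer is used because the evaluation produces one
ROC value per individual feature; anything richer would change the
question being asked.

## Synthetic cohorts

The generator emulates a tumor/adjacent bulk study at desk scale. Defaults:
2000 genes, 300 miRNAs, 60 tumor / 30 control samples (preserving the
tumor-heavy asymmetry of large tumor/adjacent designs), 150 pathways of
15–25 genes, 200 DE genes and 40 DE miRNAs at |log2FC| = 2 (half up, half
down), NB dispersion φ = 0.1, base mean 100, library-size factors
log-uniform on [0.5, 2] (so normalization matters), 30 risk-eligible
target genes, decoy interaction rate 0.002 per possible non-DE pair.

Planted structure, per stage:

* **Correlated pairs** — 5 pathway pairs; each pair's member genes (both
  pathways) share one per-sample log-normal(0, σ = 0.8) latent factor in
  both conditions, giving score correlations around 0.95. A gene belonging
  to planted pathways of different pairs receives only its first pair's
  factor, and each pair draws its DE members from a disjoint block of
  up-regulated DE genes — otherwise one pair's factor would bleed into
  another's scores and dilute within-pair correlation.
* **Differentially active pathways** — planted pathways draw 75% of their
  members from up-regulated DE genes. The fraction must be well above 50%
  because the median of a mixed membership sits at a low quantile of the
  shifted block; 75% puts the pathway log2FC near 1.8, safely past the
  inclusive ≥ 1 rule.
* **Hub** — one up-regulated DE gene placed in all 10 planted pathways and
  targeted by exactly 2 DE miRNAs, so it enters the network through every
  planted pair and tops the gene-degree ranking.

All randomness flows through generators spawned from a single seed; the
same configuration reproduces the same data bit for bit.

What the generator does **not** emulate: batch effects, GC/length bias,
isoform structure, count–count correlation beyond the planted latent
factors, miRNA-mediated repression (planted interactions are labels, not
causal links), or realistic pathway-size and overlap distributions.
Passing tests therefore demonstrate that the pipeline's inference machinery
recovers the structure its model assumes — not that the model captures
every property of real tumor cohorts.

## Numerical conventions and degenerate inputs

* Exact-test tie detection uses a 1e-10 relative log-probability tolerance;
  if every outcome qualifies, p is exactly 1.
* Even-cardinality medians take the midpoint of the central values.
* Ranking ties (degree, AUC) break by node/feature id for determinism.
* All-zero samples are rejected at normalization; constant-score pathways
  are excluded from pairing; pathways with fewer measured members than
  `min_pathway_members` are dropped with a warning; an empty interaction
  table yields an empty network, not an error.
* CV folds are stratified and seeded; a training split with one class
  triggers one fold re-draw with a derived seed, then an error.
* Problem sizes in the test suite and the reproduction script (cohorts of
  2000 × 90, 10–100 repetitions per property) were chosen as the smallest
  scales at which the planted effects are comfortably identifiable;
  recovery rates are expected to be flat or better at larger scale.

## Known limitations

* The NB test uses a single common dispersion; strongly feature-specific
  overdispersion (e.g. the latent-factor genes in the generator itself)
  makes those features' p-values anti-conservative. At the planted effect
  sizes this does not affect calls, but real-data use would warrant
  tagwise shrinkage.
* The quantile adjustment by scale-and-round is an approximation; for
  very small counts the rounding can shift a total by a few units.
* Pathway scores ignore gene weighting and topology within pathways; the
  median is deliberately simple and robust.
* Betweenness normalization uses the whole-graph node count even on
  disconnected graphs.
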