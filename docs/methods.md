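# Methods

This note documents the models and procedures implemented in
`progulons`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical decisions a user
reproducing results should know about.

## Tree-based dissimilarity

Protein–protein similarity is measured with a surrogate-tree
dissimilarity in the style of treeClust.  For every experiment column
*j* a regression tree predicts column *j* from all other columns,
fitted on the rows where *j* is observed (columns observed in fewer
than `min_rows = 20` rows are skipped).  Trees are grown with
`min_samples_leaf = 5` and pruned by weakest-link cost-complexity
pruning under a K-fold cross-validated **1-SE rule** (default
`cv_folds = 10`): the pruning sequence of per-node collapse thresholds
is computed once from the unpruned tree, each fold fits one unpruned
tree whose predictions at every candidate alpha are obtained by
thresholded routing (no refitting), and the largest alpha whose CV
error is within one standard error of the minimum wins.  Trees pruned
back to the root are discarded; if none survives, the matrix has no
usable structure and an error is raised.

The dissimilarity of two proteins is the fraction of retained trees in
which they occupy different leaves (the unweighted variant; a
deviance-weighted variant is available via a flag).  Trees for which a
protein has no observed predictor are skipped for that protein, and the
per-pair denominator is adjusted; a pair with no usable tree is
*undefined* (NaN), never silently zero.  Missing predictor values are
routed through medians of the tree's training rows, frozen at fit time,
a deterministic stand-in for surrogate splits.

Granularity caveat: with *T* retained trees the dissimilarity takes
values on a 1/*T* grid.  On small, fully observed matrices this
produces large tie blocks (many pairs at exactly 0), which makes the
top-fraction edge selection arbitrary at the boundary.  Real
perturbation panels — and the synthetic default of block-structured
missingness — diversify the per-pair denominators and effectively
break these ties.  Boundary ties that remain are broken by
lexicographic pair order, which is logged.

## Seed discovery

Two clusterings with different principles consume asymmetric inputs:
OPTICS (precomputed-distance, Xi extraction, default `xi = 1e-4`,
`min_pts = 5`; undefined dissimilarities imputed to the maximum
observed distance) sees the full dissimilarity matrix, while the
cohesiveness clustering sees only the network of the top-fraction
(default 0.5%) most similar pairs.  Cohesiveness of a vertex set V is
w_in / (w_in + w_bound + penalty·|V|) with edge weights 1 − d,
`penalty = 2`; each unused vertex (descending weighted degree) greedily
grows a candidate by single-vertex additions/removals until no move
improves cohesiveness; candidates with match coefficient ≥ 0.8 merge;
survivors need size ≥ 4 and graph density ≥ 0.4.  OPTICS clusters that
span the entire dataset are dropped as structureless.  A seed is the
intersection of an OPTICS cluster with its maximal-overlap cohesiveness
cluster (ties by Jaccard, then lexicographic order; each graph cluster
serves at most one OPTICS cluster); intersections below 4 proteins are
dropped.

`min_pts`, the penalty and the merge threshold follow the defaults of
the cited algorithms' reference implementations; they are exposed in
the configuration and echoed to the run log rather than asserted as the
only sensible values.

## Balanced Random-Forest ensembles

Training positives are the seed members with at least
`min_train_features = 45` quantified ratios (overridable, e.g. 7/5 for
narrow experiment subsets); negatives are `n_negatives = 1000` proteins
drawn uniformly without replacement from all eligible non-seed proteins
(a smaller pool is used in full with a warning).  The ensemble trains
M = ⌈|negatives| / n_pos⌉ balanced models so that each pool negative is
used approximately once; negatives are cycled without replacement and
the pool reshuffled on exhaustion.  Each model is a forest of 500
unlimited-depth CART trees (Gini splits, bootstrap resampling,
√p-feature subsampling) trained on all positives plus n_pos negatives.
Missing values are median-imputed per feature from each model's own
training rows, and the imputation is frozen for scoring.  Only proteins
with ≥ `min_test_features = 30` ratios are scored; ineligible proteins
are excluded with a recorded reason rather than scored zero.

The forest kernel is a purpose-built, numba-compiled implementation:
the scheme trains hundreds of forests on ~20-row training sets per
progulon, a regime where per-model overhead dominates, and the compiled
kernel executes a full 500-tree model (fit plus scoring) in
milliseconds.  Its scores are cross-checked against an independent
general-purpose Random-Forest implementation in the test suite.

Leave-one-out cross-validation retrains the full ensemble once per seed
protein with that protein removed from the positive class (same
negative pool and rng stream per fold); the held-out protein's score
from the retrained ensemble is its LOO score.  Quality gates: ROC AUC
of LOO positive scores against the ensemble scores of the negative
training proteins must be ≥ 0.99, and ≥ 4 of the 10 highest-scoring
proteins (positives represented by their LOO score — the stricter of
the two possible readings) must be cross-validated positives.

A structural note on the AUC gate at desk scale: when the eligible pool
is smaller than 1,000, *all* non-seed proteins serve as negatives, so
genuine module members outside the seed sit in the negative class.  If
those members are exactly as tightly co-regulated as the seed (as in a
uniform synthetic module), their scores are exchangeable with the
positives' LOO scores and the expected AUC is capped at
1 − ½·(contaminants/negatives) — e.g. ≈ 0.981 for 20 contaminants among
520 negatives — below the 0.99 gate even though separation from true
background is perfect.  The gate behaves as published when seeds are
tighter than the module periphery, which is how clustering-derived
seeds arise in real data.

## Membership cutoff by connectivity

The co-regulation network is built once from all scoreable proteins.
For a candidate member set, a one-sided Fisher's exact test asks
whether its internal pairs are enriched among the network's edges,
over the universe of all pairs of scoreable proteins (pairs with
undefined similarity count as non-edges).  The cutoff grid is the 51
inclusive points {0.50, 0.51, …, 1.00}; the minimum cutoff whose member
set (≥ 2 members) reaches P < 0.05 defines the progulon, and a
candidate with no qualifying cutoff is discarded — a reported negative
outcome, not an error.  Training positives are members only if their
LOO score clears the cutoff; they are not force-included.

Progulons are visualised by exact t-SNE (no Barnes–Hut approximation)
on the member-restricted dissimilarity matrix; perplexity is shrunk
with a warning when members are few, and coordinates are deterministic
given the rng seed.

## Group statistics

All correlations are Spearman on pairwise-complete observations
(undefined below 3 shared points).  *Contribution* is the median over
genes of the mRNA–protein rho; *coordination* is the median
within-group pairwise rho of either layer; *scale* is the median
per-member MAD (unscaled — no 1.4826 consistency factor, since the
statistic is only compared between groups).  Permutation tests draw B
(default 10,000) uniform same-size gene sets from the universe and
report P = (r+1)/(B+1), whose floor 1/(B+1) is attained when the
observed median beats every null draw.  Annotation enrichment is a flat
one-sided Fisher test per (group, set) over the universe of analysed ∩
annotated proteins, sets below 20 members excluded, Bonferroni across
all tested combinations (graph-aware ontology elimination is out of
scope).  Conservation of co-regulation classifies pairs with
rho > 0.5 in the reference dataset into same-progulon / different-
progulon / no-progulon categories and compares conservation rates in a
second dataset by Fisher's test.  Same-chromosome enrichment contrasts
a group's same-chromosome pair fraction with the mapped universe's by a
two-sided Fisher test on the pair table.

## Screen scoring

Well values are normalised by subtracting the median of the
negative-control wells of the same plate, readout and replicate (the
library is biased toward real phenotypes, so the plate median would be
confounded).  Per readout, the hit threshold is a multiple of the SD of
the normalised control *wells* across plates and replicates: 3× for
SD ≤ 0.05, 2× for 0.05 < SD ≤ 0.13, 1× above.  Candidate activity per
siRNA is the mean of its normalised replicate values (median behind a
flag); a gene scores a readout when ≥ 2 of its 3 siRNAs exceed the
threshold in the same direction, at most one point per readout
regardless of direction.  Points accumulate under per-process caps —
replication 5 (EdU, EdU+Aph, RPA, RPA+HU, RPA+Aph), DNA damage 4
(53BP1, γH2A.X, γH2A.X+HU, γH2A.X+Aph), cell cycle 4 (G1/S/G2M changes
capped at one point per experimental condition; four conditions) — for
a maximum cumulative score of 13.  Confidence tiers: high above 13/2,
medium above 13/3, otherwise unvalidated.

## Synthetic data

`simulate_proteomehd` plants modules as shared latent perturbation
responses: a member row is the module latent (sd = response_sd) plus
member noise (sd = noise_sd), so the implied within-module correlation
is response_sd²/(response_sd² + noise_sd²); background rows are
independent noise.  Missingness is block-structured by default — each
protein is observed in a contiguous window of experiments sized by its
detection fraction — emulating per-project quantification in real
panels (uniform missingness is a flag).  Latents and noise are Gaussian
by default with a heavy-tailed (t, df = 3) option for ratio outliers.
`simulate_paired_omics` gives each group an mRNA latent (coordination),
a coupling coefficient α transmitting mRNA into protein
(contribution), and an optional protein-level latent that lets protein
coordination exceed what mRNA transmits.  `simulate_screen` lays out
plates with negative controls, Gaussian plate offsets, per-siRNA
efficacy variation, and three replicates (six for aphidicolin
conditions).

What the generators do *not* emulate: peptide-level quantitation,
intensity-dependent missingness, correlated background structure,
batch effects beyond plate offsets, and off-target siRNA phenotypes.
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour under the stated noise model, not performance guarantees on
any particular real dataset.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale: matrices of
~250–530 proteins × 100 experiments, modules of 15–30 members, screens
of a dozen genes.  These sizes were chosen so that every planted
structure is recoverable under the stated noise model while each full
pipeline run completes in seconds.  Every source of randomness flows
from a single integer seed per run (matrix generation, negative
sampling, per-model tree seeds, OPTICS/t-SNE, permutation draws), and
identical configurations produce byte-identical outputs.

## Known limitations

* The dissimilarity's 1/T granularity limits edge-selection resolution
  on matrices with few informative columns (see above); the network
  stage needs input rich in co-regulated structure, as real proteomes
  are.
* The greedy cohesiveness clustering finds local optima of the
  objective (verified exhaustively on small graphs); it does not claim
  byte-parity with the reference Java implementation.
* Negative-pool contamination bounds the attainable LOO AUC when the
  candidate module extends beyond the seed and the pool is small
  (quantified above).
* ID mapping is exact → synonym table → case-insensitive; no external
  identifier services are consulted.
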