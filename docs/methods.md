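# Methods notes

This note documents the models behind `hepregen`, the defaults that
matter, what the synthetic generators do and do not emulate, and the
design choices made where the procedures admitted more than one reading.

## Scope and data model

All expression containers are `AnnData` objects (cells × genes) with
per-cell `sample`, `group`, `timepoint` and, for layered references,
`layer` labels; a `log_normalized` flag in `.uns` guards against double
normalization. Normalization is library-size scaling to 10,000 counts per
cell followed by log(1 + x). Cells with zero total counts are an error
(reported by identifier) rather than silently dropped: in this pipeline a
zero cell always indicates an upstream filtering bug.

## Module scoring

The score contrasts a signature against expression-matched controls:
genes are ranked by mean expression over the scored cells and cut into 24
equal-frequency bins; each signature gene draws 100 controls from the
non-signature genes of its bin (without replacement when the pool
suffices, with replacement otherwise; a bin fully occupied by the
signature falls back to the nearest-ranked non-signature genes). The 24/100
defaults follow the widely used convention for this estimator. Two
consequences matter in practice:

- *Signature exclusion.* Control pools exclude the signature's own genes.
  With contaminated pools, a signature that dominates its expression bin
  is partially compared against itself and a planted log-scale offset δ is
  recovered attenuated; with exclusion the between-group score gap is an
  unbiased estimate of δ (verified by simulation in the test suite).
- *Within-sample centering.* Because controls are matched on average
  expression *in the scored matrix*, scoring each timecourse sample
  separately absorbs exactly the between-sample dynamics. Any analysis of
  score dynamics over time must therefore score the pooled matrix once and
  aggregate per sample afterwards; `pipeline.timecourse_coupling_pipeline`
  does this.

Cycling cells are flagged when their cell-cycle score strictly exceeds
mean + 3·sd (sample sd, n − 1). The rule is invariant under positive
affine transformations of the score and flags ≈ 0.135 % of cells under a
Gaussian null; with all-identical scores nothing is flagged.

## Differential expression and the ARS

The rank-sum test uses exact enumeration when both groups have ≤ 10 cells
and no ties occur, and otherwise the normal approximation with tie
correction and *no* continuity correction — the convention of the
single-cell DE implementations this wrapper emulates; at the global null
the raw p-values are calibrated to within Monte-Carlo error (checked over
2,000 genes). The fold change reverses log1p before averaging and adds a
pseudocount of 1 on the count scale, so fixtures are exactly computable.

Temporal clustering z-scores each gene's per-timepoint mean profile and
runs fuzzy c-means (Euclidean, fuzzifier m = 2, seeded membership
initialization, convergence at max |Δu| < 1e-6 or 300 iterations).
A cluster is "transplant-upregulated" iff its centroid at both early
timepoints (defaults R1_1W, R1_3W) exceeds its centroid at the baseline
(R0_0W) and at the late timepoint (R1_12W); genes are assigned by maximal
membership. The cluster-selection rule is this package's explicit,
testable criterion — the upstream tool it replaces leaves the choice to
visual inspection. Constant profiles are dropped with a warning before
z-scoring.

The ARS is a set union: genes with log₂FC strictly above 1 and adjusted
p strictly below 0.05, united with the temporal early-up genes. Both
thresholds are strict, so boundary values are excluded; relaxing either
threshold can only grow the signature.

## Zonation

Layer 1 is pericentral (central vein, glutamine-synthetase-positive
territory) and layer 8 periportal; the staining-comparable grouping is
fixed: layers 1–3 → Zone3, 4–6 → Zone2, 7–8 → Zone1.

The PLSR coordinate regresses the centered layer index on z-scored marker
expression (NIPALS, 2 components by default); predictions are clamped to
[1, 8] and per-sample dispersion is the sample sd of the coordinates.
Treating the layer as a single continuous response is this package's
choice; z-scoring makes predictions invariant to affine rescaling of any
predictor. A caution encoded in the tests: a PLSR fitted to *permuted*
labels still projects mostly onto the dominant expression axis — which in
a zonated reference is the zonation gradient itself — so permutation nulls
must be evaluated out-of-sample.

Marker selection fits a preliminary gradient-boosted classifier on all 18
candidates and ranks features by mean absolute additive (tree SHAP)
contribution over cells and classes; only the ranking is contractual, not
the attribution engine. The layer classifier is an XGBoost multiclass
model with fixed, documented defaults (150 trees, depth 3, learning rate
0.2, hist grower, single thread) — deliberately plain; the contract is
the evaluation protocol, not a tuned model. Class imbalance is handled by
weights w_c = N/(8·N_c); evaluation is stratified 5-fold CV with seeded
splits on identifier-sorted cells (so the metric is invariant to input
order), scored by macro one-vs-rest AUC. Macro (rather than weighted)
averaging is this package's reading of "mean multiclass AUC". Argmax ties
resolve to the lowest layer index.

## Trajectory coupling

DTW uses the symmetric step pattern on |aᵢ − bⱼ| with cumulative
boundaries, no window and no path-length normalization — the simplest
defensible dialect for 8-point series; the implementation is pinned
exactly to an exhaustive warping-path oracle. Series are z-normalized
before comparison because pathway scores and zone proportions live on
different scales; zero-variance series z-normalize to all zeros with a
warning.

Per pathway the three per-zone distances are reported, and the default
aggregate is their **minimum** (the closest zone). The three zone
proportions are complementary — they sum to 1 — so a pathway that tracks
one zone perfectly is necessarily anti-correlated with the others; a mean
aggregate would penalize exactly the strongest couplings (in simulation
it ranks a perfectly Zone2-coupled pathway below unrelated noise
profiles). The mean remains available (`aggregate="mean"`), and the
per-zone columns allow any other combination. Ranks are deterministic
(ascending aggregate, lexicographic tie-break).

## Regulon specificity

RSS = (target-group mean − pooled-complement mean) / max activity over
all cells. "Other groups" is the pooled complement, not a mean of
per-group means — the two differ on unbalanced data and a fixture pins the
choice. The maximum is taken over all cells (documented choice; the
alternative, non-target cells only, is not used). Zero-max regulons score
0 rather than NaN so tables stay totally ordered; for nonnegative
activities RSS lies in [−1, 1] and is invariant to positive rescaling of a
regulon's activity vector.

## Co-expression sub-networks

The network is unsigned with soft power β = 6 (the standard unsigned
convention; both are configurable since real analyses vary). Adjacency
diagonals are zero so connectivity sums need no exclusion terms; TOM
diagonals are 1, and "directly connected to the anchor" therefore uses
off-diagonal TOM entries only. The module eigengene is the first
principal component over cells of the z-scored module submatrix,
sign-oriented so its average correlation with module genes is
nonnegative, and kME is the Pearson correlation of each gene with it.
Module *discovery* is out of scope — modules arrive as inputs (planted by
the simulator), isolating the extraction math: keep genes with kME
strictly above 0.25 and TOM weight to the anchor strictly above 0.025,
always retain the anchor, and report the anchor's kME rank (descending,
lexicographic tie-break). Raising either threshold can only remove genes.

## Co-IP-MS filtering

The four steps run in a fixed order and each is logged (input size,
output size, removed ids). Exclusion phrasings ("fewer than 2 peptides")
become keep-rules with ≥; enrichment phrasings ("FC > 4") stay strict.
The intensity rule "mean IgG + 3·SD" is computed from the protein's own
IgG replicates when at least two exist, and from the table-wide IgG
intensity distribution otherwise (both logged). A zero IgG mean passes
the fold-change rule by convention (infinite enrichment). The iBAQ share
denominator is the post-contaminant table, so the abundance step must run
last; the first three steps commute (asserted on the fixture). Zero
iBAQ_IgG values are imputed with half the table-wide minimum nonzero
value before log₂(iBAQ/iBAQ_IgG); imputation never touches nonzero
values. Consensus interactors are the id intersection of two filtered
experiments with the two log₂FC and log₂ iBAQ-ratio values averaged.

## Synthetic generators: what they emulate, and what they do not

All generators share a log-normal/Poisson counts model: planted structure
lives in per-gene log means, per-cell Gaussian noise of width `noise_sd`
(default 0.3) is added on the log scale, and counts are Poisson draws
from the exponentiated values. Every generator is deterministic given
`SimConfig.seed` and returns its ground truth explicitly.

- *Zonated reference*: 8 layers × 150 cells; 18 candidate markers at high
  baseline abundance (log-mean 4, ≈ 55 counts — zonation markers are among
  the most abundant hepatocyte transcripts). The four strong markers span
  `effect_size` natural-log units across the lobule; the default
  `effect_size = 3` (≈ 20-fold) reflects the dynamic range those genes
  show across lobule layers in reference atlases, where gradients of one
  to two orders of magnitude are typical. Weak markers span at most 20 %
  of that; background genes are layer-independent.
- *State groups*: five groups (Adult, Afp_low, Afp_low_cycling, Afp_high,
  Host). A single latent factor carries the Afp program: its group means
  follow the grade Adult < Afp_low = Afp_low_cycling < Host < Afp_high
  and the 200 module genes load on it with Afp highest (0.9), so the Afp
  expression gradient and the module-hub structure are two views of one
  planted signal. A 78-gene signature is elevated in the three
  reprogrammed groups (weakly in Host), and 20 cycling genes only in
  Afp_low_cycling. With `effect_size = 0` all groups are exchangeable.
- *Timecourse*: eight samples (R0_0W … R2_12W) whose Zone2 proportion
  rises through the first round, peaks at R1_12W/R2_3W and falls back to
  near baseline; Zone1/Zone3 split the remainder. One pathway profile is
  an affine transform of the Zone2 series plus noise; 20 decoys are
  independent noise. With expression enabled, cells draw layers from the
  zone mixture using the same marker model as the reference (shared
  sub-seed), and each pathway's 30-gene set tracks its profile.
- *Regulon activities*: lognormal activities around per-regulon baselines;
  one regulon per group has its target-group activities scaled by
  (1 + effect_size).
- *Co-IP tables*: 12 records each for Ctl and AFP-OE — four planted true
  interactors (one with iBAQ_IgG = 0 to exercise imputation), seven
  near-misses violating exactly one rule each (1 peptide; score 29;
  coverage 4.9 %; FC 3.9; intensity below mean IgG + 3·SD; contaminant;
  iBAQ 0.09 %), and one experiment-specific passer per table. Boundary
  records are fixed constants; seeded jitter only touches fields far from
  any rule boundary.

Not emulated: ambient RNA, doublets, batch effects, dropout beyond
Poisson sampling, gene-length or GC bias, realistic gene-gene correlation
outside the planted module, and any spatial structure beyond the layer
labels. Passing tests therefore demonstrate that the *procedures* recover
planted structure under clean generative assumptions — they are evidence
of implementation correctness, not of performance on real tissue data.

## Problem sizes and numerical choices

The test suite and the acceptance script use 1,200-cell references,
1,650-cell group matrices, 8 × 500-cell timecourses, 2,000-gene null
panels, 100-replicate coupling studies and 100,000-score calibrations —
sizes at which every Monte-Carlo band in the tests is a 3σ band of the
quantity being estimated and the whole suite runs in well under a minute
per module on one CPU. Fuzzy c-means converges at max membership change
< 1e-6; TOM symmetry is enforced to 1e-9; eigengenes are unit-norm;
dispersion of samples with fewer than two cells is reported as missing
rather than 0.

## Known limitations

- The temporal cluster-selection rule and the PLSR response coding are
  explicit stand-ins for under-specified upstream conventions; both are
  exposed as parameters.
- The layer classifier's fixed defaults are not tuned; on hard (noisy)
  references a tuned model would score higher. The package contracts the
  protocol and metric only.
- DTW is univariate, unwindowed and unnormalized by design; 8-point
  series do not support more elaborate dialects.
- The Co-IP "score" column is treated as a generic search-engine quality
  score; engine-specific calibrations are out of scope.
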