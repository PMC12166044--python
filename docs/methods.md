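# Methods

This note records the models, parameter choices and numerical
conventions behind `netstrat`, and what the synthetic cohorts do and
do not establish about behaviour on real data.

## Synthetic cohorts and what they emulate

All testing runs on a linear-Gaussian latent-factor model: module `m`
has a per-sample factor `f_m ~ N(0,1)` and a member gene `g` observes
`x_g = baseline_g + loading_g · f_m + ε`, `ε ~ N(0, noise_sd²)`, on
the log2 scale; background genes are baseline plus noise. This is the
minimal structure under which eigengenes, kME and co-expression
modules are well defined and recoverable, which is exactly what makes
it the right null bed for this pipeline: every downstream statistic
has a planted ground truth to be checked against.

Defaults are study-scale: a reference of 150 samples × 2000 genes with
five planted modules of 469/323/190/48/42 genes; `noise_sd = 0.5`;
loadings drawn uniformly from (0.4, 1.2) so that modules contain both
hub-like and peripheral members and the kME ranking has real signal to
recover; baselines `N(7, 2²)` mimicking log2-TPM abundance. The
clinical generator produces 13 patients (8 responders / 5
non-responders by default) with paired Bx1/Bx2 samples: the response
module's Bx1 factor is placed `effect · U(0.1, 1)` above (responders)
or below (non-responders) the planted threshold, so at `label_noise =
0` the factor orders the classes perfectly; Bx2 factors share the Bx1
factor at a configurable within-patient correlation (default 0.8 —
the real-world value is unknown, so it is a parameter, not a claim)
plus an additive treatment shift on selected modules (default +1 on
the response module). A mild per-gene batch shift/scale (SD 0.3 / 0.1
on the log scale) separates the clinical cohort from the reference so
harmonization is exercised, not bypassed. Clonotype tables draw clone
sizes from a discrete power law (exponent 2) truncated at the read
budget, with per-sample totals scaling as `exp(0.8 · factor)` so
immunoglobulin abundance tracks the immune module.

What the synthetic model does **not** emulate: count noise and
mean–variance coupling of real RNA-seq, correlated modules,
copy-number or purity effects, nonlinear batch distortions, and
repertoire structure beyond clone-size heavy tails (no V/J usage, no
sequence content). Passing tests therefore establish correctness of
the algorithms and calibration of the statistical gates under the
model's assumptions, not clinical performance: the 92–100% training
accuracies on synthetic cohorts are recovery of a planted signal, not
an estimate of real-world accuracy.

## Reference network and module detection

Correlation is the biweight midcorrelation with the standard 9-MAD
outlier weights; a vector whose MAD is zero falls back to Pearson
centering (the conventional "individual fallback"), and a constant
vector yields NaN — explicitly distinct from 0, since "no evidence" is
not "no correlation". Adjacency is signed-hybrid, `max(bicor, 0)^β`
with soft-threshold power β = 5; the topological overlap matrix uses
the standard shared-neighbour formula with a zero self-dissimilarity.

Module detection is a deliberately simplified dynamic hybrid cut.
After average-linkage clustering of the TOM dissimilarity, the tree is
traversed top-down: a node is split when its merge height exceeds the
static cut height (0.995) **or** when the gap between its height and
its taller child exceeds a threshold derived from `deep_split` —
`(1 − (0.64 + 0.08·ds)) · 3/4` of the usable height range (the same
interpolation scale the published heuristic uses for its core-scatter
and gap parameters), giving 0.15 at the default `ds = 2`. Tight
branches have small top gaps and survive whole; loosely glued
background chains shatter. Clusters under the minimum size (30)
dissolve to label 0. The PAM stage then reassigns an unlabeled gene to
its nearest module (smallest mean dissimilarity) only if it fits no
worse than that module's most peripheral member — a radius rule that
keeps genuinely unstructured genes grey. The full published heuristic
has many undocumented corner cases; this reconstruction is documented,
deterministic and permutation-equivariant, and recovers the planted
partition at ARI ≈ 0.9 with per-module Jaccard > 0.9 on the default
reference.

The topological-significance gate compares each module's density-based
statistics against 100 random gene sets of equal size drawn without
replacement from the 2000-gene universe; a module passes at median
Z ≥ 2. The two statistics are the subnetwork density and its mean
adjacency; for a fully weighted network with zero diagonal these
coincide by definition (both are the mean off-diagonal adjacency), so
the median Z equals either — both are still reported to keep the
gate's definition explicit. When the null is degenerate (sd ≈ 0 up to
float noise), Z is 0 if observed equals the null mean, else ±∞ with a
warning. Stability assessment repeats full detection on 63.2% sample
subsamples (50 iterations by default in the API; the pipeline's
RunConfig ships with the stage off and the demo enables cheaper
settings, since the gate is a parameter-selection tool rather than a
per-run output).

## Eigengenes, projection, harmonization

The eigengene model stores per-gene means and SDs, the first two
right-singular vectors of the standardized submatrix, and explained
variance fractions. Sign conventions: PC1 is oriented to correlate
non-negatively with the module's mean standardized expression (so the
eigengene "points along" the module); PC2's largest-magnitude loading
is made positive. Constant genes are dropped before the decomposition
with a warning.

Cross-cohort comparability uses reference-moment matching: each shared
gene in the target cohort is shifted/rescaled so its cohort mean and
SD equal the reference's; a zero-variance target gene is only
re-centered. This intentionally replaces empirical-Bayes batch
shrinkage: with a single target batch against a fixed reference, the
shrinkage step mainly matters for tiny batches, and exact moment
matching makes the round-trip identity (harmonize → project reproduces
reference scores to 1e-9) provable. Projection standardizes by the
*reference* moments and multiplies into the stored eigenvectors; it
refuses to run on a partial gene basis, because a silently truncated
basis changes the score scale.

## Signature scoring

kME-derived gene sets come in threshold form (kME > θ, default 0.9)
and top-n form (default 3), ordered by descending kME then gene id.
The single-sample enrichment score ranks the gene universe per sample
(average ranks on ties), walks genes in decreasing rank and integrates
the difference between the weighted in-set cumulative mass (weights
`rank^0.25`; the exponent is a config default, since the original
setting is not pinned down) and the uniform out-of-set mass. No
cross-sample renormalization is applied, so scores are only comparable
within a fixed universe and exponent. GSVA scoring estimates a
Gaussian-kernel CDF per gene across samples (bandwidth sd/4, with
*population* SD so duplicating samples is a no-op), converts to
per-sample symmetric rank statistics `|rank − N/2|`, and reports
`max(walk) + min(walk)`. Note a consequence of the gene-relative CDF:
a gene set that is uniformly highly expressed does **not** score high —
only sample-specific activation does; tests are written accordingly.
Mean-score classification averages raw expression over the set
(optionally per-gene standardized — used for the single-hub-gene
classifier) and splits at the cohort median with ties going to "low".
Over-representation is a hypergeometric upper tail with
Benjamini–Yekutieli adjustment across the collection.

## Classification and subtype calling

The threshold classifier realizes a depth-1 conditional-inference
tree: the association gate is a permutation test of the linear
statistic `Σ score·label` — exact enumeration of label placements for
n ≤ 12, Monte-Carlo (default 10 000 draws, observed arrangement
counted once) above. Only if p < α (0.05) is a cutoff placed, at the
admissible midpoint (each leaf ≥ 3) maximizing the standardized
two-sample statistic; ties prefer the lowest cutoff and a score
exactly at the cutoff goes to the "≤" side. Otherwise the model is a
flagged majority-class predictor. MCC is reported as `N/A` whenever a
confusion-matrix marginal is zero and F1 when positives are absent —
explicit values, never silent zeros.

Subtype calls use Spearman correlation (average ranks) against
centroid profiles; margin < 0.1 → INDETERMINATE; a constant sample is
INDETERMINATE with a reason code. Rescue maps predicted responders to
the good-prognosis subtype and predicted non-responders to the
poor-prognosis one, recording `rescue_source`. A subtlety worth
stating: the *value* midpoint of two arbitrary centroids is not
exactly rank-equidistant from both under Spearman; exact zero margin
holds for symmetric constructions (e.g. centroids that are pair-swap
permutations of each other), which is how the margin rule is tested.

## Patient-specific networks

The interpolation weight is `(N+1)·e(ref ∪ {q}) − N·e(ref)` with N
the reference size; whether the leave-in term carries N or N+1 is a
convention, so the constant is part of the network provenance. The
default edge function is bicor for consistency with the reference
network; plain Pearson is available by flag (the convention of the
cited single-sample approach). Conversion to adjacency zeroes negative
edges and divides by the per-network maximum positive weight (a global
clip at 1 is available by config; the original scaling is not
specified, so the choice is recorded). Per-edge interpolated weights
are intentionally high-variance — only aggregates (per-gene
connectivity, module-level features, group means) are stable, and the
tests treat them that way. Undefined features (isolated gene, zero
clustering denominator) propagate as NaN flags and are excluded from
downstream tests with a logged count, never imputed as zeros, which
would bias differential wiring tests toward the null.

## Differential testing and sectors

TMM factors follow the trimmed-mean-of-M-values recipe (trim 30% on M,
5% on A, inverse asymptotic-variance weights, reference = deepest
library, factors rescaled to geometric mean 1). The moderated t shrinks
per-feature variances toward a prior fitted by moment matching on
log-variances (digamma/trigamma inversion); `prior_df = 0` recovers
the ordinary t exactly, `trend=True` replaces the constant prior with
a lowess fit of log-variance against mean. The implementation is
cross-checked against the Bioconductor reference implementation on a
shared fixture in the test suite. Differential tables use
Benjamini–Hochberg (matching the FDR < 0.05 usage downstream); BY is
reserved for gene-set enrichment. Paired deltas subtract Bx1 from Bx2
within patient, dropping incomplete pairs with a warning.

Sector assignment is a reconstruction — the upstream construction is
not fully specified — so the geometry is explicit: with θ =
atan2(t_net, t_expr), sectors 2 and 5 are wedges within a boundary
angle (default 30°) of the +t_net and −t_net axes (wiring-dominant);
sectors 1/3 flank 2 and 6/4 flank 5 (mixed); boundary ties go to the
lower-numbered sector and the origin is unassigned. The wedges are
symmetric under t_expr sign flips by construction.

## Repertoire diversity

Entropy is in natural log; Evenness = H/ln(n_clonotypes) is
base-invariant and undefined (flagged, not zero) for a single
clonotype. D50 is the minimal number of top clonotypes reaching half
the reads (top clone at exactly 50% → D50 = 1). Gini uses the
population formula on sorted counts; the companion index reported as
`gini_simpson` is 1 − Σp² — the conventional heterozygosity-style
measure, chosen because the alternative name sometimes attached to it
is not defined precisely enough to reimplement. Downsampling draws
without replacement (multivariate hypergeometric — reads are a finite
multiset), five repeats, per-metric median, with per-biopsy default
depths 8500 (Bx1) and 400 (Bx2); samples below depth are excluded
rather than extrapolated.

## Problem sizes and determinism

The shipped defaults run the full study shape: the demo builds the
150 × 2000 reference, a 26-sample clinical cohort, 78 patient
networks, and completes in about a minute on one CPU; simulation-based
calibration checks use 100–400 repetitions. All randomness flows from
named `numpy` generators seeded from a single integer; reports are
JSON with sorted keys, which makes every artifact byte-reproducible
under a fixed seed (asserted in the test suite).

## Known limitations

- The dynamic-cut reconstruction matches the published heuristic's
  *parameters*, not its exact branch decisions; on strongly nested or
  correlated module structures the partitions may differ.
- Reference-moment harmonization assumes a location/scale batch model;
  nonlinear platform effects are out of scope.
- The GSVA and enrichment scorers are dense implementations intended
  for ≤ a few thousand genes × hundreds of samples.
- No survival modelling, no multi-batch designs, no blockwise network
  decomposition for >20k genes.
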