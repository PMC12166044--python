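# netstrat

Network-based stratification of triple-negative breast cancer (TNBC)
expression cohorts.

Metastatic TNBC trials collect small paired-biopsy cohorts (a
pre-treatment Bx1 and an on-treatment Bx2 sample per patient) that are
far too small to discover expression programs de novo. `netstrat`
implements the alternative: learn weighted gene co-expression modules
once on a large pre-treatment reference cohort of basal-like tumours,
then carry those modules to the clinical cohort as portable summaries —
eigengene projections, kME-derived gene signatures, single-sample
enrichment scores, patient-specific subnetworks — and use them to
predict treatment response, rescue indeterminate molecular subtype
calls, and relate immune modules to B-cell-receptor repertoires.

It is written for computational biologists working with bulk RNA-seq
cohorts: every stage is a plain library function over pandas
containers, with a thin `netstrat` CLI on top, and a synthetic-data
module generates full study-shaped cohorts with planted ground truth
so the whole pipeline is testable without any controlled-access data.

## The model

**Reference network.** On the log2 expression of the top 2000 most
variable genes, the signed-hybrid adjacency is
`a_ij = max(bicor(x_i, x_j), 0)^5` with `bicor` the biweight
midcorrelation. Modules are branches of the average-linkage dendrogram
of the topological-overlap dissimilarity
`1 − (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, cut by a
simplified dynamic hybrid procedure (cut height 0.995, deepSplit 2,
minimum size 30, PAM stage on). Modules must pass a topological
significance gate: median Z ≥ 2 of density-based statistics against
100 equally sized random gene sets.

**Module summaries.** The eigengene is PC1 of the standardized module
submatrix, oriented to correlate non-negatively with mean module
expression; `kME(g) = cor(x_g, eigengene)` measures membership. A new
cohort is first harmonized by reference-moment matching (per-gene
location/scale to the reference batch) and then *projected* using the
reference means, SDs and eigenvectors — never refitted.

**Classification.** Response classifiers are depth-1 conditional
inference trees: a permutation test on `Σ score_i · label_i` gates the
split (α = 0.05, minimum leaf 3); accuracy, MCC and F1 are reported
with explicit `N/A` for degenerate confusion tables. Subtypes are
called by Spearman correlation against centroid profiles, with calls
whose top-two margin is below 0.1 flagged INDETERMINATE and rescued by
the network response predictor (predicted responders → good-prognosis
subtype, non-responders → poor-prognosis).

**Patient-specific networks.** Each module is decomposed per sample by
linear interpolation against the reference (`(N+1)·e(ref ∪ {q}) −
N·e(ref)`), converted to a [0,1] adjacency, and summarized by
connectivity, MAR, clustering coefficient, density, centralization and
heterogeneity; group differences in expression vs wiring are tested
with an empirical-Bayes moderated t and visualized as six angular
sectors of the (t_expression, t_network) plane.

**Repertoires.** Clonotype tables yield Shannon entropy, Evenness
(entropy / ln #clonotypes), D50, Gini and Gini–Simpson, optionally as
medians over five rounds of read downsampling (defaults 8500 reads for
Bx1, 400 for Bx2).

## Worked example

```bash
netstrat demo --seed 7 --out demo_out/
```

builds the default synthetic reference (150 samples × 2000 genes with
five planted modules of 469/323/190/48/42 genes), generates a
13-patient paired-biopsy cohort whose response is driven by module 3,
and runs both pipeline stages. It prints:

```
Network stratification report
==============================

Response module: M3

Classifier training performance (Bx1):
  eigengene            accuracy  100.0%  MCC  1.000  F1  1.000
  kme_signature        accuracy  100.0%  MCC  1.000  F1  1.000
  top_genes            accuracy   92.3%  MCC  0.854  F1  0.933
  hub_gene             accuracy  100.0%  MCC  1.000  F1  1.000
  external_signature   accuracy  100.0%  MCC  1.000  F1  1.000
  rescued_subtype      accuracy   84.6%  MCC  0.732  F1  0.857

Subtype no-call rate: 84.6% before rescue, 0.0% after

Patient networks: 78 (26 samples x 3 modules)
```

Reading it: the pipeline identified the planted response module (M3)
purely from the Bx1 association gate; its eigengene, its kME > 0.9
signature, the top-3-gene signature and the single hub gene all
separate the 8 responders from the 5 non-responders at 92–100%
training accuracy on 13 patients; every indeterminate centroid call
was rescued by the network predictor; and 26 samples × 3 modules gives
the expected 78 patient-specific subnetworks. All artifacts under
`demo_out/` (module tables, projection models, scores, calls, sector
tables, reports) are byte-identical across reruns with the same seed.

The same two stages run on real data via
`netstrat build-reference --expression ref.tsv --out ref/` and
`netstrat analyze-cohort --reference-dir ref/ --bx1 bx1.tsv --bx2
bx2.tsv --clinical clinical.tsv --out cohort/`.

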