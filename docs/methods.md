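# Methods

## The model in brief

The pipeline analyzes counts from a targeted immune expression panel
(nCounter-style: endogenous probes plus housekeeping, negative-control and
positive-control probes) for a cohort of tumors labeled with one of four
driver-mutation groups. Its outputs are (i) relative immune-cell abundances
per sample, (ii) a hot/cold dichotomy of the cohort, (iii) per-gene
nonparametric differential-expression statistics across groups, and
(iv) Fisher-exact category enrichment and pathway-coverage accounting.

## Normalization

Counts are processed per sample in a fixed order; every step can be disabled
to match alternative conventions:

1. **Positive-control scaling** multiplies each sample by
   (grand geometric mean of per-sample positive-control geomeans) /
   (the sample's positive-control geomean), removing lane/assay efficiency.
2. **Background flooring** raises endogenous counts to the sample's
   mean + 2·SD of its negative controls. Flooring (not subtraction)
   preserves nonnegativity; mean + 2·SD is the common detection threshold
   for these assays.
3. **Housekeeping scaling** equalizes the geometric mean of housekeeping
   counts across samples; after this step those geomeans agree to 1e-9
   relative, which is asserted in tests.
4. **log2(x + pseudocount)** with pseudocount 1.0 (default), bounding the
   transform at zero counts. Whether a study log-transformed with a
   pseudocount or excluded zeros is often unstated; the pseudocount is a
   parameter for that reason.

Geomeans of control blocks floor isolated zero counts at 1 with a warning;
an all-zero housekeeping or positive-control column is a hard error naming
the sample. Control probes are dropped from the normalized output, which
contains exactly the endogenous genes in input order.

## Immune-cell scores

A population's score is the arithmetic mean of its markers' log2 normalized
expression — equivalently the log2 geometric mean on the linear scale. This
is the Danaher-style relative abundance: it supports between-sample
comparison per population, not absolute cell fractions (no simplex
constraint, no reference profiles). Markers are data (`resources/markers.yaml`,
overridable per run). Two points of note:

* figure text in the literature names a truncated "KIR3DL" symbol among the
  CD56dim NK markers; the packaged catalog uses KIR3DL1 and KIR3DL2;
* **total TILs** defaults to the mean of all 14 population scores. The exact
  subset used by any given study is often not restated, so the subset is a
  parameter;
* **cytolytic activity** is by definition `cell_score` on {GZMA, PRF1} and
  is implemented as exactly that call (asserted identical in tests).

Scores are translation-equivariant (adding c to every marker adds c to the
score) and monotone in each marker.

## Hot/cold classification

Samples are clustered on the row-centered population-score matrix with
agglomerative clustering (Euclidean distance, average linkage — common
heatmap defaults; both configurable since published dendrogram parameters
are rarely stated) and the tree is cut into exactly k = 2 clusters. The
cluster with the higher mean total-TIL score is labeled hot. An exact tie
labels the larger cluster cold (arbitrary, warned). Cutting at k = 2 rather
than at a height threshold reflects the two-main-groups structure the
dichotomy presumes. The 3×3 bi-clustering of a significant-gene submatrix
uses the same machinery on both axes, with clusters named S1–S3 / G1–G3 in
decreasing size order.

## Exact association test

Cluster-versus-genotype tables and enrichment 2×2 tables share one
two-sided Fisher exact core: the p-value is the total probability, under the
fixed-margin (multivariate hypergeometric) null, of all tables whose
probability does not exceed the observed table's (relative tolerance 1e-7,
matching common practice). For r×c tables the core enumerates all tables
with the observed margins; if enumeration would exceed a configurable bound
(default 2×10^6 tables) it falls back to a seeded Monte-Carlo estimate
(add-one estimator over 10^5 permutation draws), flagged in the result's
`method` field and in run summaries. Degenerate margins (an all-zero row or
column) return p = 1 with a warning. The 2×2 path is verified in tests
against independent hypergeometric enumeration and against
`scipy.stats.fisher_exact` to ≤1e-10.

## Differential expression

* **Omnibus:** Kruskal–Wallis with tie correction, p from the chi-squared
  reference with (groups − 1) df. A separately written vectorized version
  (rank formula over matrix rows) is used for large calibration runs and is
  tested against `scipy.stats.kruskal` per gene to 1e-10.
* **Post-hoc:** two-sided Wilcoxon rank-sum; exact null distribution when
  the combined n ≤ 25 with no ties, otherwise the normal approximation with
  continuity and tie correction. The switch is deliberate: exact where
  feasible, documented approximation elsewhere.
* **Multiplicity:** Benjamini–Hochberg step-up. Families are (a) all genes
  for the omnibus test and (b) all genes tested within one pairwise
  contrast; pairwise testing is gated on omnibus significance by default
  (configurable), since published workflows report both omnibus lists and
  pairwise contrasts without always stating the family structure. Raw and
  adjusted p-values are both emitted.
* **Fold changes** are computed from differences of group mean log2 values
  and reported with the signed convention (−1/r below 1), matching the
  negative-FC reporting style; the transform is antisymmetric under pair
  reversal.
* Cell-population testing reuses the identical machinery on the score
  matrix rows.

## Enrichment and coverage

Enrichment tests one 2×2 table per category — (in category / out) ×
(significant / not) — against the universe of endogenous panel genes. A
targeted assay's denominators are panel-relative, so the universe is never
the genome. Depletion is reported through the same two-sided p with
direction from the odds ratio. Categories are user-supplied GMT data; a
small illustrative catalog (including a cytotoxicity category) is packaged
for tests and demos. Pathway coverage is pure set accounting (annotated ∩
panel, DE among covered, percentages rounded to integers); pathway gene
lists are user-provided files — there is no KEGG client and no figure
rendering of pathway maps.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 98 samples in
four groups (19/13/40/26), 770 endogenous genes (the ~59 marker genes keep
their real symbols; the rest are synthetic ids), 20 housekeeping, 8 negative
and 6 positive controls. Generative model:

* per sample, a latent hot/cold state ~ Bernoulli(group hot fraction);
  defaults use hot fractions 6/19, 3/13, 16/40, 17/26 so the wild-type group
  is predominantly hot and the mutated groups predominantly cold;
* per population, latent log2 abundance ~ Normal(state mean, 1.0) with hot
  and cold means 2.0 and 0.0 — a 2-SD separation, giving a clearly bimodal
  infiltration structure;
* marker-gene log2 mean = gene baseline + 1.0 × its population's latent
  abundance (unit slope keeps score scale = latent scale, making recovery
  tests interpretable); non-marker genes are baseline plus planted effects;
* planted effects are additive log2 shifts applied to one group's samples,
  so the contrast's expected difference of group means equals the planted
  size exactly;
* counts ~ negative binomial, var = m + φm² with dispersion φ = 0.1 —
  integer counts with the overdispersion typical of panel data; with
  baseline means 2^5–2^10 this yields a within-group SD of ≈0.5 on the log2
  scale; per-sample library factors are log-normal (SD 0.3 log2);
* housekeeping genes see only the library factor; negative controls are
  Poisson(2); positive controls are a fixed ladder (8192…8 expected counts)
  scaled by the library factor.

One master seed drives everything; per-stage substreams are spawned from it
in a fixed order, so identical configs reproduce byte-identical files. The
matched null (`simulate_null`) removes planted effects and equalizes the hot
fraction across groups at the size-weighted mean, making group labels
exchangeable.

What the generator does **not** emulate: the real panel's gene list and
per-gene abundance spectrum, batch/lane effects, gene–gene correlation
beyond the shared infiltration latents, or dropout/saturation artifacts.
Passing recovery tests therefore demonstrates correctness of the pipeline's
computations under a faithful statistical caricature, not performance on any
real cohort.

## Problem sizes used in validation

The validation suite measures: type-I error of the omnibus test over 130
null cohorts (100,100 gene-replicates), empirical FDR over 200 cohorts with
10% non-null genes (planted |log2 effect| 1.322), detection and fold-change
recovery for a planted FC of −2.5 between the n = 13 and n = 26 groups over
30 replicates, score/latent Spearman correlation on a 98-sample cohort, and
hot/cold recovery over 10 cohorts. These sizes give stable estimates
(e.g. ±0.002 on the rejection rate) while keeping the full suite fast.

## Known limitations

* The r×c exact test enumerates tables; heavily unbalanced tables beyond the
  bound use the seeded Monte-Carlo path, whose resolution is limited by the
  draw count (p ≥ 1/(n+1)).
* Wilcoxon p-values under heavy ties rely on the normal approximation.
* Hot/cold labels are a hard dichotomy; cohorts with a continuum of
  infiltration will be split at an essentially arbitrary boundary.
* No covariate adjustment and no parametric (limma-style) alternatives —
  the workflow is deliberately rank-based.
* No sample-level QC (RNA integrity screening happens upstream of counts).
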