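# immunopanel

Targeted immune gene-expression analysis of driver-defined lung
adenocarcinoma subgroups.

Tumors driven by *EGFR* or *ERBB2* exon 20 insertions respond poorly to both
kinase inhibitors and immune checkpoint blockade, and their tumor
microenvironment (TME) is not well characterized. This package reimplements,
as a tested and reusable pipeline, the analysis workflow used to profile such
cohorts with targeted immuno-oncology expression panels (NanoString
nCounter-style counts, ~770 immune genes):

1. **Normalization** — positive-control scaling, negative-control background
   flooring (mean + 2·SD), housekeeping geometric-mean scaling, log2(x+1).
2. **Immune-cell scores** — for each of 14 populations (B cells, CD45+,
   CD56dim NK, CD8+ T, cytotoxic cells, dendritic cells, exhausted CD8+ T,
   macrophages, mast cells, neutrophils, NK, T cells, Th1, Treg), the score
   is the mean log2 expression of its marker genes (Danaher-style relative
   abundance), plus **total TILs** (mean of population scores) and
   **cytolytic activity** = (log2 GZMA + log2 PRF1)/2.
3. **Hot/cold classification** — hierarchical clustering of samples on the
   score matrix, cut at k = 2; the cluster with higher mean total TILs is
   "hot". Cluster-versus-genotype association uses a two-sided Fisher exact
   test (full r×c enumeration, seeded Monte-Carlo fallback).
4. **Differential expression** — per gene, Kruskal–Wallis omnibus across the
   four driver groups, Wilcoxon rank-sum post-hoc contrasts versus wild type,
   Benjamini–Hochberg FDR at 5%, signed fold changes
   (FC = 2^Δ if Δ ≥ 0 else −2^(−Δ), Δ = difference of group mean log2), and
   the 7-cell Venn partition of up-/down-regulated genes.
5. **Enrichment & coverage** — Fisher-exact over-representation of
   significant genes in annotation categories (universe = panel genes) and
   pathway-coverage accounting against user-supplied gene lists (GMT).

Because raw data of such studies are typically not deposited, the package
ships a **synthetic cohort generator** that emulates the study design — 98
samples in groups of 19/13/40/26, a bimodal hot/cold infiltration state
driving correlated marker-gene expression, negative-binomial counts, and
planted group-specific effects — with the full ground truth emitted for
validation.

## Worked example

```bash
immunopanel run-all --out results/demo --seed 7
```

runs simulate → normalize → score → cluster → de → enrich on a default
synthetic cohort and prints a run summary; the same stages are available as
individual subcommands (`immunopanel simulate|normalize|score|cluster|de|enrich|coverage`)
and as library functions. The numbered drivers under `analysis/` tell the
story step by step:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_normalize_and_score.py
python analysis/03_cluster_hot_cold.py
...
```

Output of `03_cluster_hot_cold.py` on the demo cohort (seed 7):

```
k=2 clustering: 37 hot / 61 cold; agreement with planted truth 100.0%
hot/cold x 4 groups Fisher p = 0.0107 (exact)
  EGFR-Ex18/19/21mut vs EGFR/ERBB2wt: p = 0.0059
  EGFR-Ex20mut vs EGFR/ERBB2wt: p = 0.0187
  ERBB2-Ex20mut vs EGFR/ERBB2wt: p = 0.0156
worked-example table [[10,3],[9,17]]: p = 0.0187 (expect 0.0187)
```

The first lines classify the simulated tumors into immunologically hot
(infiltrated) and cold (depleted) groups and test whether that split is
associated with the driver genotype. The last line re-tests the published
cold/hot × (EGFR-Ex20mut, EGFR/ERBB2wt) contingency table — 10/13 of the
EGFR-Ex20mut tumors cold versus 9/26 of the wild-type tumors — for which the
two-sided Fisher exact p is 0.0187, the reported P = 0.018.

`04_differential_expression.py` then reports the omnibus-significant gene
count, per-comparison Venn cells, and the 3×3 bi-clustering of the
significant-gene submatrix (which on the demo cohort recovers the three
mutated groups exactly as sample clusters S1–S3).

All TSV outputs have fixed column orders: counts/normalized matrices are
gene-rows × sample-columns with a `gene_id` header column; DE tables carry
`mean:<group>`, `H`, `p_omnibus`, `q_omnibus`, `sig_omnibus`, then
`p:/q:/fc:/sig:<A> vs <B>` per contrast; Venn tables are
(cell, n, genes); every CLI run can write a JSON summary.

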