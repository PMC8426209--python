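#!/usr/bin/env python
"""Differential expression across the four driver groups.

Kruskal-Wallis omnibus per gene (and per immune-cell score), BH-FDR at 5%,
Wilcoxon post-hoc contrasts of each mutated group against EGFR/ERBB2wt with
signed fold changes, and the 7-cell Venn partition of up-/down-regulated
genes across the three comparisons. The omnibus-significant gene submatrix
is bi-clustered into S1-S3 sample and G1-G3 gene clusters.

Reads results/normalized.tsv + cell_scores.tsv, writes results/de.tsv,
de_cell_scores.tsv, venn_up.tsv, venn_down.tsv, biclusters.tsv.
"""

from pathlib import Path

import pandas as pd

from immunopanel import panel_io
from immunopanel.cluster import bicluster
from immunopanel.diffexp import de_analysis, significant_sets, venn_partition
from immunopanel.synthetic import GROUP_WT

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    norm = pd.read_csv(ROOT / "normalized.tsv", sep="\t", index_col=0)
    scores = pd.read_csv(ROOT / "cell_scores.tsv", sep="\t", index_col=0)
    samples = panel_io.read_samples(ROOT / "cohort/samples.tsv")

    de = de_analysis(norm, samples, reference=GROUP_WT, fdr=0.05)
    de.to_csv(ROOT / "de.tsv", sep="\t")
    n_sig = int(de["sig_omnibus"].sum())
    print(f"omnibus: {n_sig} of {len(de)} genes significant at FDR 5%")

    de_sc = de_analysis(scores, samples, reference=GROUP_WT, fdr=0.05)
    de_sc.to_csv(ROOT / "de_cell_scores.tsv", sep="\t")
    sig_pops = de_sc.index[de_sc["sig_omnibus"]].tolist()
    print(f"cell scores: {len(sig_pops)} of {len(de_sc)} rows omnibus-significant "
          f"({', '.join(sig_pops) if sig_pops else 'none'})")

    pairs = [(g, GROUP_WT) for g in dict.fromkeys(samples["group"]) if g != GROUP_WT]
    for direction in ("up", "down"):
        sets = [significant_sets(de, p, direction) for p in pairs]
        cells = venn_partition(*sets, names=tuple(a for a, _ in pairs))
        rows = [("+".join(k), len(v), ",".join(sorted(v))) for k, v in cells.items()]
        pd.DataFrame(rows, columns=["cell", "n", "genes"]).to_csv(
            ROOT / f"venn_{direction}.tsv", sep="\t", index=False)
        sizes = {"+".join(k): len(v) for k, v in cells.items() if v}
        print(f"venn ({direction}-regulated vs {GROUP_WT}): {sizes or 'empty'}")

    sig_genes = de.index[de["sig_omnibus"]]
    if len(sig_genes) >= 6:
        mutated = samples.index[samples["group"] != GROUP_WT]
        s_labels, g_labels = bicluster(norm.loc[sig_genes, mutated])
        pd.DataFrame({"sample_cluster": s_labels}).rename_axis("sample_id").to_csv(
            ROOT / "biclusters.tsv", sep="\t")
        print("bi-clustering of significant genes (mutated samples): "
              f"{s_labels.value_counts().to_dict()}")
    else:
        print("too few omnibus-significant genes for bi-clustering")


if __name__ == "__main__":
    main()
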