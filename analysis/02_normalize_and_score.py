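#!/usr/bin/env python
"""Normalize the cohort and compute immune-cell scores.

Positive-control scaling -> negative-control background flooring ->
housekeeping geometric-mean scaling -> log2(x+1), then Danaher-style
marker-mean scores for the 14 immune populations plus total TILs and
cytolytic activity (mean of log2 GZMA and PRF1).

Reads results/cohort/, writes results/normalized.tsv and results/cell_scores.tsv.
"""

from pathlib import Path

from immunopanel import panel_io
from immunopanel.normalization import normalize
from immunopanel.scores import TOTAL_TILS, load_marker_catalog, score_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts, probes = panel_io.read_counts(ROOT / "cohort/counts.tsv",
                                          ROOT / "cohort/probes.tsv")
    norm = normalize(counts, probes)
    norm.rename_axis("gene_id").to_csv(ROOT / "normalized.tsv", sep="\t")
    catalog = load_marker_catalog()
    scores = score_matrix(norm, catalog)
    scores.to_csv(ROOT / "cell_scores.tsv", sep="\t")
    print(f"normalized {norm.shape[0]} endogenous genes x {norm.shape[1]} samples")
    print(f"scored {len(catalog)} populations + total TILs + cytolytic activity")
    til = scores.loc[TOTAL_TILS]
    print(f"total TILs: median {til.median():.2f}, range {til.min():.2f}-{til.max():.2f} (log2)")


if __name__ == "__main__":
    main()
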