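#!/usr/bin/env python
"""Gene-set enrichment of differential genes and pathway coverage.

Fisher-exact over-representation of each comparison's significant genes in
the packaged annotation categories (universe = the endogenous panel genes),
then a coverage report for a pathway gene list: how much of it the targeted
panel covers and how many covered genes are differentially expressed.
The demonstration pathway list here is synthetic (a stand-in built from the
packaged categories plus off-panel filler symbols); real analyses supply
their own GMT, e.g. KEGG-derived lists.

Reads results/de.tsv, writes results/enrichment.tsv and results/coverage.tsv.
"""

from pathlib import Path

import pandas as pd

from immunopanel import panel_io
from immunopanel.enrichment import enrich, pathway_coverage
from immunopanel.diffexp import significant_sets
from immunopanel.synthetic import GROUP_WT

ROOT = Path(__file__).resolve().parent.parent / "results"
GMT = Path(__file__).resolve().parent.parent / "src/immunopanel/resources/genesets.gmt"


def main() -> None:
    de = pd.read_csv(ROOT / "de.tsv", sep="\t", index_col=0)
    samples = panel_io.read_samples(ROOT / "cohort/samples.tsv")
    catalog = panel_io.read_gmt(GMT)
    universe = set(de.index)

    pairs = [(g, GROUP_WT) for g in dict.fromkeys(samples["group"]) if g != GROUP_WT]
    frames = []
    for a, b in pairs:
        sig = significant_sets(de, (a, b), "up") | significant_sets(de, (a, b), "down")
        res = enrich(sig, universe, catalog)
        res.insert(0, "comparison", f"{a} vs {b}")
        frames.append(res)
        top = res.sort_values("p").head(1)
        if len(top) and len(sig):
            cat = top.index[0]
            print(f"{a} vs {b}: {len(sig)} significant genes; most extreme category "
                  f"{cat!r} (p={top['p'].iloc[0]:.3g}, {top['direction'].iloc[0]})")
        else:
            print(f"{a} vs {b}: {len(sig)} significant genes")
    pd.concat(frames).to_csv(ROOT / "enrichment.tsv", sep="\t")

    # synthetic stand-in pathway: every cytokine/cytotoxicity category member
    # plus off-panel filler symbols, to exercise the coverage accounting
    pathway = set().union(*(set(catalog[c]) for c in
                            ("cytotoxicity", "cytokine_receptor_interaction")))
    pathway |= {f"OFFPANEL_{i}" for i in range(40)}
    de_sets = {f"{a} vs {b}": significant_sets(de, (a, b), "up")
               | significant_sets(de, (a, b), "down") for a, b in pairs}
    rep = pathway_coverage(pathway, universe, de_sets, name="synthetic_immune_pathway")
    rep.to_frame().to_csv(ROOT / "coverage.tsv", sep="\t")
    print(f"pathway coverage: {rep.n_covered}/{rep.n_annotated} genes "
          f"({rep.coverage_percent}%) on panel; {rep.n_de_total} of those DE")


if __name__ == "__main__":
    main()
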