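"""Fisher-exact over-representation and pathway-coverage accounting.

Enrichment is tested per annotation category with a two-sided Fisher exact
test on the 2x2 table (in category / out of category) x (significant / not),
against a universe of the endogenous panel genes — the assay is targeted, so
denominators are panel-relative, not genome-wide. Direction (enriched or
depleted) comes from the odds ratio; BH adjustment runs across categories.
The exact-test core is shared with the clustering module's association test.

Pathway coverage reports, for an externally supplied pathway gene list, how
many genes the panel covers and how many of those are differentially
expressed per comparison, with percentages rounded to the nearest integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import association_test
from .diffexp import bh_adjust
from .panel_io import GeneSetCatalog

log = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    """Invalid enrichment request."""


def enrich(
    sig: set,
    universe: set,
    catalog: GeneSetCatalog | Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-category over-representation of ``sig`` within ``universe``.

    Returns a DataFrame indexed by category with the 2x2 cells
    (``n_set_sig``, ``n_set_notsig``, ``n_out_sig``, ``n_out_notsig``),
    ``odds_ratio``, two-sided ``p``, BH ``q`` and ``direction``. Categories
    with no member in the universe are skipped with a warning.
    """
    sig, universe = set(sig), set(universe)
    offenders = sig - universe
    if offenders:
        raise EnrichmentError(
            "significant genes outside the universe: " + ", ".join(sorted(offenders)[:20])
        )
    items = catalog.items() if hasattr(catalog, "items") else catalog
    rows = []
    for name, members in items:
        in_set = set(members) & universe
        if not in_set:
            log.warning("category %r has no member in the universe; skipped", name)
            continue
        a = len(in_set & sig)               # in set & significant
        b = len(in_set) - a                 # in set & not
        c = len(sig) - a                    # out of set & significant
        d = len(universe) - len(in_set) - c
        p = association_test([[a, b], [c, d]]).pvalue
        odds = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else np.nan)
        direction = "enriched" if (np.isnan(odds) or odds >= 1) else "depleted"
        rows.append((name, a, b, c, d, odds, p, direction))
    if not rows:
        return pd.DataFrame(
            columns=["n_set_sig", "n_set_notsig", "n_out_sig", "n_out_notsig",
                     "odds_ratio", "p", "q", "direction"]
        )
    out = pd.DataFrame(
        rows,
        columns=["category", "n_set_sig", "n_set_notsig", "n_out_sig",
                 "n_out_notsig", "odds_ratio", "p", "direction"],
    ).set_index("category")
    out.insert(6, "q", bh_adjust(out["p"]))
    return out


@dataclass
class CoverageReport:
    """Panel coverage of one externally annotated pathway."""

    pathway: str
    n_annotated: int
    n_covered: int
    de_counts: dict[str, int] = field(default_factory=dict)
    _de_sets: dict = field(default_factory=dict, repr=False)

    @property
    def coverage_fraction(self) -> float:
        return self.n_covered / self.n_annotated if self.n_annotated else 0.0

    @property
    def coverage_percent(self) -> int:
        """Coverage as a whole percent (matching the reporting convention)."""
        return round(100 * self.coverage_fraction)

    @property
    def n_de_total(self) -> int:
        """Number of covered genes differentially expressed in any comparison."""
        return len(set().union(*self._de_sets.values())) if self._de_sets else 0

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "pathway": self.pathway,
            "n_annotated": self.n_annotated,
            "n_covered": self.n_covered,
            "coverage_percent": self.coverage_percent,
            "n_de_any": self.n_de_total,
        }
        for comp, n in self.de_counts.items():
            rows[f"n_de:{comp}"] = n
        return pd.DataFrame([rows]).set_index("pathway")


def pathway_coverage(
    pathway_genes: set,
    panel_genes: set,
    de_sets: Mapping[str, set] | None = None,
    name: str = "pathway",
) -> CoverageReport:
    """Coverage of a pathway gene list by the panel, plus DE counts per comparison."""
    pathway_genes, panel_genes = set(pathway_genes), set(panel_genes)
    covered = pathway_genes & panel_genes
    de_sets = de_sets or {}
    de_in_pathway = {comp: set(genes) & covered for comp, genes in de_sets.items()}
    report = CoverageReport(
        pathway=name,
        n_annotated=len(pathway_genes),
        n_covered=len(covered),
        de_counts={comp: len(g) for comp, g in de_in_pathway.items()},
        _de_sets=de_in_pathway,
    )
    return report
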