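"""Immune-cell population scores from normalized expression.

A population's score in a sample is the arithmetic mean of its marker genes'
log2 normalized expression — a geometric mean on the linear scale, the
Danaher-style relative abundance. The packaged catalog covers the 14
populations scored by the pipeline (B cells, CD45+ cells, CD56dim NK cells,
CD8+ T cells, cytotoxic cells, dendritic cells, exhausted CD8+ T cells,
macrophages, mast cells, neutrophils, NK cells, T cells, Th1 cells and Treg
cells); it is data, not code, and can be overridden per run.

Two composite scores are derived:

* total TILs — mean of a configurable subset of population scores
  (default: all 14);
* cytolytic activity — mean of log2 GZMA and PRF1, the granzyme/perforin
  killing-capacity proxy (definitionally ``cell_score`` on {GZMA, PRF1}).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

TOTAL_TILS = "total_TILs"
CYTOLYTIC_ACTIVITY = "cytolytic_activity"


class ScoreError(ValueError):
    """Markers unavailable or malformed marker catalog."""


def load_marker_catalog(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load a population -> marker list catalog (packaged default if no path)."""
    if path is None:
        text = (resources.files("immunopanel") / "resources" / "markers.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    populations = data.get("populations", data) if isinstance(data, dict) else None
    if not isinstance(populations, dict) or not populations:
        raise ScoreError("marker catalog must map population names to marker lists")
    catalog: dict[str, list[str]] = {}
    for pop, markers in populations.items():
        if not markers:
            raise ScoreError(f"population {pop!r} has an empty marker list")
        if len(set(markers)) != len(markers):
            raise ScoreError(f"population {pop!r} lists duplicate markers")
        catalog[str(pop)] = [str(m) for m in markers]
    return catalog


def cell_score(
    norm: pd.DataFrame, markers: Sequence[str], population: str = "?"
) -> pd.Series:
    """Mean log2 expression of the markers found in ``norm`` (per sample).

    Markers absent from the matrix are dropped with a warning listing them;
    zero present markers is a hard error naming the population.
    """
    present = [m for m in markers if m in norm.index]
    absent = [m for m in markers if m not in norm.index]
    if not present:
        raise ScoreError(
            f"no markers of population {population!r} present in the matrix "
            f"(wanted: {', '.join(markers)})"
        )
    if absent:
        log.warning(
            "population %r: marker(s) absent from matrix, dropped: %s",
            population, ", ".join(absent),
        )
    return norm.loc[present].mean(axis=0)


def score_matrix(
    norm: pd.DataFrame, catalog: Mapping[str, Sequence[str]] | None = None
) -> pd.DataFrame:
    """Population scores + total TILs + cytolytic activity, rows x samples."""
    catalog = catalog if catalog is not None else load_marker_catalog()
    rows = {pop: cell_score(norm, markers, pop) for pop, markers in catalog.items()}
    scores = pd.DataFrame(rows).T
    scores.loc[TOTAL_TILS] = total_til_score(scores.loc[list(catalog)])
    scores.loc[CYTOLYTIC_ACTIVITY] = cytolytic_activity(norm)
    scores.index.name = "population"
    return scores


def total_til_score(
    scores: pd.DataFrame, populations: Sequence[str] | None = None
) -> pd.Series:
    """Mean of a subset of population scores per sample (default: all rows)."""
    if populations is None:
        subset = scores
    else:
        if len(populations) == 0:
            raise ScoreError("total TILs requires a non-empty population subset")
        missing = [p for p in populations if p not in scores.index]
        if missing:
            raise ScoreError(f"total TILs subset not in score matrix: {missing}")
        subset = scores.loc[list(populations)]
    if subset.shape[0] == 0:
        raise ScoreError("total TILs requires a non-empty population subset")
    return subset.mean(axis=0)


def cytolytic_activity(norm: pd.DataFrame) -> pd.Series:
    """(log2 GZMA + log2 PRF1) / 2 per sample; both genes must be present."""
    missing = [g for g in ("GZMA", "PRF1") if g not in norm.index]
    if missing:
        raise ScoreError(f"cytolytic activity requires GZMA and PRF1; missing: {missing}")
    return cell_score(norm, ["GZMA", "PRF1"], CYTOLYTIC_ACTIVITY)
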