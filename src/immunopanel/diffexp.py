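"""Nonparametric differential expression across driver groups.

Per feature (gene or immune-cell score) the four groups are compared with a
Kruskal-Wallis omnibus test; pairwise contrasts use the two-sided Wilcoxon
rank-sum test (exact when the combined n is small and tie-free, normal
approximation with continuity correction otherwise). Benjamini-Hochberg
adjustment is applied across features, separately for the omnibus family and
for each pairwise family; pairwise testing is gated on omnibus significance
by default (configurable).

Fold changes are computed from the difference of group mean log2 values and
reported on the linear scale with the signed convention: ``2**d`` when
``d >= 0`` and ``-2**(-d)`` otherwise, so FC = -2.5 means 2.5-fold lower in
the first group.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

EXACT_MAX_N = 25  # combined-n threshold for the exact rank-sum distribution


class DiffExpError(ValueError):
    """Invalid testing request."""


def _group_values(values: pd.Series, groups: pd.Series) -> dict[str, np.ndarray]:
    common = values.index.intersection(groups.index)
    out: dict[str, np.ndarray] = {}
    for g, idx in groups.loc[common].groupby(groups.loc[common]).groups.items():
        out[g] = values.loc[idx].to_numpy(dtype=float)
    return out


def _check_group_sizes(split: Mapping[str, np.ndarray]) -> None:
    small = [g for g, v in split.items() if len(v) < 2]
    if small:
        raise DiffExpError(f"group(s) with fewer than 2 samples: {small}")
    if len(split) < 2:
        raise DiffExpError("need at least 2 groups")


def kruskal_omnibus(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-squared p-value."""
    split = _group_values(values, groups)
    _check_group_sizes(split)
    arrays = list(split.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def kruskal_matrix(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Vectorized per-row Kruskal-Wallis over a features x samples matrix.

    Same statistic as :func:`kruskal_omnibus` (rank formula with tie
    correction, chi-squared reference with k-1 df) computed for all rows at
    once; used for large calibration runs.
    """
    cols = values.columns.intersection(groups.index)
    groups = groups.loc[cols]
    sizes = groups.value_counts()
    if (sizes < 2).any() or len(sizes) < 2:
        raise DiffExpError("each group needs >= 2 samples and >= 2 groups")
    x = values[cols].to_numpy(dtype=float)
    n = x.shape[1]
    ranks = stats.rankdata(x, axis=1)
    h = np.zeros(x.shape[0])
    for g in sizes.index:
        mask = (groups == g).to_numpy()
        r_g = ranks[:, mask].sum(axis=1)
        h += r_g**2 / mask.sum()
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction: 1 - sum(t^3 - t) / (n^3 - n) per row
    sorted_r = np.sort(ranks, axis=1)
    ties = np.zeros(x.shape[0])
    for i in range(x.shape[0]):
        _, counts = np.unique(sorted_r[i], return_counts=True)
        ties[i] = (counts**3 - counts).sum()
    correction = 1.0 - ties / (n**3 - n)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(correction > 0, h / correction, 0.0)
    df = len(sizes) - 1
    p = stats.chi2.sf(h, df)
    p = np.where(correction > 0, p, 1.0)
    return pd.DataFrame({"H": h, "p": p}, index=values.index)


def pairwise_wilcoxon(
    values: pd.Series,
    groups: pd.Series,
    pairs: Sequence[tuple[str, str]],
) -> dict[tuple[str, str], float]:
    """Two-sided rank-sum p per group pair.

    Exact null distribution when the combined n <= 25 with no ties, normal
    approximation with continuity and tie correction otherwise.
    """
    split = _group_values(values, groups)
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        for g in (a, b):
            if g not in split or len(split[g]) < 2:
                raise DiffExpError(f"group {g!r} missing or has fewer than 2 samples")
        x, y = split[a], split[b]
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            out[(a, b)] = 1.0
            continue
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= EXACT_MAX_N and not has_ties) else "asymptotic"
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        out[(a, b)] = float(p)
    return out


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return arr
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise DiffExpError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def signed_fold_change(mean_a: float, mean_b: float):
    """Linear-scale fold change with sign convention (negative = lower in A)."""
    d = np.asarray(mean_a, dtype=float) - np.asarray(mean_b, dtype=float)
    r = 2.0**d
    out = np.where(r >= 1.0, r, -1.0 / r)
    return float(out) if out.ndim == 0 else out


def venn_partition(
    sig_a: set, sig_b: set, sig_c: set, names: tuple[str, str, str] = ("A", "B", "C")
) -> dict[tuple[str, ...], set]:
    """Disjoint 7-cell decomposition of three significant-gene sets.

    Keys are sorted tuples of the comparison names a gene belongs to; the
    union of the 7 cells equals the union of the inputs.
    """
    sets = dict(zip(names, (set(sig_a), set(sig_b), set(sig_c))))
    cells: dict[tuple[str, ...], set] = {}
    for r in (1, 2, 3):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            cells[combo] = inside - outside
    return cells


def de_analysis(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    reference: str | None = None,
    fdr: float = 0.05,
    pairs: Sequence[tuple[str, str]] | None = None,
    gate_on_omnibus: bool = True,
) -> pd.DataFrame:
    """Full per-feature differential-expression table.

    Columns: per-group means; omnibus ``H``, ``p_omnibus``, ``q_omnibus``,
    ``sig_omnibus``; per pair ``p:A vs B``, ``q:A vs B``, ``fc:A vs B``,
    ``sig:A vs B``. Pairwise q-values are BH-adjusted across the features
    tested within that pair's family (omnibus-significant features when
    ``gate_on_omnibus``).
    """
    if not 0 < fdr < 1:
        raise DiffExpError(f"FDR must be in (0, 1), got {fdr}")
    groups = samples["group"]
    group_names = list(dict.fromkeys(groups.loc[norm.columns.intersection(groups.index)]))
    if reference is not None and reference not in group_names:
        raise DiffExpError(f"reference group {reference!r} not among groups {group_names}")
    if pairs is None:
        if reference is not None:
            pairs = [(g, reference) for g in group_names if g != reference]
        else:
            pairs = list(itertools.combinations(group_names, 2))

    omni = kruskal_matrix(norm, groups)
    res = pd.DataFrame(index=norm.index)
    cols = norm.columns.intersection(groups.index)
    for g in group_names:
        res[f"mean:{g}"] = norm[cols].loc[:, groups.loc[cols] == g].mean(axis=1)
    res["H"] = omni["H"]
    res["p_omnibus"] = omni["p"]
    res["q_omnibus"] = bh_adjust(omni["p"])
    res["sig_omnibus"] = res["q_omnibus"] <= fdr

    family = res.index[res["sig_omnibus"]] if gate_on_omnibus else res.index
    for a, b in pairs:
        pcol, qcol, fcol, scol = (f"{k}:{a} vs {b}" for k in ("p", "q", "fc", "sig"))
        res[fcol] = signed_fold_change(res[f"mean:{a}"], res[f"mean:{b}"])
        res[pcol] = np.nan
        res[qcol] = np.nan
        res[scol] = False
        if len(family) == 0:
            continue
        pvals = [
            pairwise_wilcoxon(norm.loc[feat], groups, [(a, b)])[(a, b)] for feat in family
        ]
        res.loc[family, pcol] = pvals
        res.loc[family, qcol] = bh_adjust(pvals)
        res.loc[family, scol] = res.loc[family, qcol] <= fdr
    res.index.name = norm.index.name or "feature"
    return res


def significant_sets(
    de_table: pd.DataFrame, pair: tuple[str, str], direction: str = "up"
) -> set:
    """Features significant for a pair, split by fold-change direction."""
    a, b = pair
    scol, fcol = f"sig:{a} vs {b}", f"fc:{a} vs {b}"
    if scol not in de_table.columns:
        raise DiffExpError(f"pair {pair} not present in the DE table")
    sig = de_table.index[de_table[scol].fillna(False).astype(bool)]
    if direction == "up":
        return set(sig[de_table.loc[sig, fcol] > 0])
    if direction == "down":
        return set(sig[de_table.loc[sig, fcol] < 0])
    raise DiffExpError(f"direction must be 'up' or 'down', got {direction!r}")
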