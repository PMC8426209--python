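"""Hierarchical clustering, hot/cold labeling and exact association tests.

Samples are clustered on the immune-cell score matrix (Euclidean distance on
row-centered values, average linkage by default) and the two-cluster cut is
labeled hot/cold by mean total-TIL score. Cluster-versus-genotype association
uses a two-sided Fisher exact test: for an r x c table the p-value is the
total null probability (multivariate hypergeometric, margins fixed) of all
tables no more probable than the observed one, computed by full enumeration
when feasible and by a seeded Monte-Carlo sample of the null otherwise.
The same exact core backs the enrichment module.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.special import gammaln

log = logging.getLogger(__name__)

HOT = "hot"
COLD = "cold"


class ClusterError(ValueError):
    """Invalid clustering request."""


# ---------------------------------------------------------------------------
# matrix helpers and agglomerative clustering
# ---------------------------------------------------------------------------

def center_rows(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Subtract each row's mean (the heatmap convention: above-mean vs below)."""
    if isinstance(matrix, pd.DataFrame):
        if matrix.size == 0:
            raise ClusterError("center_rows of an empty matrix")
        return matrix.sub(matrix.mean(axis=1), axis=0)
    arr = np.asarray(matrix, dtype=float)
    if arr.size == 0:
        raise ClusterError("center_rows of an empty matrix")
    return arr - arr.mean(axis=1, keepdims=True)


@dataclass
class ClusterAssignment:
    """A flat k-cluster cut of an agglomerative tree."""

    labels: pd.Series                 # item id -> cluster label (1..k)
    linkage_matrix: np.ndarray        # scipy merge list with heights
    method: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return int(self.labels.nunique())

    def members(self, label) -> list:
        return list(self.labels.index[self.labels == label])


def hcluster(
    matrix: pd.DataFrame,
    axis: Literal["rows", "columns"] = "columns",
    distance: str = "euclidean",
    linkage: str = "average",
    k: int = 2,
) -> ClusterAssignment:
    """Agglomerative clustering of rows or columns, cut into exactly k clusters.

    Deterministic given inputs (scipy breaks ties by input order).
    """
    data = matrix.T if axis == "columns" else matrix
    items = data.index
    n = len(items)
    if not 1 <= k <= n:
        raise ClusterError(f"k={k} out of range for {n} items")
    values = data.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ClusterError("matrix contains non-finite values")
    if n == 1:
        Z = np.empty((0, 4))
        flat = np.array([1])
    else:
        Z = hierarchy.linkage(pdist(values, metric=distance), method=linkage)
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(flat)) != k:
            # maxclust can undershoot with exactly tied heights; fall back to
            # cutting at an explicit merge height
            heights = np.sort(Z[:, 2])
            t = heights[n - k - 1] if n - k - 1 >= 0 else -1.0
            flat = hierarchy.fcluster(Z, t=t, criterion="distance")
    labels = pd.Series(flat, index=items, name="cluster")
    return ClusterAssignment(
        labels=labels,
        linkage_matrix=Z,
        method={"axis": axis, "distance": distance, "linkage": linkage, "k": k},
    )


def label_hot_cold(assign: ClusterAssignment, total_til: pd.Series) -> pd.Series:
    """Map a k=2 assignment to hot/cold by mean total-TIL score.

    The cluster with the higher mean is hot. An exact tie labels the larger
    cluster cold (arbitrary, warned); a further size tie labels the cluster
    containing the first sample cold.
    """
    if assign.k != 2:
        raise ClusterError(f"hot/cold labeling needs exactly 2 clusters, got {assign.k}")
    labels = assign.labels
    means = total_til.loc[labels.index].groupby(labels).mean()
    a, b = means.index[0], means.index[1]
    if means[a] == means[b]:
        log.warning("hot/cold tie in mean total TILs; labeling larger cluster cold")
        sizes = labels.value_counts()
        if sizes[a] != sizes[b]:
            cold = sizes.idxmax()
        else:
            cold = labels.iloc[0]
        hot = b if cold == a else a
    else:
        hot = means.idxmax()
    return labels.map(lambda c: HOT if c == hot else COLD).rename("state")


def contingency_table(rows: pd.Series, cols: pd.Series) -> pd.DataFrame:
    """Cross-tabulate two per-sample label series over their shared index."""
    common = rows.index.intersection(cols.index)
    return pd.crosstab(rows.loc[common], cols.loc[common])


# ---------------------------------------------------------------------------
# exact association test (shared with the enrichment module)
# ---------------------------------------------------------------------------

class FisherResult(NamedTuple):
    pvalue: float
    method: str          # "exact" or "monte_carlo(seed=..., n=...)"

    def __float__(self) -> float:  # convenience: float(result) == p
        return self.pvalue


_REL_TOL = 1e-7  # tables within this relative log-probability count as "as extreme"


def _table_logprob(table: np.ndarray, row_margins: np.ndarray, col_margins: np.ndarray) -> float:
    n = row_margins.sum()
    return float(
        gammaln(row_margins + 1).sum()
        + gammaln(col_margins + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_margins: np.ndarray, col_margins: np.ndarray, max_tables: int):
    """Yield every nonnegative integer table with the given margins.

    Raises ``OverflowError`` after ``max_tables`` tables (caller falls back to
    Monte Carlo)."""
    r, c = len(row_margins), len(col_margins)
    count = 0
    table = np.zeros((r, c), dtype=np.int64)

    def fill_row(i: int, remaining_cols: np.ndarray):
        nonlocal count
        if i == r - 1:
            if np.all(remaining_cols >= 0):
                table[i, :] = remaining_cols
                count += 1
                if count > max_tables:
                    raise OverflowError
                yield table
            return
        target = row_margins[i]

        def fill_cell(j: int, left: int):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    table[i, j] = left
                    yield from fill_row(i + 1, remaining_cols - table[i, :])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                table[i, j] = v
                yield from fill_cell(j + 1, left - v)

        yield from fill_cell(0, target)

    yield from fill_row(0, col_margins.copy())


def association_test(
    table,
    max_tables: int = 2_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> FisherResult:
    """Two-sided Fisher exact test on an r x c contingency table.

    Degenerate margins (an all-zero row or column) return p = 1 with a
    warning. When exact enumeration would exceed ``max_tables`` tables the
    p-value is estimated from ``n_mc`` Monte-Carlo draws of the null
    (add-one estimator) with the given seed, flagged in ``method``.
    """
    arr = np.asarray(pd.DataFrame(table).to_numpy() if isinstance(table, pd.DataFrame) else table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ClusterError(f"association test needs an r x c table with r,c >= 2; got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.number):
        raise ClusterError("contingency table entries must be numeric")
    if np.any(arr < 0) or not np.allclose(arr, np.round(np.asarray(arr, dtype=float))):
        raise ClusterError("contingency table entries must be nonnegative integers")
    arr = np.asarray(np.round(np.asarray(arr, dtype=float)), dtype=np.int64)
    row_m, col_m = arr.sum(axis=1), arr.sum(axis=0)
    if np.any(row_m == 0) or np.any(col_m == 0):
        log.warning("degenerate margins (zero row/column); association p = 1.0")
        return FisherResult(1.0, "exact")
    obs_lp = _table_logprob(arr, row_m, col_m)
    cutoff = obs_lp + _REL_TOL * abs(obs_lp) + 1e-12
    try:
        total = 0.0
        for t in _enumerate_tables(row_m, col_m, max_tables):
            lp = _table_logprob(t, row_m, col_m)
            if lp <= cutoff:
                total += np.exp(lp)
        return FisherResult(min(float(total), 1.0), "exact")
    except OverflowError:
        pass
    # Monte Carlo: permute column labels against row labels, tabulate, compare
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(len(row_m)), row_m)
    cols = np.repeat(np.arange(len(col_m)), col_m)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        sim = np.zeros_like(arr)
        np.add.at(sim, (rows, perm), 1)
        if _table_logprob(sim, row_m, col_m) <= cutoff:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    method = f"monte_carlo(seed={seed}, n={n_mc})"
    log.warning("association test fell back to Monte Carlo (%s)", method)
    return FisherResult(float(p), method)


# ---------------------------------------------------------------------------
# bi-clustering of a selected-gene submatrix (S/G clusters)
# ---------------------------------------------------------------------------

def bicluster(
    matrix: pd.DataFrame,
    k_samples: int = 3,
    k_genes: int = 3,
    distance: str = "euclidean",
    linkage: str = "average",
) -> tuple[pd.Series, pd.Series]:
    """Cluster samples and genes of a (typically significant-gene) submatrix.

    Returns (sample labels S1..Sk, gene labels G1..Gk), each named in
    decreasing cluster-size order (ties broken by first occurrence).
    """
    centered = center_rows(matrix)
    s_assign = hcluster(centered, axis="columns", distance=distance, linkage=linkage, k=k_samples)
    g_assign = hcluster(centered, axis="rows", distance=distance, linkage=linkage, k=k_genes)

    def rename(labels: pd.Series, prefix: str) -> pd.Series:
        sizes = labels.value_counts()
        order = sizes.sort_values(ascending=False, kind="stable").index
        mapping = {old: f"{prefix}{i + 1}" for i, old in enumerate(order)}
        return labels.map(mapping)

    return rename(s_assign.labels, "S"), rename(g_assign.labels, "G")


def plot_heatmap(
    matrix: pd.DataFrame,
    path,
    sample_labels: pd.Series | None = None,
    title: str = "",
):
    """Basic row-centered heatmap with a blue (below mean) / yellow (above) palette."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centered = center_rows(matrix)
    order_rows = hierarchy.leaves_list(
        hierarchy.linkage(pdist(centered.to_numpy()), method="average")
    ) if centered.shape[0] > 2 else np.arange(centered.shape[0])
    order_cols = hierarchy.leaves_list(
        hierarchy.linkage(pdist(centered.to_numpy().T), method="average")
    ) if centered.shape[1] > 2 else np.arange(centered.shape[1])
    data = centered.iloc[order_rows, order_cols]
    fig, ax = plt.subplots(figsize=(max(6, data.shape[1] * 0.12), max(4, data.shape[0] * 0.25)))
    vmax = np.abs(data.to_numpy()).max() or 1.0
    im = ax.imshow(data, aspect="auto", cmap="cividis", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(data.shape[0]), labels=data.index, fontsize=6)
    ax.set_xticks([])
    if sample_labels is not None:
        colors = {HOT: "firebrick", COLD: "steelblue"}
        for x, s in enumerate(data.columns):
            ax.plot(x, -1, "s", color=colors.get(sample_labels.get(s), "gray"), ms=3)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log2 expression (row-centered)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
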