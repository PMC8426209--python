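"""Raw panel counts -> log2 normalized expression.

The default pipeline is the standard nCounter workflow, applied per sample in
this order:

1. positive-control scaling: multiply every count by
   (grand geometric mean of positive-control geomeans) / (the sample's
   positive-control geomean), removing lane-to-lane assay efficiency;
2. background flooring: raise endogenous counts to the sample's
   mean + 2 SD of its (scaled) negative controls, a detection threshold that
   preserves nonnegativity (flooring, not subtraction);
3. housekeeping scaling: multiply by (grand geometric mean of housekeeping
   geomeans) / (the sample's housekeeping geomean), equalizing RNA content;
4. log2(value + pseudocount).

Each step is switchable via :class:`NormalizationParams` so alternative
conventions can be matched; control probes are dropped from the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .panel_io import validate_probes

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """Inputs incompatible with the requested normalization."""


@dataclass
class NormalizationParams:
    use_positive_controls: bool = True
    background_mode: Literal["none", "threshold_mean_plus_2sd"] = "threshold_mean_plus_2sd"
    housekeeping_mode: Literal["geomean_scale", "none"] = "geomean_scale"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise NormalizationError(f"pseudocount must be > 0, got {self.pseudocount}")
        if self.background_mode not in ("none", "threshold_mean_plus_2sd"):
            raise NormalizationError(f"unknown background_mode {self.background_mode!r}")
        if self.housekeeping_mode not in ("geomean_scale", "none"):
            raise NormalizationError(f"unknown housekeeping_mode {self.housekeeping_mode!r}")


def geometric_mean(values: Iterable[float]) -> float:
    """exp(mean(log(values))); requires a non-empty list of positives."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise NormalizationError("geometric_mean of an empty list")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise NormalizationError("geometric_mean requires finite positive values")
    return float(np.exp(np.mean(np.log(arr))))


def _column_geomeans(block: pd.DataFrame, what: str) -> pd.Series:
    """Per-sample geometric mean of a probe block, flooring zeros at 1.

    An all-zero column is a hard error; isolated zero counts (vanishingly rare
    for high-expressed control/housekeeping probes) are floored with a warning
    rather than aborting the run.
    """
    vals = block.to_numpy(dtype=float)
    zero_cols = (vals <= 0).all(axis=0)
    if zero_cols.any():
        bad = block.columns[zero_cols][0]
        raise NormalizationError(f"all {what} counts are zero in sample {bad!r}")
    if (vals <= 0).any():
        log.warning("%s block contains zero counts; flooring at 1 for geomean", what)
        vals = np.maximum(vals, 1.0)
    return pd.Series(np.exp(np.mean(np.log(vals), axis=0)), index=block.columns)


def normalize(
    counts: pd.DataFrame,
    probes: pd.DataFrame,
    params: NormalizationParams | None = None,
) -> pd.DataFrame:
    """Normalize a genes x samples counts matrix; returns endogenous log2 values.

    Output rows are exactly the endogenous genes, in input order; values are
    finite log2 expression.
    """
    params = params if params is not None else NormalizationParams()
    validate_probes(probes, genes=counts.index)
    cls = probes.loc[counts.index, "probe_class"]
    endo = counts.index[cls == "endogenous"]
    hk = counts.index[cls == "housekeeping"]
    neg = counts.index[cls == "negative_control"]
    pos = counts.index[cls == "positive_control"]

    work = counts.astype(float).copy()

    if params.use_positive_controls:
        if len(pos) == 0:
            raise NormalizationError("positive-control scaling requested but no positive_control probes")
        gm = _column_geomeans(work.loc[pos], "positive control")
        factors = geometric_mean(gm) / gm
        work = work.mul(factors, axis=1)

    if params.background_mode == "threshold_mean_plus_2sd":
        if len(neg) == 0:
            raise NormalizationError("background thresholding requested but no negative_control probes")
        negblock = work.loc[neg]
        thresh = negblock.mean(axis=0) + 2.0 * negblock.std(axis=0, ddof=1)
        work.loc[endo] = work.loc[endo].clip(lower=thresh, axis=1)

    if params.housekeeping_mode == "geomean_scale":
        if len(hk) == 0:
            raise NormalizationError("housekeeping scaling requested but no housekeeping probes")
        gm = _column_geomeans(work.loc[hk], "housekeeping")
        factors = geometric_mean(gm) / gm
        work = work.mul(factors, axis=1)

    out = np.log2(work.loc[endo] + params.pseudocount)
    if not np.all(np.isfinite(out.to_numpy())):
        raise NormalizationError("non-finite values after normalization")
    return out
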