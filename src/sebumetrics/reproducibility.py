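"""Replicate reproducibility via percent relative standard deviation.

Two designs, each evaluated per grooming region:

* intrabatch — %RSD across the six technical replicates within each MS batch
  independently (N = 5 batches);
* interbatch — %RSD across the five repeat injections of each replicate
  sample independently (N = 6 replicates).

The summary metric is the median of all per-(bin, group) %RSD values.

%RSD is an intensity CV, so it is computed on the linear scale. By default
the values used are the TIC-normalized fractional ion counts restricted to
the top-selected bins (pass the ``tic_normalized``-stage matrix, or any
log-stage matrix, which is mapped back through ``2**v - epsilon``). See the
methods note for why the pre-batch-correction scale is the default: after
exact per-feature batch-mean removal on a balanced design, interbatch
residual variance is mathematically at most the intrabatch variance, so
batch-to-batch variability is only visible where batch effects survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import BinnedFeatureMatrix

__all__ = ["RSDSummary", "percent_rsd", "intrabatch_rsd", "interbatch_rsd"]

logger = logging.getLogger(__name__)


@dataclass
class RSDSummary:
    """Per-(bin, group) %RSD values and their pooled median."""

    mode: str  # "intrabatch" | "interbatch"
    region: str
    rsd_values: np.ndarray  # (n_bins, n_groups), NaN where the mean was zero
    median_percent_rsd: float
    n_groups: int
    n_excluded: int  # non-finite per-(bin, group) values excluded from the median


def percent_rsd(values) -> float:
    """100 x sample standard deviation (n-1 denominator) / mean.

    Requires at least two values. A zero mean yields NaN (flagged
    non-finite); callers exclude such values from medians.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("percent_rsd requires at least two values")
    mean = v.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


def _rsd_columns(x: np.ndarray) -> np.ndarray:
    """Row-wise %RSD of a bins x replicates block; NaN where the mean is 0."""
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    rsd[mean == 0] = np.nan
    return rsd


def _summarize(mode: str, region: str, blocks: list[np.ndarray]) -> RSDSummary:
    rsd = np.column_stack(blocks)
    finite = np.isfinite(rsd)
    n_excluded = int((~finite).sum())
    if n_excluded:
        logger.info("%s %s: excluded %d non-finite %%RSD values", mode, region, n_excluded)
    if not finite.any():
        raise ValidationError(f"no finite %RSD values for {mode}/{region}")
    return RSDSummary(
        mode=mode,
        region=region,
        rsd_values=rsd,
        median_percent_rsd=float(np.median(rsd[finite])),
        n_groups=rsd.shape[1],
        n_excluded=n_excluded,
    )


def _region_meta(metadata: pd.DataFrame, region: str) -> pd.DataFrame:
    md = metadata[metadata["region"] == region]
    if md.empty:
        raise ValidationError(f"no samples for region {region!r}")
    for col in ("replicate", "batch"):
        if col not in md.columns:
            raise ValidationError(f"metadata is missing the {col!r} column")
    return md


def intrabatch_rsd(
    matrix: BinnedFeatureMatrix, metadata: pd.DataFrame, region: str
) -> RSDSummary:
    """%RSD across technical replicates within each batch, pooled median."""
    md = _region_meta(metadata, region)
    values = matrix.linear_values()
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    blocks = []
    for batch, group in md.groupby("batch"):
        if len(group) < 2:
            raise ValidationError(f"batch {batch} has fewer than 2 replicates for {region!r}")
        idx = [col[s] for s in group["sample_id"].astype(str)]
        blocks.append(_rsd_columns(values[:, idx]))
    return _summarize("intrabatch", region, blocks)


def interbatch_rsd(
    matrix: BinnedFeatureMatrix, metadata: pd.DataFrame, region: str
) -> RSDSummary:
    """%RSD across each replicate's repeat injections, pooled median."""
    md = _region_meta(metadata, region)
    values = matrix.linear_values()
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    n_batches = md["batch"].nunique()
    blocks = []
    gaps = []
    for rep, group in md.groupby("replicate"):
        if group["batch"].nunique() != len(group) or len(group) != n_batches:
            gaps.append(
                f"replicate {rep}: batches {sorted(group['batch'])} (expected {n_batches})"
            )
            continue
        idx = [col[s] for s in group["sample_id"].astype(str)]
        blocks.append(_rsd_columns(values[:, idx]))
    if gaps:
        raise ValidationError("replicates missing from batches: " + "; ".join(gaps))
    return _summarize("interbatch", region, blocks)
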