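"""Feature-matrix normalization chain.

Five steps, applied strictly in order to a raw bins x samples matrix:

1. ``filter_sparse_bins`` — drop bins nonzero in fewer than 1% of samples.
2. ``tic_normalize`` — divide each column by its total ion count.
3. ``log_transform`` — add a small epsilon and take log2.
4. ``remove_batch_effects`` — per-feature linear-model batch correction
   (intercept plus sum-to-zero batch contrasts; the fitted batch terms are
   subtracted, preserving the grand-mean structure — the same algebra as
   limma's removeBatchEffect with a batch vector only).
5. ``select_top_median_bins`` — keep the bins with the highest medians.

Each operation checks the stage tag on the matrix, so the chain cannot run
out of order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, ValidationError
from .matrix import BinnedFeatureMatrix

__all__ = [
    "BatchAssignment",
    "NormalizationConfig",
    "assign_batches",
    "filter_sparse_bins",
    "tic_normalize",
    "log_transform",
    "remove_batch_effects",
    "select_top_median_bins",
    "normalize_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class BatchAssignment:
    """Maps every sample to an MS batch index (1..B, contiguous)."""

    batches: dict[str, int]

    def __post_init__(self) -> None:
        idx = sorted(set(self.batches.values()))
        if not idx or idx != list(range(1, len(idx) + 1)):
            raise ValidationError(f"batch indices must be contiguous from 1, got {idx}")

    @property
    def n_batches(self) -> int:
        return len(set(self.batches.values()))

    def vector(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.batches]
        if missing:
            raise ValidationError(f"samples without a batch assignment: {missing}")
        return np.array([self.batches[s] for s in sample_ids], dtype=int)

    @classmethod
    def explicit(cls, mapping: Mapping[str, int]) -> "BatchAssignment":
        return cls(dict(mapping))

    @classmethod
    def consecutive_blocks(cls, metadata: pd.DataFrame, block_size: int) -> "BatchAssignment":
        """Blocks of ``block_size`` consecutive injections form one batch."""
        n = len(metadata)
        if block_size <= 0 or n % block_size:
            raise ValidationError(
                f"block size {block_size} does not divide {n} samples evenly"
            )
        order = metadata.sort_values("injection_order", kind="stable")
        ranks = np.arange(n)
        return cls(
            {
                str(sid): int(rank // block_size) + 1
                for sid, rank in zip(order["sample_id"], ranks)
            }
        )


def assign_batches(metadata: pd.DataFrame, mode: str) -> BatchAssignment:
    """Build a :class:`BatchAssignment` from metadata.

    ``mode`` is ``"blocks:N"`` (N consecutive injections per batch) or
    ``"column:NAME"`` (take batch indices from a metadata column, e.g. the
    repeat-injection series of the reproducibility design).
    """
    if metadata["injection_order"].duplicated().any():
        raise ValidationError("injection_order values must be unique")
    if mode.startswith("blocks:"):
        return BatchAssignment.consecutive_blocks(metadata, int(mode.split(":", 1)[1]))
    if mode.startswith("column:"):
        col = mode.split(":", 1)[1]
        if col not in metadata.columns:
            raise ValidationError(f"metadata has no column {col!r}")
        return BatchAssignment.explicit(
            dict(zip(metadata["sample_id"].astype(str), metadata[col].astype(int)))
        )
    raise ConfigurationError(f"unknown batch mode {mode!r}")


@dataclass
class NormalizationConfig:
    """Parameters of the normalization chain."""

    min_nonzero_fraction: float = 0.01
    epsilon: float = 1e-10
    n_keep_bins: int = 3000
    batch_mode: str = "blocks:30"

    def __post_init__(self) -> None:
        if not (0 < self.min_nonzero_fraction < 1):
            raise ConfigurationError("min_nonzero_fraction must be in (0, 1)")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if self.n_keep_bins <= 0:
            raise ConfigurationError("n_keep_bins must be positive")


# ---------------------------------------------------------------------------


def filter_sparse_bins(
    matrix: BinnedFeatureMatrix, min_nonzero_fraction: float = 0.01
) -> BinnedFeatureMatrix:
    """Keep bins nonzero in at least ``min_nonzero_fraction`` of samples.

    The comparison is inclusive: with 180 samples and a 1% threshold a bin
    needs at least 2 nonzero samples (count/n >= 0.01). The result is
    densified — the surviving bin set is small.
    """
    matrix.require_stage("raw")
    vals = matrix.values
    if sp.issparse(vals):
        v = vals.tocsr().copy()
        v.eliminate_zeros()
        counts = np.diff(v.indptr)
    else:
        counts = (vals != 0).sum(axis=1)
    keep = counts / matrix.n_samples >= min_nonzero_fraction
    if not keep.any():
        raise ValidationError(
            "no bins survive the sparsity filter; review min_nonzero_fraction"
        )
    kept = vals.tocsr()[keep] if sp.issparse(vals) else vals[keep]
    dense = np.asarray(kept.todense()) if sp.issparse(kept) else np.asarray(kept, dtype=float)
    logger.info("sparse filter kept %d of %d bins", int(keep.sum()), matrix.n_bins)
    return matrix.advance("sparse_filtered", dense, bin_edges=matrix.bin_edges[keep])


def tic_normalize(matrix: BinnedFeatureMatrix) -> BinnedFeatureMatrix:
    """Divide each column by its sum so values are fractional ion counts."""
    matrix.require_stage("sparse_filtered")
    vals = matrix.dense()
    sums = vals.sum(axis=0)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        names = [matrix.sample_ids[i] for i in zero]
        raise ValidationError(f"samples with zero total intensity: {names}")
    return matrix.advance("tic_normalized", vals / sums)


def log_transform(matrix: BinnedFeatureMatrix, epsilon: float = 1e-10) -> BinnedFeatureMatrix:
    """Shift by ``epsilon`` and take log2; records epsilon on the matrix."""
    matrix.require_stage("tic_normalized")
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be positive")
    vals = matrix.dense()
    if (vals < 0).any():
        raise ValidationError("negative intensities reached the log step")
    return matrix.advance("log2", np.log2(vals + epsilon), log_epsilon=epsilon)


def remove_batch_effects(
    matrix: BinnedFeatureMatrix, batch: BatchAssignment
) -> BinnedFeatureMatrix:
    """Subtract per-feature least-squares batch terms (sum-to-zero contrasts).

    For every feature, fit ``value ~ intercept + batch`` with sum-to-zero
    batch coding and subtract the fitted batch contribution. The per-feature
    intercept (grand-mean structure) is preserved; in a balanced design the
    per-feature batch means become equal.
    """
    matrix.require_stage("log2")
    b = batch.vector(matrix.sample_ids)
    levels = np.unique(b)
    n_b = levels.size
    if n_b == 1:
        warnings.warn("single batch: batch correction is the identity", stacklevel=2)
        return matrix.advance("batch_corrected", matrix.dense().copy())
    counts = {int(l): int((b == l).sum()) for l in levels}
    empty = [l for l, c in counts.items() if c == 0]
    if empty:
        raise ValidationError(f"batches with zero samples: {empty}")

    # sum-to-zero contrast coding: batch j<B -> e_j, batch B -> -1 everywhere
    n = len(matrix.sample_ids)
    C = np.zeros((n, n_b - 1))
    for j, level in enumerate(levels[:-1]):
        C[b == level, j] = 1.0
    C[b == levels[-1], :] = -1.0
    X = np.column_stack([np.ones(n), C])

    Y = matrix.dense()  # features x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (1 + B-1) x features
    corrected = Y - (C @ beta[1:, :]).T
    return matrix.advance("batch_corrected", corrected)


def select_top_median_bins(matrix: BinnedFeatureMatrix, n_keep: int) -> BinnedFeatureMatrix:
    """Keep the ``n_keep`` bins with the largest per-bin medians.

    Ties at the boundary break toward the lower m/z edge; the original row
    order is preserved among survivors, and values are untouched.
    """
    matrix.require_stage("batch_corrected")
    if n_keep <= 0:
        raise ConfigurationError("n_keep must be positive")
    if n_keep > matrix.n_bins:
        raise ValidationError(f"n_keep={n_keep} exceeds bin count {matrix.n_bins}")
    med = np.median(matrix.dense(), axis=1)
    # primary key: median descending; tie-break: row index (= lower m/z) ascending
    ranked = np.lexsort((np.arange(matrix.n_bins), -med))
    keep = np.sort(ranked[:n_keep])
    return matrix.advance(
        "top_selected", matrix.dense()[keep], bin_edges=matrix.bin_edges[keep]
    )


def normalize_matrix(
    matrix: BinnedFeatureMatrix,
    metadata: pd.DataFrame,
    config: NormalizationConfig | None = None,
    batch: BatchAssignment | None = None,
    return_stages: bool = False,
):
    """Run the full chain on a raw matrix.

    Returns the top-selected matrix, or (if ``return_stages``) a dict of the
    intermediate matrices keyed by stage.
    """
    cfg = config or NormalizationConfig()
    if batch is None:
        md = metadata[metadata["sample_id"].astype(str).isin(matrix.sample_ids)]
        batch = assign_batches(md, cfg.batch_mode)
    stages: dict[str, BinnedFeatureMatrix] = {"raw": matrix}
    m = filter_sparse_bins(matrix, cfg.min_nonzero_fraction)
    stages["sparse_filtered"] = m
    m = tic_normalize(m)
    stages["tic_normalized"] = m
    m = log_transform(m, cfg.epsilon)
    stages["log2"] = m
    m = remove_batch_effects(m, batch)
    stages["batch_corrected"] = m
    m = select_top_median_bins(m, cfg.n_keep_bins)
    stages["top_selected"] = m
    return stages if return_stages else m
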