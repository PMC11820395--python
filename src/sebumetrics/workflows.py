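"""High-level study workflows composed from the pipeline stages.

These mirror how the analyses are actually run on a cohort: each comparison
re-runs the normalization chain on its own sample subset (its own batch
vector and top-median bin selection), then applies the donor-exclusion
classifier or the %RSD metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import CVResult, run_cv
from .errors import ValidationError
from .matrix import BinnedFeatureMatrix
from .normalize import BatchAssignment, NormalizationConfig, assign_batches, normalize_matrix
from .reproducibility import RSDSummary, interbatch_rsd, intrabatch_rsd

__all__ = ["classification_comparison", "replicate_rsd_summaries", "rsd_input_matrix"]


def _batch(metadata: pd.DataFrame, batch_mode: str) -> BatchAssignment:
    if batch_mode == "column:batch" and "batch" not in metadata.columns:
        raise ValidationError("metadata has no 'batch' column")
    return assign_batches(metadata, batch_mode)


def classification_comparison(
    raw: BinnedFeatureMatrix,
    metadata: pd.DataFrame,
    task: str = "sex",
    regions: tuple[str, str] | None = None,
    n_keep: int = 3000,
    batch_mode: str = "column:batch",
    seed: int = 0,
    positive_class: str | None = None,
) -> CVResult:
    """Normalize the relevant sample subset of a raw matrix and run
    donor-exclusion LOOCV for one comparison (sex, or a region pair)."""
    if task == "sex":
        md = metadata
        label_col = "sex"
        positive = positive_class or "male"
    elif task == "region":
        if not regions or len(regions) != 2:
            raise ValidationError("region task needs exactly two regions")
        md = metadata[metadata["region"].isin(regions)]
        label_col = "region"
        positive = positive_class or regions[0]
    else:
        raise ValidationError(f"unknown task {task!r}")
    ids = list(md["sample_id"].astype(str))
    sub = raw.select_samples(ids)
    cfg = NormalizationConfig(n_keep_bins=n_keep, batch_mode=batch_mode)
    final = normalize_matrix(sub, md, cfg, batch=_batch(md, batch_mode))
    labels = md.set_index(md["sample_id"].astype(str)).loc[final.sample_ids, label_col]
    return run_cv(final, labels, md, seed=seed, positive_class=positive)


def rsd_input_matrix(stages: dict, scale: str = "tic") -> BinnedFeatureMatrix:
    """Matrix on which %RSD is evaluated for a given scale choice.

    ``tic`` (default): linear TIC-normalized fractional ion counts restricted
    to the top-selected bins; ``final``: the batch-corrected top-selected
    matrix (mapped back to linear by the %RSD functions).
    """
    final = stages["top_selected"]
    if scale == "final":
        return final
    if scale != "tic":
        raise ValidationError(f"unknown %RSD scale {scale!r}")
    tic = stages["tic_normalized"]
    keep = np.isin(tic.bin_edges, final.bin_edges)
    return BinnedFeatureMatrix(
        tic.bin_edges[keep], list(tic.sample_ids), tic.dense()[keep],
        "tic_normalized", tic.bin_width,
    )


def replicate_rsd_summaries(
    raw: BinnedFeatureMatrix,
    metadata: pd.DataFrame,
    n_keep: int = 3000,
    scale: str = "tic",
) -> dict[str, dict[str, RSDSummary]]:
    """Run the chain on a replicate-study matrix and compute intrabatch and
    interbatch %RSD summaries for every region."""
    cfg = NormalizationConfig(n_keep_bins=n_keep, batch_mode="column:batch")
    stages = normalize_matrix(
        raw, metadata, cfg, batch=_batch(metadata, "column:batch"), return_stages=True
    )
    mat = rsd_input_matrix(stages, scale)
    out: dict[str, dict[str, RSDSummary]] = {"intrabatch": {}, "interbatch": {}}
    for region in sorted(metadata["region"].unique()):
        out["intrabatch"][region] = intrabatch_rsd(mat, metadata, region)
        out["interbatch"][region] = interbatch_rsd(mat, metadata, region)
    return out
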