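"""Build the raw bins x samples feature matrix from centroid spectra.

Peak intensities are summed into fixed-width m/z bins over a retention-time
window (closed interval, default [0.8, 1.0] min — the flow-injection plug).
Peaks outside the scan range are excluded silently but counted in the log.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .matrix import BinDefinition, BinnedFeatureMatrix
from .ms1 import CentroidSpectrum, read_ms1, read_mzml

__all__ = ["accumulate_sample", "build_feature_matrix", "load_spectra"]

logger = logging.getLogger(__name__)

RT_WINDOW = (0.8, 1.0)


def load_spectra(path: str | Path) -> list[CentroidSpectrum]:
    """Read a spectra file, dispatching on suffix (.ms1 text or .mzML)."""
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return read_mzml(path)
    return read_ms1(path)


def accumulate_sample(
    spectra: Sequence[CentroidSpectrum],
    bin_def: BinDefinition = BinDefinition(),
    rt_window: tuple[float, float] = RT_WINDOW,
) -> np.ndarray:
    """Sum peak intensities into m/z bins over the retention window.

    Returns a dense vector of length ``bin_def.n_bins``. Scans with retention
    time inside the closed interval ``rt_window`` contribute; peaks with m/z
    outside ``[mz_min, mz_max)`` are dropped (count logged).
    """
    lo, hi = rt_window
    out = np.zeros(bin_def.n_bins, dtype=np.float64)
    n_excluded = 0
    for spec in spectra:
        if not (lo <= spec.retention_time <= hi) or len(spec) == 0:
            continue
        idx = bin_def.index_of(spec.mz)
        keep = idx >= 0
        n_excluded += int((~keep).sum())
        if keep.any():
            out += np.bincount(idx[keep], weights=spec.intensity[keep], minlength=bin_def.n_bins)
    if n_excluded:
        logger.info("accumulate_sample: excluded %d out-of-range peaks", n_excluded)
    return out


def build_feature_matrix(
    samples: Mapping[str, str | Path | Sequence[CentroidSpectrum]],
    metadata: pd.DataFrame,
    bin_def: BinDefinition = BinDefinition(),
    rt_window: tuple[float, float] = RT_WINDOW,
) -> BinnedFeatureMatrix:
    """Assemble the raw feature matrix, columns ordered by injection order.

    Parameters
    ----------
    samples : mapping
        ``sample_id -> spectra`` where spectra is a file path (MS1 or mzML)
        or an in-memory list of :class:`CentroidSpectrum`.
    metadata : DataFrame
        Must contain ``sample_id`` and ``injection_order``; its sample ids
        must match ``samples`` one-to-one.
    """
    meta_ids = list(metadata["sample_id"].astype(str))
    extra = sorted(set(samples) - set(meta_ids))
    missing = sorted(set(meta_ids) - set(samples))
    if extra or missing:
        raise ValidationError(
            f"sample/metadata mismatch: files without metadata {extra}; "
            f"metadata without files {missing}"
        )
    if len(meta_ids) != len(set(meta_ids)):
        raise ValidationError("duplicate sample_id in metadata")

    order = metadata.sort_values("injection_order", kind="stable")["sample_id"].astype(str)
    cols: list[sp.csc_matrix] = []
    for sid in order:
        source = samples[sid]
        spectra = load_spectra(source) if isinstance(source, (str, Path)) else source
        vec = accumulate_sample(spectra, bin_def, rt_window)
        cols.append(sp.csc_matrix(vec.reshape(-1, 1)))
    values = sp.hstack(cols, format="csr") if cols else sp.csr_matrix((bin_def.n_bins, 0))
    return BinnedFeatureMatrix(
        bin_edges=bin_def.lower_edges,
        sample_ids=list(order),
        values=values,
        stage="raw",
        bin_width=bin_def.width,
    )
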