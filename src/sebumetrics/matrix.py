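"""Binned feature matrices and sample metadata.

The central container is :class:`BinnedFeatureMatrix`: an m/z-bins x samples
intensity table tagged with its processing stage. Stages advance only in the
documented order (raw -> sparse_filtered -> tic_normalized -> log2 ->
batch_corrected -> top_selected); each normalization operation checks the tag
so the chain cannot be run out of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import StageError, ValidationError

__all__ = [
    "STAGES",
    "BinDefinition",
    "BinnedFeatureMatrix",
    "read_metadata",
    "write_metadata",
    "read_matrix_table",
]

STAGES = (
    "raw",
    "sparse_filtered",
    "tic_normalized",
    "log2",
    "batch_corrected",
    "top_selected",
)

#: stages whose values live on the log2(v + epsilon) scale
LOG_STAGES = ("log2", "batch_corrected", "top_selected")

REQUIRED_METADATA_COLUMNS = ("sample_id", "donor_id", "sex", "region", "replicate", "injection_order")


@dataclass(frozen=True)
class BinDefinition:
    """Fixed-width m/z binning over a half-open scan range.

    Defaults follow positive-mode lipid profiling over 250-1300 m/z with
    0.01 Da bins (105,000 bins). Bins are half-open ``[lower, lower+width)``;
    a peak exactly on a boundary belongs to the upper bin.
    """

    mz_min: float = 250.0
    mz_max: float = 1300.0
    width: float = 0.01

    # absorbs float representation error at bin boundaries
    _GUARD: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        if not (self.mz_max > self.mz_min and self.width > 0):
            raise ValidationError("require mz_max > mz_min and width > 0")

    @property
    def n_bins(self) -> int:
        return int(round((self.mz_max - self.mz_min) / self.width))

    @property
    def lower_edges(self) -> np.ndarray:
        return self.mz_min + self.width * np.arange(self.n_bins)

    def index_of(self, mz: np.ndarray) -> np.ndarray:
        """Bin index for each m/z; values outside [mz_min, mz_max) get -1."""
        mz = np.asarray(mz, dtype=np.float64)
        idx = np.floor((mz - self.mz_min + self._GUARD) / self.width).astype(np.int64)
        idx[(idx < 0) | (idx >= self.n_bins)] = -1
        return idx


@dataclass
class BinnedFeatureMatrix:
    """Bins x samples intensity table with a processing-stage tag.

    ``values`` may be a dense ndarray or a scipy sparse matrix (the raw stage
    of a full 105,000-bin matrix is almost entirely empty). All operations are
    defined value-wise, independent of storage.
    """

    bin_edges: np.ndarray  # lower m/z edge per row, Da
    sample_ids: list[str]
    values: np.ndarray | sp.spmatrix
    stage: str = "raw"
    bin_width: float = 0.01
    log_epsilon: float | None = None  # epsilon used by the log2 step, once applied

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if self.values.shape != (self.bin_edges.size, len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{self.bin_edges.size} bins x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")

    # -- helpers ----------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return int(self.bin_edges.size)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, matrix is at {self.stage!r}"
            )

    def advance(self, new_stage: str, values, bin_edges=None, **kw) -> "BinnedFeatureMatrix":
        """Return a copy at ``new_stage``; transitions must move forward."""
        if STAGES.index(new_stage) < STAGES.index(self.stage):
            raise StageError(f"cannot move from {self.stage!r} back to {new_stage!r}")
        edges = self.bin_edges if bin_edges is None else bin_edges
        eps = kw.pop("log_epsilon", self.log_epsilon)
        return BinnedFeatureMatrix(
            bin_edges=edges,
            sample_ids=list(self.sample_ids),
            values=values,
            stage=new_stage,
            bin_width=self.bin_width,
            log_epsilon=eps,
        )

    def select_samples(self, ids: Sequence[str]) -> "BinnedFeatureMatrix":
        """Column subset in the given order; stage is preserved."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise ValidationError(f"sample ids not in matrix: {missing}")
        cols = [pos[s] for s in ids]
        vals = self.values[:, cols] if not sp.issparse(self.values) else self.values.tocsc()[:, cols]
        return BinnedFeatureMatrix(
            self.bin_edges.copy(), [self.sample_ids[c] for c in cols], vals,
            self.stage, self.bin_width, self.log_epsilon,
        )

    def column_sums(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)

    def linear_values(self) -> np.ndarray:
        """Values on the linear intensity scale.

        Log-stage matrices are mapped back through ``2**v - epsilon`` (clipped
        at zero); earlier stages are returned as stored.
        """
        dense = self.dense()
        if self.stage in LOG_STAGES:
            if self.log_epsilon is None:
                raise StageError("log-stage matrix is missing its epsilon record")
            return np.clip(np.exp2(dense) - self.log_epsilon, 0.0, None)
        return dense

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path, drop_empty_bins: bool | None = None) -> None:
        """Write as TSV: first column the bin lower edge (2 decimals), then
        one column per sample.

        At the raw stage, bins with no signal in any sample default to being
        omitted (they carry no information and are removed by the 1% sparsity
        filter regardless); pass ``drop_empty_bins=False`` to keep them.
        """
        if drop_empty_bins is None:
            drop_empty_bins = self.stage == "raw"
        vals = self.values
        edges = self.bin_edges
        if drop_empty_bins:
            if sp.issparse(vals):
                keep = np.diff(vals.tocsr().indptr) > 0
            else:
                keep = (vals != 0).any(axis=1)
            vals = vals.tocsr()[keep] if sp.issparse(vals) else vals[keep]
            edges = edges[keep]
        dense = np.asarray(vals.todense()) if sp.issparse(vals) else vals
        df = pd.DataFrame(dense, columns=self.sample_ids)
        df.insert(0, "mz_bin", [f"{e:.2f}" for e in edges])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, stage: str = "raw",
                 bin_width: float = 0.01, log_epsilon: float | None = None
                 ) -> "BinnedFeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        edges = df.iloc[:, 0].astype(float).to_numpy()
        return cls(edges, list(df.columns[1:]), df.iloc[:, 1:].to_numpy(dtype=np.float64),
                   stage, bin_width, log_epsilon)


def read_matrix_table(path: str | Path, stage: str = "raw", bin_width: float = 0.01
                      ) -> BinnedFeatureMatrix:
    """Read a bins x samples matrix from TSV/CSV/XLSX, bypassing binning.

    This is the entry point for externally supplied raw feature matrices
    (e.g. a study's deposited supplementary tables): first column = bin m/z,
    remaining columns = samples.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
    edges = df.iloc[:, 0].astype(float).to_numpy()
    return BinnedFeatureMatrix(
        edges, list(df.columns[1:]), df.iloc[:, 1:].to_numpy(dtype=np.float64),
        stage, bin_width,
    )


def write_metadata(path: str | Path, metadata: pd.DataFrame) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValidationError(f"metadata is missing columns: {missing}")
    return md
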