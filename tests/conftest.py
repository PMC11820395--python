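"""Shared fixtures: simulated cohorts at the default study conditions.

Session-scoped because the full cohort (30 donors x 3 regions x 2 fingers)
and the replicate study (6 replicates x 5 batches x 3 regions) are reused by
several analysis tests.
"""

import numpy as np
import pandas as pd
import pytest

from sebumetrics import (
    BinnedFeatureMatrix,
    CohortConfig,
    NormalizationConfig,
    assign_batches,
    build_feature_matrix,
    normalize_matrix,
    simulate_cohort,
    simulate_replicate_study,
)

#: bins kept by top-median selection in synthetic runs (~80% of the ~500
#: bins that survive the sparsity filter at the default 500-peak profile)
SYNTHETIC_N_KEEP = 400


@pytest.fixture(scope="session")
def default_cohort():
    """Full default cohort (180 samples) with its raw feature matrix."""
    sim = simulate_cohort(CohortConfig(rng_seed=0))
    raw = build_feature_matrix(sim.spectra, sim.metadata)
    return sim, raw


@pytest.fixture(scope="session")
def replicate_study():
    """Default reproducibility design (90 spectra) with its raw matrix and
    normalization stages."""
    sim = simulate_replicate_study(CohortConfig(rng_seed=0))
    raw = build_feature_matrix(sim.spectra, sim.metadata)
    batch = assign_batches(sim.metadata, "column:batch")
    stages = normalize_matrix(
        raw,
        sim.metadata,
        NormalizationConfig(n_keep_bins=SYNTHETIC_N_KEEP, batch_mode="column:batch"),
        batch=batch,
        return_stages=True,
    )
    return sim, raw, stages


@pytest.fixture()
def small_cohort():
    """4 donors x 3 regions x 2 fingers, 60 peaks: fast unit-test cohort."""
    sim = simulate_cohort(CohortConfig(n_donors=4, n_lipid_peaks=60, rng_seed=0))
    return sim


def make_matrix(values, stage="top_selected", sample_ids=None, log_epsilon=1e-10):
    """Wrap a plain array as a BinnedFeatureMatrix for direct-op tests."""
    values = np.asarray(values, dtype=float)
    n_bins, n_samples = values.shape
    ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    return BinnedFeatureMatrix(
        250.0 + 0.01 * np.arange(n_bins), ids, values, stage, 0.01,
        log_epsilon if stage in ("log2", "batch_corrected", "top_selected") else None,
    )


def make_metadata(n, donors=None, region="forehead", sex="female", batch=None, replicate=None):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "donor_id": donors if donors is not None else [f"d{i}" for i in range(n)],
            "sex": sex if not isinstance(sex, (list, np.ndarray, pd.Series)) else sex,
            "region": region,
            "replicate": replicate if replicate is not None else 1,
            "injection_order": np.arange(1, n + 1),
            **({"batch": batch} if batch is not None else {}),
        }
    )
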