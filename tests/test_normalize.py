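"""Normalization chain: sparsity filter, TIC, log2, batch correction,
top-median selection, batch assignment, and stage-order enforcement."""

import subprocess
import textwrap

import numpy as np
import pytest

from conftest import make_matrix, make_metadata
from sebumetrics import (
    BatchAssignment,
    NormalizationConfig,
    assign_batches,
    filter_sparse_bins,
    log_transform,
    normalize_matrix,
    remove_batch_effects,
    select_top_median_bins,
    tic_normalize,
)
from sebumetrics.errors import ConfigurationError, StageError, ValidationError


# -- sparsity filter --------------------------------------------------------


def test_sparse_filter_boundary_is_inclusive():
    n = 200
    values = np.zeros((3, n))
    values[0, 0] = 5.0  # 0.5% of samples: dropped
    values[1, :2] = 5.0  # 1.0%: kept
    values[2, :] = 1.0
    out = filter_sparse_bins(make_matrix(values, stage="raw"), 0.01)
    assert out.n_bins == 2
    np.testing.assert_array_equal(out.values[0], values[1])


def test_sparse_filter_all_zero_matrix_errors():
    with pytest.raises(ValidationError):
        filter_sparse_bins(make_matrix(np.zeros((4, 10)), stage="raw"), 0.01)


def test_sparse_filter_matches_brute_force_count():
    rng = np.random.default_rng(3)
    values = rng.random((50, 40)) * (rng.random((50, 40)) < 0.05)
    kept = filter_sparse_bins(make_matrix(values, stage="raw"), 0.05)
    expected = [(row != 0).sum() / 40 >= 0.05 for row in values]
    assert kept.n_bins == sum(expected)
    np.testing.assert_array_equal(kept.bin_edges, make_matrix(values).bin_edges[expected])


# -- TIC --------------------------------------------------------------------


def test_tic_normalization_fractions():
    out = tic_normalize(make_matrix([[2.0], [3.0], [5.0]], stage="sparse_filtered"))
    np.testing.assert_allclose(out.values[:, 0], [0.2, 0.3, 0.5])


def test_tic_scale_invariance_and_unit_sums():
    rng = np.random.default_rng(1)
    v = rng.exponential(1, (20, 6))
    a = tic_normalize(make_matrix(v, stage="sparse_filtered"))
    b = tic_normalize(make_matrix(v * rng.uniform(0.1, 10, 6), stage="sparse_filtered"))
    np.testing.assert_allclose(a.values, b.values, rtol=1e-12)
    np.testing.assert_allclose(a.values.sum(axis=0), 1.0, atol=1e-9)


def test_tic_zero_sum_column_names_sample():
    v = np.ones((3, 2))
    v[:, 1] = 0.0
    with pytest.raises(ValidationError, match="s1"):
        tic_normalize(make_matrix(v, stage="sparse_filtered"))


# -- log2 -------------------------------------------------------------------


def test_log_transform_closed_forms():
    out = log_transform(
        make_matrix([[0.0], [1.0 - 1e-10]], stage="tic_normalized"), 1e-10
    )
    assert out.values[0, 0] == pytest.approx(-10 * np.log2(10))  # ~ -33.2193
    assert out.values[1, 0] == pytest.approx(0.0, abs=1e-9)
    assert out.log_epsilon == 1e-10


def test_log_transform_rejects_negatives():
    with pytest.raises(ValidationError):
        log_transform(make_matrix([[-0.1]], stage="tic_normalized"))


# -- batch correction -------------------------------------------------------


def test_balanced_shift_cancels_to_midline():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(5, 4))
    c = 1.7
    values = np.column_stack([base, base + c])
    ids = [f"s{i}" for i in range(8)]
    batch = BatchAssignment({s: 1 if i < 4 else 2 for i, s in enumerate(ids)})
    out = remove_batch_effects(
        make_matrix(values, stage="log2", sample_ids=ids), batch
    )
    np.testing.assert_allclose(out.values[:, :4], out.values[:, 4:], atol=1e-10)
    np.testing.assert_allclose(out.values[:, :4], base + c / 2, atol=1e-10)


def test_single_batch_is_identity_with_warning():
    m = make_matrix(np.arange(6.0).reshape(2, 3), stage="log2")
    batch = BatchAssignment({s: 1 for s in m.sample_ids})
    with pytest.warns(UserWarning):
        out = remove_batch_effects(m, batch)
    np.testing.assert_array_equal(out.values, m.values)


def _sum_contrast_oracle(Y, b):
    """Per-feature two-pass reference: subtract each batch's mean, then add
    back the unweighted grand mean of the batch means (the sum-to-zero
    least-squares intercept)."""
    out = np.empty_like(Y)
    levels = np.unique(b)
    for f in range(Y.shape[0]):
        batch_means = np.array([Y[f, b == l].mean() for l in levels])
        grand = batch_means.mean()
        for j, l in enumerate(levels):
            out[f, b == l] = Y[f, b == l] - batch_means[j] + grand
    return out


def test_batch_correction_matches_two_pass_oracle():
    rng = np.random.default_rng(7)
    Y = rng.normal(size=(50, 24))
    b = np.repeat([1, 2, 3, 4], 6)
    ids = [f"s{i}" for i in range(24)]
    out = remove_batch_effects(
        make_matrix(Y, stage="log2", sample_ids=ids),
        BatchAssignment(dict(zip(ids, b))),
    )
    np.testing.assert_allclose(out.values, _sum_contrast_oracle(Y, b), atol=1e-8)


def test_batch_correction_preserves_intercept_unbalanced():
    rng = np.random.default_rng(8)
    Y = rng.normal(size=(30, 17))
    b = np.array([1] * 3 + [2] * 6 + [3] * 8)  # unbalanced
    ids = [f"s{i}" for i in range(17)]
    batch = BatchAssignment(dict(zip(ids, b)))
    out = remove_batch_effects(make_matrix(Y, stage="log2", sample_ids=ids), batch)

    def sum_to_zero_intercept(values):
        C = np.zeros((17, 2))
        C[b == 1, 0] = 1.0
        C[b == 2, 1] = 1.0
        C[b == 3, :] = -1.0
        X = np.column_stack([np.ones(17), C])
        beta, *_ = np.linalg.lstsq(X, values.T, rcond=None)
        return beta[0]

    np.testing.assert_allclose(
        sum_to_zero_intercept(out.values), sum_to_zero_intercept(Y), atol=1e-8
    )
    # balanced case additionally equalizes per-feature batch means
    Yb = rng.normal(size=(10, 12))
    bb = np.repeat([1, 2, 3], 4)
    idsb = [f"t{i}" for i in range(12)]
    outb = remove_batch_effects(
        make_matrix(Yb, stage="log2", sample_ids=idsb),
        BatchAssignment(dict(zip(idsb, bb))),
    )
    means = np.stack([outb.values[:, bb == l].mean(axis=1) for l in (1, 2, 3)])
    np.testing.assert_allclose(means, np.broadcast_to(means[[0]], means.shape), atol=1e-8)


def test_batch_correction_agrees_with_limma(tmp_path):
    """Cross-check against the R limma reference implementation."""
    rng = np.random.default_rng(5)
    Y = rng.normal(size=(8, 10))
    b = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3, 3])  # unbalanced on purpose
    np.savetxt(tmp_path / "y.csv", Y, delimiter=",")
    script = textwrap.dedent(
        """
        suppressMessages(library(limma))
        y <- as.matrix(read.csv("y.csv", header=FALSE))
        batch <- factor(c(1,1,1,2,2,2,3,3,3,3))
        out <- removeBatchEffect(y, batch=batch)
        write.table(out, "out.csv", sep=",", row.names=FALSE, col.names=FALSE)
        """
    )
    (tmp_path / "rbe.R").write_text(script)
    subprocess.run(["Rscript", "rbe.R"], cwd=tmp_path, check=True, capture_output=True)
    expected = np.loadtxt(tmp_path / "out.csv", delimiter=",")
    ids = [f"s{i}" for i in range(10)]
    out = remove_batch_effects(
        make_matrix(Y, stage="log2", sample_ids=ids),
        BatchAssignment(dict(zip(ids, b))),
    )
    np.testing.assert_allclose(out.values, expected, atol=1e-8)


# -- top-median selection ---------------------------------------------------


def test_top_median_selection_counts_and_value_preservation():
    rng = np.random.default_rng(2)
    v = rng.normal(size=(10, 5))
    m = make_matrix(v, stage="batch_corrected")
    out = select_top_median_bins(m, 3)
    med = np.median(v, axis=1)
    expected_rows = np.sort(np.argsort(-med, kind="stable")[:3])
    assert out.n_bins == 3
    np.testing.assert_array_equal(out.values, v[expected_rows])
    np.testing.assert_array_equal(out.bin_edges, m.bin_edges[expected_rows])
    identity = select_top_median_bins(m, 10)
    np.testing.assert_array_equal(identity.values, v)


def test_top_median_ties_break_toward_lower_mz():
    v = np.array([[1.0, 1.0], [2.0, 2.0], [1.0, 1.0], [0.5, 0.5]])
    out = select_top_median_bins(make_matrix(v, stage="batch_corrected"), 2)
    # medians: 1, 2, 1, 0.5 -> keep row 1 and (tie between rows 0 and 2) row 0
    np.testing.assert_array_equal(out.values, v[[0, 1]])


def test_top_median_invalid_n_keep():
    m = make_matrix(np.ones((4, 3)), stage="batch_corrected")
    with pytest.raises(ConfigurationError):
        select_top_median_bins(m, 0)
    with pytest.raises(ValidationError):
        select_top_median_bins(m, 5)


# -- batch assignment -------------------------------------------------------


def test_consecutive_blocks_of_30():
    md = make_metadata(180)
    batches = assign_batches(md, "blocks:30")
    vec = batches.vector(list(md["sample_id"]))
    assert batches.n_batches == 6
    assert np.bincount(vec)[1:].tolist() == [30] * 6


def test_batch_from_column():
    md = make_metadata(90, batch=np.repeat(np.arange(1, 6), 18))
    batches = assign_batches(md, "column:batch")
    assert batches.n_batches == 5
    assert np.bincount(batches.vector(list(md["sample_id"])))[1:].tolist() == [18] * 5


def test_block_size_must_divide_sample_count():
    with pytest.raises(ValidationError):
        assign_batches(make_metadata(179), "blocks:30")


# -- chain ------------------------------------------------------------------


def test_stage_order_is_enforced():
    raw = make_matrix(np.ones((4, 3)), stage="raw")
    with pytest.raises(StageError):
        tic_normalize(raw)
    with pytest.raises(StageError):
        log_transform(raw)
    filtered = filter_sparse_bins(raw, 0.1)
    with pytest.raises(StageError):
        filter_sparse_bins(filtered, 0.1)  # cannot re-run an earlier stage
    with pytest.raises(StageError):
        select_top_median_bins(filtered, 2)


def test_full_chain_is_deterministic(small_cohort):
    from sebumetrics import build_feature_matrix

    sim = small_cohort
    raw = build_feature_matrix(sim.spectra, sim.metadata)
    cfg = NormalizationConfig(n_keep_bins=30, batch_mode="column:batch")
    a = normalize_matrix(raw, sim.metadata, cfg)
    b = normalize_matrix(raw, sim.metadata, cfg)
    assert np.array_equal(a.dense(), b.dense())
    assert a.sample_ids == b.sample_ids
    assert a.stage == "top_selected"
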