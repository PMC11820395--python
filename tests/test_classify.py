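"""Donor-exclusion LOOCV, ROC/AUC, accuracy, PCA, concentration ellipses."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from conftest import make_matrix, make_metadata
from sebumetrics import (
    CVResult,
    BoosterHyperparameters,
    classification_accuracy,
    group_ellipse,
    leave_one_donor_out_splits,
    pca_projection,
    roc_auc,
    run_cv,
)
from sebumetrics.errors import ValidationError


# -- splits -----------------------------------------------------------------


def test_donor_exclusion_split_sizes():
    md = make_metadata(180, donors=np.repeat([f"d{i}" for i in range(30)], 6))
    splits = leave_one_donor_out_splits(md)
    assert len(splits) == 180
    assert all(train.size == 174 for train, _ in splits)


def test_two_donor_splits_train_on_the_other():
    md = make_metadata(2, donors=["a", "b"])
    splits = leave_one_donor_out_splits(md)
    assert [(list(tr), te) for tr, te in splits] == [([1], 0), ([0], 1)]


def test_splits_partition_all_samples_exactly_once():
    md = make_metadata(24, donors=np.repeat([f"d{i}" for i in range(8)], 3))
    splits = leave_one_donor_out_splits(md)
    tests = sorted(te for _, te in splits)
    assert tests == list(range(24))
    donors = md["donor_id"].to_numpy()
    for train, te in splits:
        assert donors[te] not in donors[train]


def test_missing_donor_ids_rejected():
    md = make_metadata(4)
    md.loc[2, "donor_id"] = None
    with pytest.raises(ValidationError):
        leave_one_donor_out_splits(md)


# -- ROC / AUC --------------------------------------------------------------


def pair_counting_auc(probs, labels):
    """Brute-force U-statistic: P(score_pos > score_neg) + 0.5 P(equal)."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, bool)
    pos, neg = probs[labels], probs[~labels]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_auc_hand_example():
    _, auc = roc_auc([0.9, 0.4, 0.6, 0.1], [True, True, False, False])
    assert auc == pytest.approx(0.75)


def test_auc_degenerate_cases():
    _, tied = roc_auc([0.5] * 6, [True, False] * 3)
    assert tied == pytest.approx(0.5)
    _, perfect = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
    assert perfect == pytest.approx(1.0)


def test_auc_single_class_rejected():
    with pytest.raises(ValidationError):
        roc_auc([0.3, 0.7], [True, True])


@pytest.mark.parametrize("seed", range(10))
def test_trapezoid_auc_equals_pair_counting(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 201))
    labels = np.zeros(n, bool)
    labels[: int(rng.integers(1, n))] = True
    rng.shuffle(labels)
    probs = np.round(rng.random(n), 2)  # coarse grid forces ties
    _, auc = roc_auc(probs, labels)
    assert auc == pytest.approx(pair_counting_auc(probs, labels), abs=1e-12)


# -- accuracy ---------------------------------------------------------------


def _cv_result(probs, labels, positive="a", negative="b"):
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(probs))],
            "donor_id": [f"d{i}" for i in range(len(probs))],
            "label": labels,
            "prob": probs,
            "pred": ["a"] * len(probs),
        }
    )
    return CVResult(table, positive, negative, 0.0, np.empty((0, 2)), 0.5, 0,
                    BoosterHyperparameters())


def test_accuracy_display_rounding():
    labels = ["a"] * 103 + ["b"] * 77  # 103 of 180 correct
    probs = [0.9] * 103 + [0.9] * 77
    acc = classification_accuracy(_cv_result(probs, labels))
    assert acc == pytest.approx(100 * 103 / 180)
    assert round(acc) == 57


def test_accuracy_tie_rule_predicts_positive():
    acc = classification_accuracy(_cv_result([0.5, 0.5], ["a", "b"]))
    assert acc == pytest.approx(50.0)  # both predicted "a"


# -- run_cv -----------------------------------------------------------------


def _separable_setup(n_donors=6, per_donor=2, n_feat=8, seed=0):
    rng = np.random.default_rng(seed)
    n = n_donors * per_donor
    donors = np.repeat([f"d{i}" for i in range(n_donors)], per_donor)
    labels = np.tile(["neg", "pos"], n // 2)
    X = rng.normal(0, 0.1, size=(n_feat, n))
    # one two-valued high-contrast feature: held-out values coincide with
    # training values, so histogram split thresholds always route correctly
    X[0] = np.where(labels == "pos", 5.0, -5.0)
    md = make_metadata(n, donors=donors)
    return make_matrix(X, stage="top_selected"), labels, md


def test_separable_labels_classified_perfectly():
    matrix, labels, md = _separable_setup()
    res = run_cv(matrix, labels, md, seed=0, positive_class="pos")
    assert res.accuracy == 100.0
    assert res.auc == pytest.approx(1.0)


def test_run_cv_is_deterministic():
    matrix, labels, md = _separable_setup(seed=3)
    a = run_cv(matrix, labels, md, seed=5)
    b = run_cv(matrix, labels, md, seed=5)
    np.testing.assert_array_equal(a.table["prob"], b.table["prob"])
    assert a.auc == b.auc


def test_each_sample_predicted_exactly_once():
    matrix, labels, md = _separable_setup(n_donors=5)
    res = run_cv(matrix, labels, md, seed=1)
    assert sorted(res.table["sample_id"]) == sorted(md["sample_id"])
    assert res.table["prob"].between(0, 1).all()


def test_single_class_training_fold_named():
    # labels follow donors, so excluding a donor removes an entire class
    md = make_metadata(4, donors=["a", "a", "b", "b"])
    matrix = make_matrix(np.random.default_rng(0).normal(size=(3, 4)))
    with pytest.raises(ValidationError, match="donor"):
        run_cv(matrix, ["x", "x", "y", "y"], md, seed=0)


def test_non_binary_labels_rejected():
    matrix, labels, md = _separable_setup()
    bad = np.array(labels, dtype=object)
    bad[0] = "third"
    with pytest.raises(ValidationError):
        run_cv(matrix, bad, md, seed=0)


def test_permutation_null_auc_centers_near_half():
    """Donor-level label permutations on featureless data: the mean
    out-of-fold AUC over 50 permutations sits near chance (the
    leave-one-donor-out design has a small pessimistic bias)."""
    rng = np.random.default_rng(0)
    n_donors, per = 20, 2
    n = n_donors * per
    X = rng.normal(size=(40, n))
    donors = [f"d{i // per}" for i in range(n)]
    md = make_metadata(n, donors=donors)
    matrix = make_matrix(X)
    aucs = []
    for p in range(50):
        assignment = dict(
            zip([f"d{i}" for i in range(n_donors)],
                rng.permutation(["a", "b"] * (n_donors // 2)))
        )
        labels = md["donor_id"].map(assignment)
        aucs.append(run_cv(matrix, labels, md, seed=p, positive_class="b").auc)
    assert 0.45 <= np.mean(aucs) <= 0.55


# -- PCA --------------------------------------------------------------------


def test_identical_samples_get_identical_scores():
    v = np.random.default_rng(1).normal(size=(6, 1))
    values = np.column_stack([v, v, v + 1, v + 1, v - 2])
    res = pca_projection(make_matrix(values))
    np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-10)
    np.testing.assert_allclose(res.scores[2], res.scores[3], atol=1e-10)


def test_collinear_data_explained_by_pc1():
    t = np.linspace(-2, 2, 9)
    direction = np.array([1.0, 2.0, -0.5])
    values = (direction[:, None] * t[None, :])  # samples on a line
    res = pca_projection(make_matrix(values))
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(4)
    values = rng.normal(size=(50, 20))  # bins x samples
    res = pca_projection(make_matrix(values))
    X = values.T - values.T.mean(axis=0)
    eigvals, eigvecs = np.linalg.eigh(np.cov(X, rowvar=False))
    order = np.argsort(eigvals)[::-1]
    eigvecs = eigvecs[:, order]
    expected = X @ eigvecs[:, :2]
    for k in range(2):  # orient per the largest-loading-positive convention
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            expected[:, k] *= -1
    np.testing.assert_allclose(res.scores, expected, atol=1e-8)
    evr = eigvals[order][:2] / eigvals.sum()
    np.testing.assert_allclose(res.explained_variance_ratio, evr, atol=1e-10)


def test_pca_needs_three_samples():
    with pytest.raises(ValidationError):
        pca_projection(make_matrix(np.ones((4, 2))))


# -- ellipses ---------------------------------------------------------------


def test_unit_variance_group_gives_chi2_circle():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(200, 2))
    pts -= pts.mean(axis=0)
    # whiten so the sample covariance is exactly the identity
    cov = np.cov(pts, rowvar=False)
    L = np.linalg.cholesky(np.linalg.inv(cov))
    pts = pts @ L
    ellipses = group_ellipse(pts, ["g"] * 200, level=0.95)
    expected = np.sqrt(chi2.ppf(0.95, 2))  # ~2.4477
    np.testing.assert_allclose(ellipses["g"].semi_axes, expected, rtol=1e-8)


def test_degenerate_group_warns_with_zero_axes():
    pts = np.ones((5, 2))
    with pytest.warns(UserWarning):
        ellipses = group_ellipse(pts, ["g"] * 5)
    np.testing.assert_allclose(ellipses["g"].semi_axes, 0.0, atol=1e-12)


def test_ellipse_coverage_near_level():
    rng = np.random.default_rng(7)
    cov = np.array([[4.0, 1.2], [1.2, 1.0]])
    pts = rng.multivariate_normal([1.0, -2.0], cov, size=500)
    ellipse = group_ellipse(pts, ["g"] * 500, level=0.95)["g"]
    centered = pts - ellipse.center
    sample_cov = np.cov(pts, rowvar=False)
    d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(sample_cov), centered)
    coverage = (d2 <= chi2.ppf(0.95, 2)).mean()
    assert coverage == pytest.approx(0.95, abs=0.03)
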