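"""Donor-aware classification and PCA of processed feature matrices.

Classification uses gradient-boosted trees (XGBoost) with fixed,
non-optimized hyperparameters under donor-exclusion leave-one-out
cross-validation: every sample is predicted by a model trained with all
samples from its donor removed, so donor identity cannot leak into the
class decision. Accuracy is the percentage of samples whose 0.5-thresholded
out-of-fold probability matches the truth; the ROC curve pools all
out-of-fold probabilities and the AUC is its trapezoidal area.

PCA operates on mean-centered (not variance-scaled) samples x features data;
group spread in the score plane is summarized by normal-probability
concentration ellipses.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import chi2
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve

from .errors import ValidationError
from .matrix import BinnedFeatureMatrix

__all__ = [
    "BoosterHyperparameters",
    "CVResult",
    "PCAResult",
    "GroupEllipse",
    "leave_one_donor_out_splits",
    "run_cv",
    "roc_auc",
    "classification_accuracy",
    "pca_projection",
    "group_ellipse",
]


@dataclass(frozen=True)
class BoosterHyperparameters:
    """Gradient-boosting settings, fixed and not optimized."""

    booster: str = "gbtree"
    objective: str = "binary:logistic"
    eta: float = 0.3
    gamma: float = 0.0
    max_depth: int = 6
    min_child_weight: float = 1.0
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    nrounds: int = 50

    def params(self, seed: int) -> dict:
        p = asdict(self)
        p.pop("nrounds")
        # single-threaded + explicit seed: the determinism contract
        p.update(tree_method="hist", nthread=1, seed=seed)
        return p


@dataclass
class CVResult:
    """Out-of-fold predictions from donor-exclusion LOOCV."""

    table: pd.DataFrame  # sample_id, donor_id, label, prob, pred
    positive_class: str
    negative_class: str
    accuracy: float  # percent correct at the 0.5 threshold
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR
    auc: float
    seed: int
    hyperparameters: BoosterHyperparameters


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # components x features
    sample_ids: list[str]


@dataclass
class GroupEllipse:
    group: str
    center: np.ndarray  # (2,)
    semi_axes: np.ndarray  # (2,) major, minor
    angle_deg: float  # orientation of the major axis
    level: float


def leave_one_donor_out_splits(metadata: pd.DataFrame) -> list[tuple[np.ndarray, int]]:
    """One (train indices, test index) split per sample; the training set
    excludes every sample sharing the test sample's donor."""
    if "donor_id" not in metadata.columns or metadata["donor_id"].isna().any():
        raise ValidationError("donor_id must be present for every sample")
    donors = metadata["donor_id"].to_numpy()
    all_idx = np.arange(len(metadata))
    return [(all_idx[donors != donors[i]], int(i)) for i in all_idx]


def roc_auc(probabilities, labels) -> tuple[np.ndarray, float]:
    """ROC by descending-probability thresholding (ties grouped) and its
    trapezoidal area, equal to P(score_pos > score_neg) + 0.5 P(equal)."""
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(probabilities, dtype=float)
    if y.all() or not y.any():
        raise ValidationError("ROC requires at least one positive and one negative")
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def run_cv(
    matrix: BinnedFeatureMatrix,
    labels,
    metadata: pd.DataFrame,
    hyperparameters: BoosterHyperparameters | None = None,
    seed: int = 0,
    positive_class: str | None = None,
) -> CVResult:
    """Donor-exclusion LOOCV with gradient-boosted trees.

    ``matrix`` is the top-selected (bins x samples) matrix; it is transposed
    to samples x features for fitting. ``labels`` aligns with
    ``matrix.sample_ids`` and must be binary. Folds sharing a test donor have
    identical training sets, so one model per donor is fitted and used for
    all of that donor's samples; the donor-exclusion invariant is asserted
    for every individual split.
    """
    hp = hyperparameters or BoosterHyperparameters()
    matrix.require_stage("top_selected")
    y_raw = np.asarray(pd.Series(list(labels)).astype(str))
    classes = sorted(set(y_raw))
    if len(classes) != 2:
        raise ValidationError(f"labels must be binary, got {classes}")
    pos = positive_class if positive_class is not None else classes[1]
    if pos not in classes:
        raise ValidationError(f"positive class {pos!r} not among labels {classes}")
    neg = next(c for c in classes if c != pos)

    md = metadata.set_index(metadata["sample_id"].astype(str)).loc[matrix.sample_ids]
    donors = md["donor_id"].to_numpy()
    X = matrix.dense().T  # samples x features
    y = (y_raw == pos).astype(np.float32)
    n = len(matrix.sample_ids)

    splits = leave_one_donor_out_splits(md.reset_index(drop=True))
    for train, test in splits:  # donor-exclusion asserted per split
        assert donors[test] not in set(donors[train])
        assert test not in train

    prob = np.full(n, np.nan)
    params = hp.params(seed)
    for donor in pd.unique(donors):
        test_idx = np.flatnonzero(donors == donor)
        train_idx = np.flatnonzero(donors != donor)
        fold_classes = np.unique(y[train_idx])
        if fold_classes.size < 2:
            raise ValidationError(
                f"training fold for donor {donor!r} contains a single class"
            )
        dtrain = xgb.DMatrix(X[train_idx], label=y[train_idx])
        booster = xgb.train(params, dtrain, num_boost_round=hp.nrounds)
        prob[test_idx] = booster.predict(xgb.DMatrix(X[test_idx]))

    assert not np.isnan(prob).any()  # every sample predicted exactly once
    pred = prob >= 0.5  # ties predicted positive
    correct = pred == y.astype(bool)
    roc_points, auc = roc_auc(prob, y.astype(bool))
    table = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "donor_id": donors,
            "label": y_raw,
            "prob": prob,
            "pred": np.where(pred, pos, neg),
        }
    )
    return CVResult(
        table=table,
        positive_class=pos,
        negative_class=neg,
        accuracy=float(100.0 * correct.mean()),
        roc_points=roc_points,
        auc=auc,
        seed=seed,
        hyperparameters=hp,
    )


def classification_accuracy(result: CVResult) -> float:
    """Percent of samples whose 0.5-thresholded probability matches the
    truth (probabilities exactly 0.5 count as positive predictions)."""
    y = result.table["label"].to_numpy() == result.positive_class
    pred = result.table["prob"].to_numpy() >= 0.5
    return float(100.0 * (pred == y).mean())


def pca_projection(
    matrix: BinnedFeatureMatrix, n_components: int = 2, scale: bool = False
) -> PCAResult:
    """Project samples onto the top principal components.

    Features are mean-centered; set ``scale`` to also divide by the feature
    standard deviation. Component signs follow the
    largest-magnitude-loading-positive convention so plots are reproducible.
    """
    matrix.require_stage("top_selected")
    X = matrix.dense().T.astype(np.float64)
    if X.shape[0] < 3:
        raise ValidationError("PCA requires at least 3 samples")
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for k in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    return PCAResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
        sample_ids=list(matrix.sample_ids),
    )


def group_ellipse(scores: np.ndarray, groups, level: float = 0.95) -> dict[str, GroupEllipse]:
    """Normal-probability concentration ellipse per group in the PC1/PC2
    plane, scaled by the chi-square(2) quantile at ``level``."""
    scores = np.asarray(scores, dtype=float)[:, :2]
    groups = np.asarray(list(groups))
    out: dict[str, GroupEllipse] = {}
    r2 = chi2.ppf(level, df=2)
    for g in pd.unique(groups):
        pts = scores[groups == g]
        if pts.shape[0] < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 samples")
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        eigvals = np.clip(eigvals, 0.0, None)[::-1]
        eigvecs = eigvecs[:, ::-1]
        if eigvals[-1] <= 0:
            warnings.warn(f"group {g!r}: degenerate score covariance", stacklevel=2)
        semi = np.sqrt(eigvals * r2)
        angle = float(np.degrees(np.arctan2(eigvecs[1, 0], eigvecs[0, 0])))
        out[str(g)] = GroupEllipse(str(g), center, semi, angle, level)
    return out
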