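"""Diagnostic model training and ROC-based evaluation.

The classifier is a radial-kernel C-support-vector machine over
log2-transformed, per-feature standardised ratio features, with risk scores
obtained by Platt scaling (a sigmoid fitted to cross-validated decision
values), so that every sample receives a calibrated probability of disease
in [0, 1].  All fitted quantities — transform statistics, support
coefficients, kernel width, sigmoid parameters, operating threshold — are
learned on training data only and are plain arrays, so models serialise to
JSON and re-score identically after a round-trip.

Evaluation follows the usual diagnostic conventions: ROC over all score
thresholds with the midrank tie convention (so the trapezoidal AUC equals
the Mann-Whitney concordance probability), and sensitivity/specificity at
an operating threshold chosen on the training data, by default the maximiser
of Youden's J = sensitivity + specificity - 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .features import LOG2_EPSILON, FeatureMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# train/test split

@dataclass
class SplitConfig:
    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_train_test(
    features: FeatureMatrix, config: SplitConfig
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified, seed-reproducible split (e.g. 100 balanced -> 75/25)."""
    labels = features.labels
    for cls in np.unique(labels):
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples; cannot split")
    idx = np.arange(len(labels))
    tr, te = train_test_split(
        idx,
        train_size=config.train_fraction,
        stratify=labels if config.stratified else None,
        random_state=config.seed,
        shuffle=True,
    )
    tr, te = np.sort(tr), np.sort(te)

    def take(rows: np.ndarray) -> FeatureMatrix:
        return FeatureMatrix(
            values=features.values.iloc[rows],
            features=features.features,
            metadata=features.metadata.iloc[rows],
        )

    return take(tr), take(te)


# ---------------------------------------------------------------------------
# model

@dataclass
class ModelBundle:
    """Fitted classifier with its feature transform, fully array-backed."""

    markers: list[str]
    log2_eps: float
    center: np.ndarray          # per-marker mean of log2 values (training)
    scale: np.ndarray           # per-marker std of log2 values (training)
    gamma: float                # numeric RBF width
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    platt_a: float              # risk = sigmoid(platt_a * decision + platt_b)
    platt_b: float
    threshold: float = 0.5
    C: float = 1.0

    def transform(self, values: pd.DataFrame) -> np.ndarray:
        missing = [m for m in self.markers if m not in values.columns]
        if missing:
            raise ValueError(f"missing marker column(s): {missing}")
        X = np.log2(values[self.markers].to_numpy(dtype=float) + self.log2_eps)
        return (X - self.center) / self.scale


@dataclass
class EvalReport:
    sensitivity: float
    specificity: float
    auc: float
    roc_points: list[tuple[float, float]]
    n_control: int
    n_disease: int
    threshold: float

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "n_control": self.n_control,
            "n_disease": self.n_disease,
            "threshold": self.threshold,
            "roc_points": [[float(f), float(t)] for f, t in self.roc_points],
        }


@dataclass
class LearningCurve:
    sizes: list[int]
    train_scores: list[float]
    cv_scores: list[float]


def _as_values(data) -> pd.DataFrame:
    return data.values if isinstance(data, FeatureMatrix) else data


def train_model(
    train,
    labels: np.ndarray | None = None,
    C: float = 1.0,
    threshold_policy: str = "youden",
    calibration_folds: int = 5,
    seed: int = 0,
    log2_eps: float = LOG2_EPSILON,
) -> ModelBundle:
    """Fit log2 -> z-score -> RBF-SVC with Platt-calibrated risk scores.

    ``train`` may be a FeatureMatrix (labels taken from metadata) or a
    DataFrame of feature columns with ``labels`` supplied.  Constant
    features are dropped with a warning.  The operating threshold is fixed
    here, on training data: the Youden-J-optimal risk score by default, or
    0.5 with ``threshold_policy="fixed"``.
    """
    values = _as_values(train)
    y = np.asarray(train.labels if labels is None else labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    X = np.log2(values.to_numpy(dtype=float) + log2_eps)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = list(values.columns[~keep])
        logger.warning("dropping constant feature(s): %s", dropped)
    if not keep.any():
        raise ValueError("all features are constant after transform")
    markers = list(values.columns[keep])
    X = X[:, keep]
    center, scale = X.mean(axis=0), X.std(axis=0)
    Z = (X - center) / scale

    svc = SVC(kernel="rbf", C=C, gamma="scale", random_state=seed)
    svc.fit(Z, y)

    # Platt scaling on out-of-fold decision values where the data allow it
    min_class = min(np.bincount(y.astype(int))[np.unique(y.astype(int))])
    folds = min(calibration_folds, int(min_class))
    if folds >= 2:
        d_cal = np.empty(len(y))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr_idx, te_idx in skf.split(Z, y):
            fold_svc = SVC(kernel="rbf", C=C, gamma="scale", random_state=seed)
            fold_svc.fit(Z[tr_idx], y[tr_idx])
            d_cal[te_idx] = fold_svc.decision_function(Z[te_idx])
    else:
        d_cal = svc.decision_function(Z)
    if np.ptp(d_cal) == 0:
        platt_a, platt_b = 1.0, 0.0
    else:
        lr = LogisticRegression(C=1e6)
        lr.fit(d_cal.reshape(-1, 1), y)
        platt_a, platt_b = float(lr.coef_[0, 0]), float(lr.intercept_[0])

    bundle = ModelBundle(
        markers=markers,
        log2_eps=log2_eps,
        center=center,
        scale=scale,
        gamma=float(svc._gamma),
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        platt_a=platt_a,
        platt_b=platt_b,
        C=C,
    )
    train_scores = risk_score(bundle, values)
    if threshold_policy == "youden":
        bundle.threshold = youden_threshold(train_scores, y)
    elif threshold_policy == "fixed":
        bundle.threshold = 0.5
    else:
        raise ValueError(f"unknown threshold_policy {threshold_policy!r}")
    return bundle


def decision_values(bundle: ModelBundle, values: pd.DataFrame) -> np.ndarray:
    """RBF decision function from the stored support coefficients."""
    Z = bundle.transform(values)
    sq = ((Z[:, None, :] - bundle.support_vectors[None, :, :]) ** 2).sum(axis=-1)
    K = np.exp(-bundle.gamma * sq)
    return K @ bundle.dual_coef + bundle.intercept


def risk_score(bundle: ModelBundle, samples) -> np.ndarray:
    """Calibrated probability of disease, in [0, 1], monotone in the margin."""
    d = decision_values(bundle, _as_values(samples))
    return 1.0 / (1.0 + np.exp(-(bundle.platt_a * d + bundle.platt_b)))


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score threshold maximising sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    t = float(thr[best])
    return min(t, 1.0)  # roc_curve's leading threshold is inf


def evaluate(
    bundle: ModelBundle,
    data,
    labels: np.ndarray | None = None,
    threshold: float | None = None,
) -> EvalReport:
    """ROC/AUC plus sensitivity/specificity at the frozen operating point.

    Positive calls are ``score >= threshold``; the threshold defaults to
    the one chosen during training and is never re-optimised here.
    """
    values = _as_values(data)
    y = np.asarray(data.labels if labels is None else labels)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation data must contain both classes (AUC undefined)")
    scores = risk_score(bundle, values)
    return score_report(scores, y, threshold=bundle.threshold if threshold is None else threshold)


def score_report(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> EvalReport:
    """EvalReport from raw scores (trapezoidal AUC, midrank ties)."""
    y = np.asarray(labels)
    fpr, tpr, _ = roc_curve(y, scores)
    area = float(_trapezoid_auc(fpr, tpr))
    pred = scores >= threshold
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float((~pred[neg]).mean()) if neg.any() else float("nan")
    return EvalReport(
        sensitivity=sens,
        specificity=spec,
        auc=area,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        n_control=int(neg.sum()),
        n_disease=int(pos.sum()),
        threshold=float(threshold),
    )


def cv_auc(
    values: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    folds: int = 5,
    seed: int = 0,
    metric: str = "cv_auc",
    log2_eps: float = LOG2_EPSILON,
) -> float:
    """Mean stratified cross-validated AUC (or accuracy) of the SVC pipeline.

    The workhorse behind genetic-algorithm fitness: log2 -> z-score (fold
    training statistics) -> RBF-SVC, scored on each held-out fold by the
    ROC AUC of the decision values (or accuracy of the sign).
    """
    X = np.log2(np.asarray(values, dtype=float) + log2_eps)
    y = np.asarray(labels)
    folds = min(folds, int(min(np.bincount(y.astype(int))[np.unique(y.astype(int))])))
    if folds < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Ztr, Zte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        svc = SVC(kernel="rbf", C=C, gamma="scale", random_state=seed)
        svc.fit(Ztr, y[tr])
        d = svc.decision_function(Zte)
        if metric == "cv_auc":
            scores.append(roc_auc_score(y[te], d))
        elif metric == "cv_accuracy":
            scores.append(float(((d >= 0).astype(int) == y[te]).mean()))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return float(np.mean(scores))


def learning_curve_report(
    train,
    labels: np.ndarray | None = None,
    sizes: list[int] | None = None,
    C: float = 1.0,
    folds: int = 5,
    seed: int = 0,
) -> LearningCurve:
    """Train vs cross-validation AUC at increasing training sizes.

    Diagnoses overfitting: a persistent gap between the training score and
    the cross-validation score that does not close with more samples.
    """
    values = _as_values(train)
    y = np.asarray(train.labels if labels is None else labels)
    n = len(y)
    if sizes is None:
        sizes = [max(4, int(f * n)) for f in (0.3, 0.5, 0.7, 1.0)]
    rng = np.random.default_rng(seed)
    out_sizes, tr_scores, cv_scores = [], [], []
    for size in sorted(set(min(s, n) for s in sizes)):
        idx = _stratified_subsample(y, size, rng)
        ys = y[idx]
        if min(np.bincount(ys.astype(int), minlength=2)[np.unique(ys.astype(int))]) < 2:
            logger.warning("learning curve size %d leaves a class nearly empty; skipped", size)
            continue
        sub = values.iloc[idx]
        cv = cv_auc(sub, ys, C=C, folds=folds, seed=seed)
        bundle = train_model(sub, ys, C=C, threshold_policy="fixed", seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr = score_report(risk_score(bundle, sub), ys).auc
        out_sizes.append(size)
        tr_scores.append(float(tr))
        cv_scores.append(float(cv))
    return LearningCurve(sizes=out_sizes, train_scores=tr_scores, cv_scores=cv_scores)


def _stratified_subsample(y: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-proportional subsample of the requested size."""
    idx = []
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        take = max(1, int(round(size * cnt / len(y))))
        members = np.flatnonzero(y == cls)
        idx.append(rng.choice(members, size=min(take, cnt), replace=False))
    return np.sort(np.concatenate(idx))
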