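"""Hold-out evaluation of a diagnostic classifier over a marker panel.

A stratified 70/30 split (technical replicates never straddle the
split) repeated over several random states; per-state AUC, sensitivity,
specificity and accuracy plus their arithmetic mean. The classifier is
a pluggable contract — any scikit-learn-style estimator emitting a
case probability — with a standardized, regularized logistic regression
as the reference model. The operating threshold is Youden-optimal on
the training scores and frozen for the test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import InputError
from .synthetic import QuantMatrix

CLASSIFIER_REGISTRY = {
    "logistic": lambda params: LogisticRegression(max_iter=2000, **params),
    "random_forest": lambda params: RandomForestClassifier(**params),
}


@dataclass(frozen=True)
class EvalConfig:
    train_fraction: float = 0.7
    random_states: tuple[int, ...] = (1, 2, 3, 4, 5)
    stratified: bool = True
    classifier: str = "logistic"
    classifier_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise InputError("train_fraction must be in (0, 1)")
        if len(self.random_states) < 1:
            raise InputError("need at least one random state")
        if self.classifier not in CLASSIFIER_REGISTRY:
            raise InputError(f"unknown classifier {self.classifier!r}")


@dataclass
class EvalResult:
    random_state: int
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold_used: float


def split_holdout(
    labels: pd.Series,
    replicate_of: pd.Series,
    cfg: EvalConfig,
    state: int,
) -> tuple[list, list]:
    """Stratified train/test split at the biological-sample level.

    ``labels`` and ``replicate_of`` are indexed by measurement
    (replicate) id; the split is drawn over unique biological parents so
    replicates of one sample always land in the same partition. Returns
    (train_ids, test_ids) of measurement ids, deterministic per state.
    """
    bio = pd.DataFrame({"label": labels, "parent": replicate_of})
    per_parent = bio.groupby("parent")["label"].first()
    classes = per_parent.unique()
    if len(classes) < 2:
        raise InputError("both classes must be present")
    rng = np.random.default_rng(state)
    train_parents: list = []
    test_parents: list = []
    groups = (
        [per_parent.index[per_parent == c] for c in sorted(classes)]
        if cfg.stratified
        else [per_parent.index]
    )
    for idx in groups:
        idx = np.array(sorted(idx))
        if idx.size < 2:
            raise InputError("need >= 2 biological samples per class")
        perm = rng.permutation(idx.size)
        n_train = int(round(cfg.train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_parents.extend(idx[perm[:n_train]])
        test_parents.extend(idx[perm[n_train:]])
    train_set, test_set = set(train_parents), set(test_parents)
    train_ids = [i for i in labels.index if bio.loc[i, "parent"] in train_set]
    test_ids = [i for i in labels.index if bio.loc[i, "parent"] in test_set]
    return train_ids, test_ids


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str = "logistic",
    params: dict | None = None,
):
    """Fit the pluggable classifier on standardized features.

    Zero-variance features are dropped with a warning before fitting.
    Returns a fitted pipeline exposing predict_proba.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature(s)",
            stacklevel=2,
        )
    if not keep.any():
        raise InputError("all features have zero variance")
    model = CLASSIFIER_REGISTRY[classifier](dict(params or {}))
    pipe = Pipeline(
        [
            ("select", _ColumnKeeper(keep)),
            ("scale", StandardScaler()),
            ("clf", model),
        ]
    )
    pipe.fit(X, y)
    return pipe


class _ColumnKeeper:
    """Minimal transformer dropping pre-identified zero-variance columns."""

    def __init__(self, keep: np.ndarray):
        self.keep = np.asarray(keep, dtype=bool)

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.keep]

    def fit_transform(self, X, y=None):
        return self.transform(X)

    def get_params(self, deep=True):
        return {"keep": self.keep}

    def set_params(self, **params):
        self.keep = params.get("keep", self.keep)
        return self


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Operating threshold maximizing sensitivity + specificity - 1."""
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    return float(thresholds[int(np.argmax(j))])


def roc_metrics(
    scores, labels, threshold: float | None = None
) -> dict[str, float]:
    """AUC plus sensitivity/specificity/accuracy at an operating point.

    AUC follows the rank-statistic identity AUC = U/(n1*n0) (ties count
    one half), equivalent to trapezoidal integration of the ROC curve.
    When no threshold is given, the Youden-optimal one on these scores
    is used (callers evaluating held-out data should pass the threshold
    frozen from training).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise InputError("both classes must be present for ROC metrics")
    auc = float(roc_auc_score(labels, scores))
    if threshold is None:
        threshold = youden_threshold(scores, labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    return {
        "auc": auc,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / labels.size,
        "threshold_used": float(threshold),
    }


def evaluate_panel(
    matrix: QuantMatrix,
    marker_ids: list[str],
    cfg: EvalConfig = EvalConfig(),
    extra_group_scores: bool = False,
) -> tuple[list[EvalResult], pd.DataFrame]:
    """Hold-out evaluation of the marker panel over all random states.

    Samples whose group is neither case nor control are excluded from
    training and the binary metrics; with ``extra_group_scores`` their
    predicted probabilities are reported per group in the returned
    summary frame's attrs (box-plot analogue for non-target disease
    groups).

    Returns (per-state results, summary table with one row per state
    plus the Average row).
    """
    if not marker_ids:
        raise InputError("marker panel is empty")
    meta = matrix.sample_meta
    binary = meta["group"].isin(["case", "control"])
    labels = (meta.loc[binary, "group"] == "case").astype(int)
    replicate_of = meta.loc[binary, "replicate_of"]
    X_all = matrix.values.loc[binary, marker_ids]

    results: list[EvalResult] = []
    extra_scores: dict[str, list[float]] = {}
    for state in cfg.random_states:
        train_ids, test_ids = split_holdout(labels, replicate_of, cfg, state)
        model = train_classifier(
            X_all.loc[train_ids].to_numpy(),
            labels.loc[train_ids].to_numpy(),
            cfg.classifier,
            cfg.classifier_params,
        )
        train_scores = model.predict_proba(X_all.loc[train_ids].to_numpy())[:, 1]
        thr = youden_threshold(train_scores, labels.loc[train_ids].to_numpy())
        test_scores = model.predict_proba(X_all.loc[test_ids].to_numpy())[:, 1]
        m = roc_metrics(test_scores, labels.loc[test_ids].to_numpy(), thr)
        results.append(EvalResult(random_state=state, **m))
        if extra_group_scores and (~binary).any():
            X_extra = matrix.values.loc[~binary, marker_ids].to_numpy()
            scores = model.predict_proba(X_extra)[:, 1]
            for grp, s in zip(meta.loc[~binary, "group"], scores):
                extra_scores.setdefault(str(grp), []).append(float(s))

    rows = [
        {
            "random_state": r.random_state,
            "specificity": r.specificity,
            "sensitivity": r.sensitivity,
            "auc": r.auc,
            "accuracy": r.accuracy,
        }
        for r in results
    ]
    avg = {
        "random_state": "Average",
        "specificity": float(np.mean([r.specificity for r in results])),
        "sensitivity": float(np.mean([r.sensitivity for r in results])),
        "auc": float(np.mean([r.auc for r in results])),
        "accuracy": float(np.mean([r.accuracy for r in results])),
    }
    summary = pd.DataFrame(rows + [avg])
    if extra_scores:
        summary.attrs["extra_group_scores"] = extra_scores
    return results, summary
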