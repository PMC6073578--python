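"""Training and evaluation protocols for the binary amyloid classifier.

Implements the full metric suite (sensitivity, specificity, accuracy, MCC,
precision, recall, F-measure), hand-rolled ROC/AUC, stratified K-fold
cross-validation, the 80/20 external-validation split, balanced
undersampling, and a paired multi-classifier benchmark.  The random forest
itself is scikit-learn's; everything around it (splits, pooling, metrics)
is computed here so reports are bit-identical for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from .ctd_features import FeatureVector
from .encoders import encode_dataset, get_encoder
from .sequence_io import LabeledDataset, ProteinSequence

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table for the positive (amyloid) class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.TN + other.TN, self.FN + other.FN,
        )


@dataclass(frozen=True)
class Metrics:
    """SE/SP/ACC/MCC/precision/recall/F for one confusion table.

    Metrics whose denominator is zero are reported as 0.0 and listed in
    ``zero_denominator`` so downstream tables never contain NaN.
    """

    SE: float
    SP: float
    ACC: float
    MCC: float
    precision: float
    recall: float
    f_measure: float
    zero_denominator: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = asdict(self)
        d["zero_denominator"] = list(self.zero_denominator)
        return d


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Evaluate the seven standard metrics on a confusion table."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on an all-zero confusion table")
    flags: list[str] = []
    tp, fp, tn, fn = float(c.TP), float(c.FP), float(c.TN), float(c.FN)
    se = _safe_div(tp, tp + fn, "SE", flags)
    sp = _safe_div(tn, tn + fp, "SP", flags)
    acc = (tp + tn) / c.total
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC", flags)
    precision = _safe_div(tp, tp + fp, "precision", flags)
    recall = se
    f = _safe_div(2 * precision * recall, precision + recall, "f_measure", flags)
    return Metrics(se, sp, acc, mcc, precision, recall, f, tuple(flags))


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_curve(scores: Sequence[float], y: Sequence[int]) -> tuple[list[tuple[float, float]], float]:
    """(FPR, TPR) points from a threshold sweep over unique scores, plus
    trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if len(scores) != len(y):
        raise ValueError("scores and labels must be aligned")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last point of each tied-score run
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters: m trees, k features per split,
    bootstrap resample size n."""

    n_trees: int = 500
    features_per_split: int | str = "sqrt"
    bootstrap_sample_size: int | None = None  # None = training-set size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def build(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.features_per_split,
            max_samples=self.bootstrap_sample_size,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )


def train_random_forest(
    X: np.ndarray | pd.DataFrame, y: Sequence[int], cfg: ForestConfig | None = None
) -> RandomForestClassifier:
    """Fit a seeded random forest; majority vote for class, vote fraction for
    probability."""
    cfg = cfg or ForestConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match len(y)")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    model = cfg.build()
    model.fit(X, y)
    return model


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    metrics: Metrics
    test_indices: list[int]


@dataclass
class EvalReport:
    """Per-fold and pooled evaluation results plus ROC."""

    per_fold: list[FoldResult]
    aggregate_counts: ConfusionCounts
    aggregate_metrics: Metrics
    roc: list[tuple[float, float]]
    auc: float
    fold_mean_metrics: dict[str, float]
    seed: int
    protocol: str

    def __post_init__(self) -> None:
        pooled = ConfusionCounts(0, 0, 0, 0)
        for fr in self.per_fold:
            pooled = pooled + fr.counts
        if pooled != self.aggregate_counts:
            raise ValueError("aggregate counts must equal the sum of per-fold counts")

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "seed": self.seed,
            "aggregate_counts": asdict(self.aggregate_counts),
            "aggregate_metrics": self.aggregate_metrics.as_dict(),
            "fold_mean_metrics": self.fold_mean_metrics,
            "auc": self.auc,
            "per_fold": [
                {
                    "fold": fr.fold,
                    "counts": asdict(fr.counts),
                    "metrics": fr.metrics.as_dict(),
                    "test_indices": fr.test_indices,
                }
                for fr in self.per_fold
            ],
            "roc": self.roc,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def roc_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.roc, columns=["FPR", "TPR"]).to_csv(path, sep="\t", index=False)


_METRIC_KEYS = ("SE", "SP", "ACC", "MCC", "precision", "recall", "f_measure")


def _build_report(
    fold_results: list[FoldResult],
    scores: np.ndarray,
    y: np.ndarray,
    seed: int,
    protocol: str,
) -> EvalReport:
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fr in fold_results:
        pooled = pooled + fr.counts
    roc, auc = roc_curve(scores, y)
    fold_means = {
        k: float(np.mean([getattr(fr.metrics, k) for fr in fold_results]))
        for k in _METRIC_KEYS
    }
    return EvalReport(
        per_fold=fold_results,
        aggregate_counts=pooled,
        aggregate_metrics=compute_metrics(pooled),
        roc=roc,
        auc=auc,
        fold_mean_metrics=fold_means,
        seed=seed,
        protocol=protocol,
    )


def _resolve_classifier(classifier, seed: int) -> BaseEstimator:
    if classifier is None:
        return ForestConfig(seed=seed).build()
    if isinstance(classifier, ForestConfig):
        cfg = ForestConfig(
            classifier.n_trees, classifier.features_per_split,
            classifier.bootstrap_sample_size, seed,
        )
        return cfg.build()
    est = clone(classifier)
    if "random_state" in est.get_params():
        est.set_params(random_state=seed)
    return est


def kfold_cv(
    dataset: LabeledDataset,
    encoder: str | Callable[[ProteinSequence], FeatureVector] = "188d+pse",
    classifier: BaseEstimator | ForestConfig | None = None,
    K: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified K-fold cross-validation; per-fold and pooled metrics."""
    if K < 2:
        raise ValueError("K must be >= 2")
    y = np.asarray(dataset.labels)
    n_min_class = min(int(np.sum(y == 1)), int(np.sum(y == 0)))
    if n_min_class < K:
        raise ValueError(
            f"smallest class has {n_min_class} members < K = {K}; use K <= {n_min_class}"
        )
    X = encode_dataset(dataset.sequences, encoder).to_numpy()
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    fold_results: list[FoldResult] = []
    oof_scores = np.zeros(len(y))
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        est = _resolve_classifier(classifier, seed)
        est.fit(X[train_idx], y[train_idx])
        scores = _positive_scores(est, X[test_idx])
        preds = (scores >= 0.5).astype(int) if hasattr(est, "predict_proba") else est.predict(X[test_idx])
        counts = confusion_from_predictions(y[test_idx], preds)
        fold_results.append(
            FoldResult(fold, counts, compute_metrics(counts), [int(i) for i in test_idx])
        )
        oof_scores[test_idx] = scores
    return _build_report(fold_results, oof_scores, y, seed, f"{K}-fold-cv")


def _positive_scores(est: BaseEstimator, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        pos_col = list(est.classes_).index(1)
        return proba[:, pos_col]
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return est.predict(X).astype(float)


def external_split_eval(
    dataset: LabeledDataset,
    encoder: str | Callable[[ProteinSequence], FeatureVector] = "188d+pse",
    classifier: BaseEstimator | ForestConfig | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> EvalReport:
    """Single stratified train/test split; metrics on the held-out fraction."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    y = np.asarray(dataset.labels)
    X = encode_dataset(dataset.sequences, encoder).to_numpy()
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed
    )
    if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
        raise ValueError("degenerate split: a partition lacks one of the classes")
    est = _resolve_classifier(classifier, seed)
    est.fit(X[train_idx], y[train_idx])
    scores = _positive_scores(est, X[test_idx])
    preds = (scores >= 0.5).astype(int) if hasattr(est, "predict_proba") else est.predict(X[test_idx])
    counts = confusion_from_predictions(y[test_idx], preds)
    fold = FoldResult(0, counts, compute_metrics(counts), [int(i) for i in test_idx])
    return _build_report([fold], scores, y[test_idx], seed, f"external-{train_fraction:.0%}")


def balance_dataset(dataset: LabeledDataset, mode: str = "undersample", seed: int = 0) -> LabeledDataset:
    """Randomly undersample the majority class to the minority-class size."""
    if mode != "undersample":
        raise ValueError(f"unknown balance mode {mode!r}")
    y = np.asarray(dataset.labels)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("balancing requires both classes present")
    rng = np.random.default_rng(seed)
    if len(pos_idx) > len(neg_idx):
        pos_idx = np.sort(rng.choice(pos_idx, size=len(neg_idx), replace=False))
    elif len(neg_idx) > len(pos_idx):
        neg_idx = np.sort(rng.choice(neg_idx, size=len(pos_idx), replace=False))
    keep = np.sort(np.concatenate([pos_idx, neg_idx]))
    return dataset.subset([int(i) for i in keep], name=f"{dataset.name}-balanced")


def classifier_bench(
    dataset: LabeledDataset,
    encoder: str | Callable[[ProteinSequence], FeatureVector],
    classifiers: dict[str, BaseEstimator | ForestConfig],
    K: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Run every classifier on identical stratified folds; one row per
    classifier.  A failing classifier yields a row with status='failed'."""
    rows = []
    for name, clf in classifiers.items():
        try:
            report = kfold_cv(dataset, encoder, clf, K=K, seed=seed)
            m = report.aggregate_metrics
            rows.append(
                {
                    "classifier": name, "status": "ok",
                    "ACC": m.ACC, "MCC": m.MCC, "SE": m.SE, "SP": m.SP,
                    "F-measure": m.f_measure, "AUC": report.auc,
                }
            )
        except Exception as exc:  # noqa: BLE001 - bench must keep going
            rows.append(
                {
                    "classifier": name, "status": f"failed: {exc}",
                    "ACC": np.nan, "MCC": np.nan, "SE": np.nan, "SP": np.nan,
                    "F-measure": np.nan, "AUC": np.nan,
                }
            )
    return pd.DataFrame(rows).set_index("classifier")


def default_bench_classifiers(seed: int = 0) -> dict[str, BaseEstimator | ForestConfig]:
    """Off-the-shelf comparison classifiers for the benchmark table."""
    from sklearn.ensemble import (
        AdaBoostClassifier, BaggingClassifier, ExtraTreesClassifier,
        GradientBoostingClassifier,
    )
    from sklearn.linear_model import LogisticRegression, SGDClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC, LinearSVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "RandomForest": ForestConfig(seed=seed),
        "NaiveBayes": GaussianNB(),
        "SGD": SGDClassifier(random_state=seed),
        "NearestNeighbors": KNeighborsClassifier(),
        "DecisionTree": DecisionTreeClassifier(random_state=seed),
        "LinearSVC": LinearSVC(random_state=seed),
        "LogisticRegression": LogisticRegression(max_iter=2000, random_state=seed),
        "SVC": SVC(probability=True, random_state=seed),
        "ExtraTrees": ExtraTreesClassifier(random_state=seed),
        "Bagging": BaggingClassifier(random_state=seed),
        "AdaBoost": AdaBoostClassifier(random_state=seed),
        "GradientBoosting": GradientBoostingClassifier(random_state=seed),
    }


def save_model(model: BaseEstimator, encoder_name: str, path: str | Path) -> None:
    joblib.dump(
        {"format_version": MODEL_FORMAT_VERSION, "encoder": encoder_name, "model": model},
        path,
    )


def load_model(path: str | Path) -> tuple[BaseEstimator, str]:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return payload["model"], payload["encoder"]
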