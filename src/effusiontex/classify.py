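"""k-nearest-neighbor discrimination of the two effusion classes.

Features are standardized to zero mean / unit population SD, distances are
Euclidean, and validation is leave-one-out: each sample is classified by the
majority label of its k nearest neighbors among all other samples (k = 1 by
default).  Distance ties break by sample order, vote ties by the benign
(negative) label.  The report carries the confusion matrix with the
malignant class as positive, and accuracy / sensitivity / specificity in
percent with exact (Clopper-Pearson) 95% binomial confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta

from .selection import feature_matrix

__all__ = [
    "ClassifierConfig",
    "RateWithCI",
    "ClassifierReport",
    "standardize",
    "knn_loocv",
    "clopper_pearson",
    "confusion_metrics",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """k-NN configuration; validation is leave-one-out."""

    k: int = 1
    positive_label: str = "malignant"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")


@dataclass
class RateWithCI:
    """A proportion in percent with its exact 95% CI (percent)."""

    percent: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    def to_dict(self) -> dict:
        return {
            "percent": self.percent,
            "ci95": [self.ci_low, self.ci_high],
            "fraction": f"{self.numerator}/{self.denominator}",
        }


@dataclass
class ClassifierReport:
    """Confusion matrix (positive = malignant) and derived rates."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: RateWithCI
    sensitivity: RateWithCI | None
    specificity: RateWithCI | None
    predictions: list[str] = field(default_factory=list)
    misclassified: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": {"TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp},
            "accuracy": self.accuracy.to_dict(),
            "sensitivity": self.sensitivity.to_dict() if self.sensitivity else None,
            "specificity": self.specificity.to_dict() if self.specificity else None,
            "misclassified": self.misclassified,
        }


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each feature column to mean 0, population SD 1.

    Zero-SD (constant) features are dropped with a warning; sample_id/label
    columns pass through untouched.
    """
    out = table.copy()
    feat_cols = [c for c in table.columns if c not in ("sample_id", "label")]
    kept = []
    for c in feat_cols:
        v = out[c].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            warnings.warn(f"dropping zero-variance feature {c!r}", stacklevel=2)
            out = out.drop(columns=[c])
            continue
        out[c] = (v - v.mean()) / sd
        kept.append(c)
    if not kept:
        raise ValueError("all features have zero variance")
    return out


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI for a proportion, as fractions in [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    low = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _rate(x: int, n: int) -> RateWithCI:
    low, high = clopper_pearson(x, n)
    return RateWithCI(
        percent=100.0 * x / n, ci_low=100.0 * low, ci_high=100.0 * high,
        numerator=x, denominator=n,
    )


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, RateWithCI | None]:
    """Accuracy, sensitivity and specificity with exact 95% CIs.

    Sensitivity is the true-positive rate TP/(TP+FN), specificity the
    true-negative rate TN/(TN+FP); a rate with an empty margin is None.
    """
    for v in (tp, fn, tn, fp):
        if v < 0 or int(v) != v:
            raise ValueError("confusion counts must be nonnegative integers")
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion matrix")
    return {
        "accuracy": _rate(tp + tn, n),
        "sensitivity": _rate(tp, tp + fn) if tp + fn > 0 else None,
        "specificity": _rate(tn, tn + fp) if tn + fp > 0 else None,
    }


def knn_loocv(
    table: pd.DataFrame,
    feature_names: list[str] | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> ClassifierReport:
    """Leave-one-out k-NN classification of a feature table.

    ``table`` needs a ``label`` column (and optionally ``sample_id``);
    ``feature_names`` restricts to a selected set.  Features are
    standardized before computing Euclidean distances.
    """
    feats, labels = feature_matrix(table)
    if feature_names is not None:
        missing = [f for f in feature_names if f not in feats.columns]
        if missing:
            raise KeyError(f"selected features absent from table: {missing}")
        feats = feats[list(feature_names)]
    n = len(feats)
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    if config.k >= n:
        raise ValueError(f"k={config.k} must be smaller than n={n}")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    pos = config.positive_label
    if pos not in classes:
        raise ValueError(f"positive label {pos!r} not present in table")
    neg = classes[classes != pos][0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = standardize(pd.DataFrame(feats))
    X = std.to_numpy(dtype=float)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)

    sample_ids = (
        table["sample_id"].astype(str).tolist()
        if "sample_id" in table.columns
        else [f"s{i:03d}" for i in range(n)]
    )
    predictions: list[str] = []
    for i in range(n):
        order = np.argsort(d2[i], kind="stable")  # distance ties -> sample order
        votes = labels[order[: config.k]]
        n_pos = int((votes == pos).sum())
        n_neg = config.k - n_pos
        predictions.append(pos if n_pos > n_neg else neg)  # vote tie -> benign

    pred = np.array(predictions)
    is_pos = labels == pos
    tp = int(((pred == pos) & is_pos).sum())
    fn = int(((pred != pos) & is_pos).sum())
    tn = int(((pred != pos) & ~is_pos).sum())
    fp = int(((pred == pos) & ~is_pos).sum())
    rates = confusion_metrics(tp, fn, tn, fp)
    return ClassifierReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        accuracy=rates["accuracy"],
        sensitivity=rates["sensitivity"],
        specificity=rates["specificity"],
        predictions=predictions,
        misclassified=[sid for sid, p, t in zip(sample_ids, pred, labels) if p != t],
    )
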