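"""Feature selection: Fisher coefficient ranking and greedy POE+ACC.

Two ten-feature sets are drawn from the full feature table, mirroring the
reduction step of the MaZda/B11 workflow:

* the Fisher coefficient of a feature is the ratio of its between-class to
  its pooled within-class variance (class priors = class frequencies,
  population variances); the top ``n`` features are kept;
* POE+ACC greedily accumulates features minimizing the probability of
  classification error of the best single-feature threshold classifier plus
  the mean absolute Pearson correlation with the features already chosen.

All orderings are deterministic: ties break lexicographically by feature
name.  Features containing non-finite values are excluded from ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureScore",
    "SelectionResult",
    "fisher_coefficient",
    "rank_by_fisher",
    "poe",
    "poe_acc_select",
    "feature_matrix",
]


@dataclass
class FeatureScore:
    """Per-feature selection scores (NaN where a score was not computed)."""

    feature_name: str
    fisher_F: float = np.nan
    poe: float = np.nan
    acc: float = np.nan
    combined: float = np.nan

    def to_dict(self) -> dict:
        return {
            "feature_name": self.feature_name,
            "fisher_F": self.fisher_F,
            "poe": self.poe,
            "acc": self.acc,
            "combined": self.combined,
        }


@dataclass
class SelectionResult:
    """An ordered selected feature set produced by one method."""

    method: str
    scores: list[FeatureScore] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return [s.feature_name for s in self.scores]

    def to_dict(self) -> dict:
        return {"method": self.method, "features": [s.to_dict() for s in self.scores]}


def feature_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a feature table into (features-only frame, label array)."""
    if "label" not in table.columns:
        raise ValueError("feature table must have a 'label' column")
    labels = table["label"].to_numpy()
    feats = table.drop(columns=[c for c in ("sample_id", "label") if c in table.columns])
    return feats, labels


def _two_class_split(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, found {classes.size}")
    return values[labels == classes[0]], values[labels == classes[1]]


def fisher_coefficient(values: np.ndarray, labels: np.ndarray) -> float:
    """Between-class over pooled within-class variance of one feature.

    F = sum_k P_k (mu_k - mu)^2 / sum_k P_k sigma_k^2 with class priors P_k
    equal to class frequencies and population variances.  A zero pooled
    within-class variance yields +inf for unequal means and 0 for equal ones.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature values must be finite")
    a, b = _two_class_split(values, np.asarray(labels))
    n = values.size
    pa, pb = a.size / n, b.size / n
    mu = values.mean()
    between = pa * (a.mean() - mu) ** 2 + pb * (b.mean() - mu) ** 2
    within = pa * a.var() + pb * b.var()
    if within == 0.0:
        return float("inf") if between > 0 else 0.0
    return float(between / within)


def poe(values: np.ndarray, labels: np.ndarray) -> float:
    """Probability of classification error of the best threshold classifier.

    Thresholds are placed at midpoints of sorted unique values; both
    polarities and the trivial majority classifier compete.  The result is
    the resubstitution misclassification fraction, so a constant feature
    yields min(P1, P2) and a separable one yields 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, found {classes.size}")
    y = labels == classes[1]
    n = values.size
    best = min(y.sum(), n - y.sum()) / n  # majority classifier
    uniq = np.unique(values)
    if uniq.size > 1:
        thresholds = (uniq[:-1] + uniq[1:]) / 2.0
        above = values[None, :] > thresholds[:, None]
        # polarity 1: predict class-1 above the threshold
        err1 = ((above != y[None, :]).sum(axis=1)) / n
        best = min(best, float(err1.min()), float((1 - err1).min()))
    return float(best)


def rank_by_fisher(table: pd.DataFrame, n: int = 10) -> SelectionResult:
    """Top-n features by descending Fisher coefficient (ties by name)."""
    feats, labels = feature_matrix(table)
    scores = []
    for name in feats.columns:
        col = feats[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            continue
        scores.append((fisher_coefficient(col, labels), name))
    if not scores:
        raise ValueError("no finite-valued feature to rank")
    if len(scores) < n:
        warnings.warn(f"only {len(scores)} finite features available; returning all", stacklevel=2)
        n = len(scores)
    scores.sort(key=lambda t: (-t[0], t[1]))
    return SelectionResult(
        method="fisher",
        scores=[FeatureScore(name, fisher_F=f) for f, name in scores[:n]],
    )


def poe_acc_select(table: pd.DataFrame, n: int = 10) -> SelectionResult:
    """Greedy POE+ACC forward selection (unit weights, ties by name).

    The first feature minimizes POE; each next feature minimizes
    POE(f) + mean |Pearson r| with the already-selected features.  An
    undefined correlation (constant feature) contributes 0.
    """
    feats, labels = feature_matrix(table)
    usable = [c for c in feats.columns if np.all(np.isfinite(feats[c].to_numpy(dtype=float)))]
    if not usable:
        raise ValueError("no finite-valued feature to select")
    if len(usable) < n:
        warnings.warn(f"only {len(usable)} finite features available; returning all", stacklevel=2)
        n = len(usable)

    X = feats[usable].to_numpy(dtype=float)
    poe_by = {name: poe(X[:, i], labels) for i, name in enumerate(usable)}
    col = {name: X[:, i] for i, name in enumerate(usable)}

    def abs_corr(u: np.ndarray, v: np.ndarray) -> float:
        su, sv = u.std(), v.std()
        if su == 0 or sv == 0:
            return 0.0
        r = np.corrcoef(u, v)[0, 1]
        return float(abs(r))

    selected: list[FeatureScore] = []
    remaining = sorted(usable)
    while len(selected) < n:
        best_name, best_score, best_acc = None, np.inf, np.nan
        for name in remaining:
            if selected:
                acc = float(np.mean([abs_corr(col[name], col[s.feature_name]) for s in selected]))
            else:
                acc = 0.0
            score = poe_by[name] + acc
            if score < best_score:  # remaining is name-sorted, so first win = lexicographic tie-break
                best_name, best_score, best_acc = name, score, acc
        selected.append(
            FeatureScore(best_name, poe=poe_by[best_name], acc=best_acc, combined=best_score)
        )
        remaining.remove(best_name)
    return SelectionResult(method="poe_acc", scores=selected)
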