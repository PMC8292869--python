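"""Univariate inference: Mann-Whitney comparison and ROC analysis.

The Mann-Whitney U statistic is computed from midranks; two-sided p-values
are exact (full enumeration) for combined samples of at most 12 without
ties, and otherwise use the normal approximation with tie and continuity
corrections.  The ROC area is the rank identity AUC = U / (n1 n2) — the
probability that a random malignant value exceeds a random benign one, ties
counted half — with a DeLong standard error for the 95% CI and the test
against AUC = 0.5.  The operating point maximizes the Youden index
J = sensitivity + specificity - 1 over observed thresholds with the
"> cutoff => positive" rule; J-ties resolve toward higher specificity.

Selected features are screened with a Bonferroni-corrected threshold: with
two ten-feature sets the correction counts all 20 tests (0.05 / 20 =
0.0025) even when the sets overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .classify import clopper_pearson
from .selection import SelectionResult, feature_matrix

__all__ = [
    "UnivariateResult",
    "RocResult",
    "mann_whitney",
    "bonferroni_threshold",
    "auc_from_ranks",
    "roc_analysis",
    "univariate_screen",
]

EXACT_ENUMERATION_LIMIT = 12


@dataclass
class RocResult:
    """ROC summary for one feature (positive class = malignant)."""

    auc: float
    ci95: tuple[float, float]
    p_vs_half: float
    cutoff: float
    cutoff_rule: str
    sens_at_cutoff: float  # percent
    sens_ci95: tuple[float, float]
    spec_at_cutoff: float  # percent
    spec_ci95: tuple[float, float]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci95": list(self.ci95),
            "p_vs_half": self.p_vs_half,
            "cutoff": self.cutoff,
            "cutoff_rule": self.cutoff_rule,
            "sensitivity_percent": self.sens_at_cutoff,
            "sensitivity_ci95": list(self.sens_ci95),
            "specificity_percent": self.spec_at_cutoff,
            "specificity_ci95": list(self.spec_ci95),
            "degenerate": self.degenerate,
        }


@dataclass
class UnivariateResult:
    """Mann-Whitney comparison of one feature between the two groups."""

    feature_name: str
    U: float
    p: float
    bonferroni_alpha: float
    significant: bool
    median_by_group: dict[str, float]
    iqr_by_group: dict[str, tuple[float, float]]
    roc: RocResult | None = None

    def to_dict(self) -> dict:
        return {
            "feature_name": self.feature_name,
            "U": self.U,
            "p": self.p,
            "bonferroni_alpha": self.bonferroni_alpha,
            "significant": self.significant,
            "groups": {
                g: {
                    "median": self.median_by_group[g],
                    "iqr": list(self.iqr_by_group[g]),
                    "display": (
                        f"{self.median_by_group[g]:.3g} [IQR, "
                        f"{self.iqr_by_group[g][0]:.3g} - {self.iqr_by_group[g][1]:.3g}]"
                    ),
                }
                for g in self.median_by_group
            },
            "roc": self.roc.to_dict() if self.roc else None,
        }


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Midrank U for group y versus x: #{y > x} + 1/2 #{y == x}."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    n2 = y.size
    return float(ranks[x.size:].sum() - n2 * (n2 + 1) / 2.0)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (for y versus x) and a two-sided p-value.

    Exact enumeration of all label arrangements when n1 + n2 <= 12 and the
    pooled values carry no ties; otherwise the normal approximation with tie
    and continuity corrections.  Identical groups give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= EXACT_ENUMERATION_LIMIT and not has_ties:
        dev = abs(u - mu)
        ranks = rankdata(pooled)
        shift = n2 * (n2 + 1) / 2.0
        count = 0
        total = 0
        for comb in combinations(range(n1 + n2), n2):
            u_perm = ranks[list(comb)].sum() - shift
            total += 1
            if abs(u_perm - mu) >= dev - 1e-12:
                count += 1
        return u, count / total

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return u, p


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-test significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


def auc_from_ranks(values: np.ndarray, is_positive: np.ndarray) -> float:
    """AUC = U_pos / (n_pos * n_neg), ties counted half."""
    pos = values[is_positive]
    neg = values[~is_positive]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return _u_statistic(neg, pos) / (pos.size * neg.size)


def _delong_se(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong standard error of the AUC via placement values."""
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > nv) + 0.5 * (pos == nv)) for nv in neg])
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    return float(np.sqrt(s10 / pos.size + s01 / neg.size))


def roc_analysis(
    values: np.ndarray, labels: np.ndarray, positive_label: str
) -> RocResult:
    """ROC of one feature: AUC with DeLong CI, Youden-optimal cutoff.

    The cutoff is an observed feature value with the rule
    "> cutoff => positive"; candidates include the all-positive rule.
    Sensitivity and specificity at the cutoff carry exact binomial CIs.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive_label
    pos, neg = values[is_pos], values[~is_pos]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    auc = auc_from_ranks(values, is_pos)
    degenerate = np.unique(values).size == 1
    se = _delong_se(pos, neg, auc)
    if se > 0:
        z975 = float(norm.ppf(0.975))
        ci = (max(0.0, auc - z975 * se), min(1.0, auc + z975 * se))
        p_half = min(1.0, 2.0 * float(norm.sf(abs(auc - 0.5) / se)))
    else:
        ci = (auc, auc)
        p_half = 1.0 if auc == 0.5 else 0.0

    # candidate cutoffs: below all values (everything positive) + observed values
    candidates = np.concatenate([[-np.inf], np.unique(values)])
    best = None
    for c in candidates:
        sens = float(np.mean(pos > c))
        spec = float(np.mean(neg <= c))
        j = sens + spec - 1.0
        key = (round(j, 12), spec, c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cutoff, sens, spec = best
    tp = int(round(sens * pos.size))
    tn = int(round(spec * neg.size))
    return RocResult(
        auc=auc,
        ci95=ci,
        p_vs_half=p_half,
        cutoff=float(cutoff),
        cutoff_rule="> cutoff => positive",
        sens_at_cutoff=100.0 * sens,
        sens_ci95=tuple(100 * v for v in clopper_pearson(tp, pos.size)),
        spec_at_cutoff=100.0 * spec,
        spec_ci95=tuple(100 * v for v in clopper_pearson(tn, neg.size)),
        degenerate=degenerate,
    )


def univariate_screen(
    table: pd.DataFrame,
    selections: list[SelectionResult],
    alpha: float = 0.05,
    positive_label: str = "malignant",
) -> list[UnivariateResult]:
    """Mann-Whitney screen of the selected features, ROC for survivors.

    The Bonferroni denominator is the total number of selected features
    across all sets, counted with multiplicity (two sets of ten => 20), even
    when the sets overlap; each distinct feature is tested once.
    """
    feats, labels = feature_matrix(table)
    m = sum(len(sel.scores) for sel in selections)
    if m == 0:
        raise ValueError("no selected features to screen")
    threshold = bonferroni_threshold(alpha, m)
    classes = np.unique(labels)
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not in table")
    neg_label = classes[classes != positive_label][0]

    seen: list[str] = []
    for sel in selections:
        for name in sel.feature_names:
            if name not in seen:
                seen.append(name)

    results = []
    for name in seen:
        v = feats[name].to_numpy(dtype=float)
        x = v[labels == neg_label]
        y = v[labels == positive_label]
        u, p = mann_whitney(x, y)
        significant = p < threshold
        med = {neg_label: float(np.median(x)), positive_label: float(np.median(y))}
        iqr = {
            neg_label: (float(np.percentile(x, 25)), float(np.percentile(x, 75))),
            positive_label: (float(np.percentile(y, 25)), float(np.percentile(y, 75))),
        }
        roc = roc_analysis(v, labels, positive_label) if significant else None
        results.append(
            UnivariateResult(
                feature_name=name, U=u, p=p, bonferroni_alpha=threshold,
                significant=significant, median_by_group=med, iqr_by_group=iqr, roc=roc,
            )
        )
    return results
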